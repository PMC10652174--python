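"""Stochastic cellular processes on the lattice.

Five phenotypes live on the healing-domain grid: MSCs, fibroblasts,
chondrocytes, immature and mature osteoblasts.  Every day each cell may
migrate (MSCs and fibroblasts, in hourly sub-steps), differentiate (MSCs
only, steered by the local mechanical stimulus), proliferate into a free
neighbor site, die, or mature (immature -> mature osteoblast).

All operations are simultaneous vectorized updates with random tie-breaking:
when several cells target the same free site, a randomly ordered winner takes
it and the rest stay.  Together with the uniformly random choice among free
neighbors this keeps the dynamics free of directional bias.  Rates convert to
per-step probabilities as p = rate * dt, sub-divided only as needed to keep
p <= 1, which preserves the per-day branching mean exactly (a population with
division rate r grows by the factor 1 + r*dt per step while space lasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .geometry import (EMPTY, MSC, FIBROBLAST, CHONDROCYTE, OB_IMMATURE,
                       OB_MATURE, Lattice)
from .scenario import CellularRates, MechanoThresholds, Scenario

__all__ = [
    "StepConfig",
    "migrate",
    "proliferate",
    "differentiate",
    "mature",
    "apoptose",
    "effective_rates",
    "daily_step",
    "check_occupancy",
]

PHENOTYPES = (MSC, FIBROBLAST, CHONDROCYTE, OB_IMMATURE, OB_MATURE)

Rate = Union[float, np.ndarray]  # scalar or per-site flat array


@dataclass(frozen=True)
class StepConfig:
    """Coupling-step configuration: 1-day steps over 12 weeks by default."""

    days: int = 84
    step_days: float = 1.0
    migration_substep_hours: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = 24.0 * self.step_days / self.migration_substep_hours
        if abs(n - round(n)) > 1e-9:
            raise ValueError("migration sub-step must divide the coupling step")


def _offsets(lattice: Lattice) -> np.ndarray:
    sx, sy, sz = lattice.strides
    return np.array([sx, -sx, sy, -sy, sz, -sz])


def _per_cell(p: Rate, cells: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p[cells] if p.ndim else np.broadcast_to(p, cells.shape)


def _place(occ: np.ndarray, cells: np.ndarray, offsets: np.ndarray,
           rng: np.random.Generator):
    """Uniformly choose a free neighbor per cell; resolve target conflicts by
    random priority.  Returns (indices into ``cells`` that won a site, their
    target sites)."""
    if len(cells) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    tgt = cells[:, None] + offsets[None, :]
    free = occ[tgt] == EMPTY
    w = rng.random(tgt.shape)
    w[~free] = -1.0
    j = w.argmax(axis=1)
    rows = np.arange(len(cells))
    ok = w[rows, j] >= 0.0
    idx = rows[ok]
    tgt = tgt[rows, j][ok]
    order = rng.permutation(len(idx))
    _, first = np.unique(tgt[order], return_index=True)
    win = order[first]
    return idx[win], tgt[win]


def migrate(lattice: Lattice, phenotype: int, rate_um_h: Rate, dt_h: float,
            rng: np.random.Generator) -> Lattice:
    """Random-walk migration: each cell attempts ``rate*dt/spacing`` unit moves
    (fractional remainder as a Bernoulli trial) to a uniformly chosen free
    neighbor; blocked cells stay."""
    occ = lattice.occupancy
    offs = _offsets(lattice)
    cells = np.nonzero(occ == phenotype)[0]
    if len(cells) == 0:
        return lattice
    # step budget is fixed by the cell's rate at its starting site
    steps = _per_cell(rate_um_h, cells) * dt_h / lattice.spacing_um
    if np.any(steps < 0):
        raise ValueError("migration rate must be >= 0")
    n_int = np.floor(steps).astype(int)
    frac = steps - n_int
    pos = cells.copy()
    for k in range(1, int(n_int.max(initial=0)) + 1):
        active = np.nonzero(n_int >= k)[0]
        win, dst = _place(occ, pos[active], offs, rng)
        moved = active[win]
        occ[pos[moved]] = EMPTY
        occ[dst] = phenotype
        pos[moved] = dst
    movers = np.nonzero(rng.random(len(pos)) < frac)[0]
    win, dst = _place(occ, pos[movers], offs, rng)
    moved = movers[win]
    occ[pos[moved]] = EMPTY
    occ[dst] = phenotype
    return lattice


def proliferate(lattice: Lattice, phenotype: int, rate_day: Rate, dt_day: float,
                rng: np.random.Generator) -> Lattice:
    """Division with probability ``rate*dt``; the daughter occupies a uniformly
    chosen free neighbor, skipped under contact inhibition.  Probabilities
    above 1 are split into equal sub-steps."""
    occ = lattice.occupancy
    offs = _offsets(lattice)
    p_max = float(np.max(np.asarray(rate_day, dtype=float))) * dt_day
    if p_max < 0:
        raise ValueError("proliferation rate must be >= 0")
    n_sub = max(1, int(np.ceil(p_max - 1e-12)))
    for _ in range(n_sub):
        cells = np.nonzero(occ == phenotype)[0]
        if len(cells) == 0:
            return lattice
        p = _per_cell(rate_day, cells) * dt_day / n_sub
        dividing = cells[rng.random(len(cells)) < p]
        _, dst = _place(occ, dividing, offs, rng)  # daughters on free sites
        occ[dst] = phenotype
    return lattice


_OUTCOME_CODE = {"fibroblast": FIBROBLAST, "chondrocyte": CHONDROCYTE,
                 "immature_osteoblast": OB_IMMATURE}


def differentiate(lattice: Lattice, stimulus: np.ndarray,
                  thresholds: MechanoThresholds,
                  channel_rates: dict[str, Rate], dt_day: float,
                  rng: np.random.Generator) -> Lattice:
    """Mechano-regulated MSC differentiation.

    Each MSC reads the stimulus at its site; the containing window selects
    the target phenotype (bone window -> immature osteoblast) and the
    corresponding channel rate sets the per-day probability.  Stimuli in the
    lazy zone, or below the quiescent bound, leave the cell unchanged.
    """
    occ = lattice.occupancy
    mscs = np.nonzero(occ == MSC)[0]
    if len(mscs) == 0:
        return lattice
    s = stimulus[mscs]
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError("stimulus must be finite and >= 0 at every MSC site")
    q, b, c = thresholds.bounds
    target = np.where(s < q, EMPTY,
                      np.where(s < b, OB_IMMATURE,
                               np.where(s < c, CHONDROCYTE, FIBROBLAST)))
    lo, hi = thresholds.lazy_zone
    if lo < hi:
        target[(s >= lo) & (s < hi)] = EMPTY  # lazy zone: no differentiation
    p = np.zeros(len(mscs))
    for name, code in _OUTCOME_CODE.items():
        m = target == code
        if m.any():
            p[m] = _per_cell(channel_rates[name], mscs[m]) * dt_day
    convert = (rng.random(len(mscs)) < p) & (target != EMPTY)
    occ[mscs[convert]] = target[convert]
    return lattice


def mature(lattice: Lattice, rate_day: float, dt_day: float,
           rng: np.random.Generator) -> Lattice:
    """Immature -> mature osteoblast transition with probability ``rate*dt``."""
    if rate_day < 0:
        raise ValueError("maturation rate must be >= 0")
    occ = lattice.occupancy
    cells = np.nonzero(occ == OB_IMMATURE)[0]
    flip = cells[rng.random(len(cells)) < rate_day * dt_day]
    occ[flip] = OB_MATURE
    return lattice


def apoptose(lattice: Lattice, phenotype: int, rate_day: Rate, dt_day: float,
             rng: np.random.Generator) -> Lattice:
    """Remove each cell of the phenotype with probability ``rate*dt``."""
    occ = lattice.occupancy
    cells = np.nonzero(occ == phenotype)[0]
    p = _per_cell(rate_day, cells) * dt_day
    occ[cells[rng.random(len(cells)) < p]] = EMPTY
    return lattice


def effective_rates(scenario: Scenario, in_guidance_zone: bool) -> CellularRates:
    """Cellular rates at a site, accounting for the plate-adjacent zone.

    Outside the zone (or with guidance disabled) the scenario rates apply; in
    the zone the healthy group gets a 10 % enhancement and the diabetic group
    is restored to the full healthy rate set.
    """
    return scenario.guidance_rates() if in_guidance_zone else scenario.rates


def _site_rate(base: float, zone: float,
               zone_mask: Optional[np.ndarray], n: int) -> Rate:
    if zone_mask is None or base == zone:
        return base
    arr = np.full(n, base)
    arr[zone_mask] = zone
    return arr


def daily_step(lattice: Lattice, stimulus: np.ndarray, scenario: Scenario,
               rng: np.random.Generator,
               zone_mask: Optional[np.ndarray] = None,
               maturation_rate: float = None,
               config: StepConfig = StepConfig()) -> Lattice:
    """One coupling step of cellular processes.

    Order: migration (hourly sub-steps) -> differentiation -> proliferation ->
    apoptosis -> maturation.  ``zone_mask`` marks plate-adjacent sites whose
    rates follow :func:`effective_rates`.
    """
    from .tissue import MATURATION_RATE
    if maturation_rate is None:
        maturation_rate = MATURATION_RATE
    base = scenario.rates
    zone = scenario.guidance_rates() if scenario.guidance else base
    if scenario.guidance is None:
        zone_mask = None
    n = lattice.occupancy.size

    def r(field: str) -> Rate:
        return _site_rate(getattr(base, field), getattr(zone, field),
                          zone_mask, n)

    dt = config.step_days
    n_mig = int(round(24.0 * dt / config.migration_substep_hours))
    for _ in range(n_mig):
        migrate(lattice, MSC, r("msc_migration"),
                config.migration_substep_hours, rng)
        migrate(lattice, FIBROBLAST, r("fibroblast_migration"),
                config.migration_substep_hours, rng)
    differentiate(lattice, stimulus, scenario.thresholds,
                  {"fibroblast": r("fibroblast_differentiation"),
                   "chondrocyte": r("chondrocyte_differentiation"),
                   "immature_osteoblast": r("osteoblast_differentiation")},
                  dt, rng)
    proliferate(lattice, MSC, r("msc_proliferation"), dt, rng)
    proliferate(lattice, FIBROBLAST, r("fibroblast_proliferation"), dt, rng)
    proliferate(lattice, CHONDROCYTE, r("chondrocyte_proliferation"), dt, rng)
    proliferate(lattice, OB_IMMATURE, r("osteoblast_proliferation"), dt, rng)
    apoptose(lattice, MSC, r("msc_apoptosis"), dt, rng)
    apoptose(lattice, FIBROBLAST, r("fibroblast_apoptosis"), dt, rng)
    apoptose(lattice, CHONDROCYTE, r("chondrocyte_apoptosis"), dt, rng)
    apoptose(lattice, OB_IMMATURE, r("osteoblast_apoptosis"), dt, rng)
    # Mature osteoblasts are matrix-embedded (osteocyte-like): they keep
    # producing bone but no longer divide or undergo the apoptosis process;
    # the tabulated osteoblast rates drive the active immature pool.
    mature(lattice, maturation_rate, dt, rng)
    return lattice


def check_occupancy(lattice: Lattice) -> None:
    """Assert the structural lattice invariants (used by tests and smoke runs)."""
    occ = lattice.occupancy
    dom = lattice.in_domain
    if not np.all(occ[~dom] == -1):
        raise AssertionError("cells outside the healing domain")
    if not np.all((occ[dom] >= 0) & (occ[dom] <= 5)):
        raise AssertionError("invalid phenotype code on the lattice")
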