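"""Per-element tissue composition, matrix production, and material blending.

Each mesh element carries a composition vector over the five evolving healing
tissues (granulation, fibrous, cartilage, immature bone, mature bone) that
always sums to one on the element's healing sub-volume.  Matrix-producing
cells (fibroblasts, chondrocytes, osteoblasts) convert granulation tissue --
then softer formed tissues -- into their matrix type; immature bone matures
into mature bone with the same first-order rate used for osteoblast
maturation, keeping cell and matrix maturation consistent.

Material properties handed to the FE solver are a volume-fraction-weighted
rule of mixtures over the tissue presets (linear for E; Poisson blended over
the solid fractions and clamped below 0.5), smoothed by averaging over the
last ten coupling iterations to represent the lag of extracellular-matrix
maturation behind cellular activity.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from . import geometry as geo
from . import mechanics as mech

__all__ = [
    "TISSUE_ORDER",
    "PRODUCTION_RATE",
    "MATURATION_RATE",
    "initial_composition",
    "produce_matrix",
    "mature_matrix",
    "mixture_properties",
    "element_properties",
    "PropertyHistory",
    "smooth_properties",
]

#: Composition column order.
TISSUE_ORDER = ("granulation", "fibrous", "cartilage",
                "immature_bone", "mature_bone")
GRAN, FIBROUS, CARTILAGE, IMM_BONE, MAT_BONE = range(5)

#: Matrix production per resident producing cell, as element volume fraction
#: per day at full cell occupancy.  An element saturated with osteoblasts
#: ossifies in 1/rate = 10 days; the published model family does not print
#: this constant, so it is exposed here as a tunable.
PRODUCTION_RATE = 0.10

#: First-order activation -> embedding rate of osteoblasts and of their
#: woven matrix (1/day); the mean active period of an osteoblast before it is
#: buried in matrix is 1/rate = 2.5 days.
MATURATION_RATE = 0.4

_E_VEC = np.array([mech.TISSUE_PROPERTIES[t].young_modulus for t in TISSUE_ORDER])
_NU_VEC = np.array([mech.TISSUE_PROPERTIES[t].poisson_ratio for t in TISSUE_ORDER])

#: Consumption priority per produced matrix type: granulation first, then the
#: softer formed tissues.
_CONSUMES = {
    FIBROUS: (GRAN,),
    CARTILAGE: (GRAN, FIBROUS),
    IMM_BONE: (GRAN, FIBROUS, CARTILAGE),
}


def initial_composition(mesh: geo.Mesh) -> np.ndarray:
    """Post-surgery state: the healing domain is granulation tissue (hematoma)."""
    comp = np.zeros((mesh.n_elements, 5))
    comp[mesh.healing_fraction > 0, GRAN] = 1.0
    return comp


def produce_matrix(comp: np.ndarray, producers: dict[int, np.ndarray],
                   capacity: np.ndarray, dt: float,
                   production_rate: float = PRODUCTION_RATE) -> np.ndarray:
    """Convert soft tissue into matrix according to resident producing cells.

    ``producers`` maps a matrix index (FIBROUS, CARTILAGE or IMM_BONE) to the
    per-element count of cells producing it; ``capacity`` is the number of
    lattice sites per element.  Each cell converts up to
    ``production_rate * dt / capacity`` of the element, consuming granulation
    tissue first.  Fractions stay on the simplex.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    comp = comp.copy()
    cap = np.maximum(capacity, 1)
    for target in (FIBROUS, CARTILAGE, IMM_BONE):
        n = producers.get(target)
        if n is None:
            continue
        amount = production_rate * dt * np.asarray(n, dtype=float) / cap
        for source in _CONSUMES[target]:
            take = np.minimum(amount, comp[:, source])
            comp[:, source] -= take
            comp[:, target] += take
            amount = amount - take
    np.clip(comp, 0.0, None, out=comp)
    total = comp.sum(axis=1)
    active = total > 0
    comp[active] /= total[active, None]
    return comp


def mature_matrix(comp: np.ndarray, dt: float,
                  rate: float = MATURATION_RATE) -> np.ndarray:
    """First-order immature -> mature bone conversion."""
    comp = comp.copy()
    delta = comp[:, IMM_BONE] * (1.0 - np.exp(-rate * dt))
    comp[:, IMM_BONE] -= delta
    comp[:, MAT_BONE] += delta
    return comp


def mixture_properties(composition: np.ndarray) -> mech.MaterialProperties:
    """Rule-of-mixtures properties of a single healing-tissue composition."""
    c = np.asarray(composition, dtype=float)
    if c.shape != (5,):
        raise ValueError("composition must have five tissue fractions")
    if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be non-negative and sum to 1")
    E = float(c @ _E_VEC)
    nu = float(min(c @ _NU_VEC, 0.499))
    perm = float(np.exp(c @ np.log([mech.TISSUE_PROPERTIES[t].permeability
                                    for t in TISSUE_ORDER])))
    kg = float(c @ [mech.TISSUE_PROPERTIES[t].bulk_modulus_grain
                    for t in TISSUE_ORDER])
    kf = float(c @ [mech.TISSUE_PROPERTIES[t].bulk_modulus_fluid
                    for t in TISSUE_ORDER])
    return mech.MaterialProperties(E, nu, perm, kg, kf)


def element_properties(mesh: geo.Mesh, comp: np.ndarray,
                       group: str) -> tuple[np.ndarray, np.ndarray]:
    """Effective per-element (E, nu) blending static regions and healing tissue.

    E is a Voigt (volume-weighted) blend over the full element volume, so a
    partially empty boundary voxel is proportionally softer; Poisson's ratio
    is averaged over the solid fractions only.
    """
    fr = mesh.fractions
    E_heal = comp @ _E_VEC
    nu_heal = comp @ _NU_VEC
    E_cort = mech.cortical_modulus(group)
    # Non-plate constituents mix in parallel (Voigt) within the cross-section.
    f_np = np.maximum(1.0 - fr[:, geo.PLATE] - fr[:, geo.AIR], 1e-12)
    E_np = (fr[:, geo.CORTEX] * E_cort
            + fr[:, geo.MARROW] * mech.TISSUE_PROPERTIES["marrow"].young_modulus
            + fr[:, geo.SOFT] * mech.TISSUE_PROPERTIES["fibrous"].young_modulus
            + fr[:, geo.SCREW] * mech.SCREW_MODULUS
            + fr[:, geo.HEALING] * E_heal) / f_np
    # Voxels containing plate metal are layered composites (thin compliant
    # contact layer in series with the stiff slab): blend in series (Reuss) so
    # the interface compliance is not averaged away.
    f_p = fr[:, geo.PLATE]
    solid = np.maximum(1.0 - fr[:, geo.AIR], 1e-12)
    has_plate = f_p > 0
    E = solid * E_np
    fp_s = f_p / solid  # plate share of the solid cross-section
    with np.errstate(divide="ignore"):
        series = 1.0 / (fp_s / mech.TITANIUM.young_modulus
                        + (1.0 - fp_s) / np.maximum(E_np, mech.E_FLOOR))
    E[has_plate] = (solid * series)[has_plate]
    nu_num = (fr[:, geo.CORTEX] * 0.3
              + fr[:, geo.MARROW] * 0.167
              + fr[:, geo.SOFT] * 0.167
              + (fr[:, geo.PLATE] + fr[:, geo.SCREW]) * 0.3
              + fr[:, geo.HEALING] * nu_heal)
    solid = np.maximum(mesh.solid_fraction, 1e-9)
    nu = np.clip(nu_num / solid, 0.0, 0.499)
    return np.maximum(E, mech.E_FLOOR), nu


class PropertyHistory:
    """Ring buffer of derived per-element properties (last ten iterations)."""

    def __init__(self, length: int = 10):
        if length < 1:
            raise ValueError("history length must be >= 1")
        self._E: deque[np.ndarray] = deque(maxlen=length)
        self._nu: deque[np.ndarray] = deque(maxlen=length)

    def __len__(self) -> int:
        return len(self._E)

    def push(self, E: np.ndarray, nu: np.ndarray) -> None:
        self._E.append(np.asarray(E, dtype=float))
        self._nu.append(np.asarray(nu, dtype=float))

    def mean(self) -> tuple[np.ndarray, np.ndarray]:
        if not self._E:
            raise ValueError("empty history")
        return (np.mean(self._E, axis=0), np.mean(self._nu, axis=0))


def smooth_properties(history: PropertyHistory, E: np.ndarray,
                      nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Push the current raw properties and return the running mean (<= 10)."""
    history.push(E, nu)
    return history.mean()
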