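"""Scenario definitions: cellular-activity rate sets for healthy and diabetic healing.

A *scenario* bundles everything that distinguishes one simulated animal group
from another: the 15 cellular-activity rates plus the two initial seeding
densities, the mechanosensitivity windows that map a mechanical stimulus to a
differentiation outcome, the optional plate-surface guidance zone, and the
group tag that selects geometry and load schedule.

The healthy preset carries the rates of the validated uneventful-healing model
family; the diabetic (T2DM) preset is derived from it by applying the
literature-reported relative alterations (reduced migration, proliferation and
differentiation, increased apoptosis).  Both presets, and the per-factor level
switching used by the screening design, live here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "CellularRates",
    "AlterationSpec",
    "MechanoThresholds",
    "GuidanceSpec",
    "Scenario",
    "build_healthy_scenario",
    "build_t2dm_scenario",
    "apply_t2dm_alterations",
    "T2DM_ALTERATIONS",
    "DOE_FACTORS",
    "DUMMY_FACTORS",
    "FACTOR_FIELDS",
    "set_factor_level",
    "scenario_from_levels",
    "load_scenario",
    "save_scenario",
]


# Rate fields in the order they are conventionally tabulated.
RATE_FIELDS = (
    "initial_msc_density_periosteum",   # fraction of seedable sites
    "initial_msc_density_marrow",       # fraction of seedable sites
    "msc_migration",                    # um/h
    "fibroblast_migration",             # um/h
    "fibroblast_differentiation",       # events/day (MSC -> fibroblast channel)
    "chondrocyte_differentiation",      # events/day (MSC -> chondrocyte channel)
    "osteoblast_differentiation",       # events/day (MSC -> osteoblast channel)
    "msc_proliferation",                # events/day
    "fibroblast_proliferation",         # events/day
    "chondrocyte_proliferation",        # events/day
    "osteoblast_proliferation",         # events/day
    "msc_apoptosis",                    # events/day
    "fibroblast_apoptosis",             # events/day
    "chondrocyte_apoptosis",            # events/day
    "osteoblast_apoptosis",             # events/day
)


@dataclass(frozen=True)
class CellularRates:
    """The 15 cellular-activity parameters of one group.

    Densities are fractions of seedable lattice sites, migration speeds are in
    um/h, and every other rate is a first-order event rate in 1/day.
    """

    initial_msc_density_periosteum: float
    initial_msc_density_marrow: float
    msc_migration: float
    fibroblast_migration: float
    fibroblast_differentiation: float
    chondrocyte_differentiation: float
    osteoblast_differentiation: float
    msc_proliferation: float
    fibroblast_proliferation: float
    chondrocyte_proliferation: float
    osteoblast_proliferation: float
    msc_apoptosis: float
    fibroblast_apoptosis: float
    chondrocyte_apoptosis: float
    osteoblast_apoptosis: float

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in RATE_FIELDS[:2]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")

    def replace(self, **changes: float) -> "CellularRates":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_FIELDS}


#: Healthy rate set of the uneventful-healing model.
HEALTHY_RATES = CellularRates(
    initial_msc_density_periosteum=0.30,
    initial_msc_density_marrow=0.30,
    msc_migration=30.0,
    fibroblast_migration=30.0,
    fibroblast_differentiation=0.3,
    chondrocyte_differentiation=0.3,
    osteoblast_differentiation=0.3,
    msc_proliferation=0.6,
    fibroblast_proliferation=0.55,
    chondrocyte_proliferation=0.2,
    osteoblast_proliferation=0.3,
    msc_apoptosis=0.05,
    fibroblast_apoptosis=0.05,
    chondrocyte_apoptosis=0.1,
    osteoblast_apoptosis=0.16,
)


@dataclass(frozen=True)
class AlterationSpec:
    """Relative changes that turn the healthy rate set into the diabetic one.

    ``changes`` maps a rate field to a signed relative change (``-0.60`` means a
    60 % reduction) interpreted as ``healthy * (1 + change)``; entries listed in
    ``multiplicative`` instead map to an absolute factor, ``healthy * factor``.
    The distinction is needed because published "X % increase" statements are
    not applied uniformly across activities: a 600 % increase of fibroblast
    apoptosis enters the operative diabetic set as a factor of 6.
    """

    changes: dict[str, float] = field(default_factory=dict)
    multiplicative: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.changes) & set(self.multiplicative)
        if overlap:
            raise ValueError(f"fields listed twice in AlterationSpec: {sorted(overlap)}")
        for name in list(self.changes) + list(self.multiplicative):
            if name not in RATE_FIELDS:
                raise ValueError(f"unknown rate field {name!r}")


#: Diabetic alterations, activity by activity.  The initial MSC densities use
#: the operative 35 % reduction of the diabetic parameter table (30 % -> 19.5 %)
#: rather than the 33 % figure of the underlying cell-count study.
T2DM_ALTERATIONS = AlterationSpec(
    changes={
        "initial_msc_density_periosteum": -0.35,
        "initial_msc_density_marrow": -0.35,
        "msc_migration": -0.60,
        "fibroblast_migration": -0.75,
        "fibroblast_differentiation": -0.50,
        "chondrocyte_differentiation": -0.50,
        "osteoblast_differentiation": -0.50,
        "msc_proliferation": -0.65,
        "fibroblast_proliferation": -0.50,
        "chondrocyte_proliferation": -0.40,
        "osteoblast_proliferation": -0.50,
        "msc_apoptosis": +0.67,
        "chondrocyte_apoptosis": +1.00,
        "osteoblast_apoptosis": +0.50,
    },
    multiplicative={
        # "600 % increase" applied as a factor of 6 in the operative set.
        "fibroblast_apoptosis": 6.0,
    },
)


def apply_t2dm_alterations(healthy: CellularRates, alt: AlterationSpec) -> CellularRates:
    """Scale a healthy rate set by per-activity relative alterations.

    Fields absent from ``alt`` pass through unchanged.  A resulting negative
    rate is rejected (an alteration below -100 % is meaningless).
    """
    out: dict[str, float] = {}
    for name in RATE_FIELDS:
        v = getattr(healthy, name)
        if name in alt.changes:
            v = v * (1.0 + alt.changes[name])
        elif name in alt.multiplicative:
            v = v * alt.multiplicative[name]
        if v < 0:
            raise ValueError(f"alteration drives {name} negative ({v})")
        out[name] = v
    return CellularRates(**out)


T2DM_RATES = apply_t2dm_alterations(HEALTHY_RATES, T2DM_ALTERATIONS)


# ---------------------------------------------------------------------------
# Mechanosensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanoThresholds:
    """Windows of the scalar mechanical stimulus and the differentiation outcome.

    The stimulus is the octahedral shear strain at a cell's site
    (dimensionless).  Windows partition [0, inf) contiguously:

    * ``quiescent_upper``: below this the progenitor does not differentiate
      (resorption/lazy regime of the mechanoregulation lineage);
    * up to ``bone_upper``: osteogenic window (MSC -> immature osteoblast);
    * up to ``cartilage_upper``: chondrogenic window;
    * above: fibrous window.

    ``shift`` multiplies all bounds (diabetic mechanosensitivity is reduced by
    moving the windows to higher stimulus levels).  ``lazy_zone`` is an
    explicit no-differentiation interval used by the diabetic set; the healthy
    set has an empty one.
    """

    quiescent_upper: float = 1.075e-3
    bone_upper: float = 3.5e-3
    cartilage_upper: float = 1.05e-2
    shift: float = 1.0
    lazy_zone: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.quiescent_upper < self.bone_upper < self.cartilage_upper:
            raise ValueError("stimulus windows must be ordered and positive")
        if self.shift <= 0:
            raise ValueError("shift must be > 0")
        lo, hi = self.lazy_zone
        if lo > hi:
            raise ValueError("lazy zone bounds out of order")

    @property
    def bounds(self) -> tuple[float, float, float]:
        """Shifted window bounds (quiescent, bone, cartilage uppers)."""
        s = self.shift
        return (self.quiescent_upper * s, self.bone_upper * s, self.cartilage_upper * s)

    def outcome(self, stimulus: float) -> Optional[str]:
        """Differentiation outcome for one stimulus value (None = no change)."""
        if stimulus < 0:
            raise ValueError("stimulus must be >= 0")
        lo, hi = self.lazy_zone
        if lo < hi and lo <= stimulus < hi:
            return None
        q, b, c = self.bounds
        if stimulus < q:
            return None
        if stimulus < b:
            return "immature_osteoblast"
        if stimulus < c:
            return "chondrocyte"
        return "fibroblast"


HEALTHY_THRESHOLDS = MechanoThresholds()
#: Diabetic mechanosensitivity: the onset of mechano-driven differentiation is
#: moved to higher stimulus levels by a lazy zone (no differentiation) sitting
#: just above the shared quiescent bound.
T2DM_THRESHOLDS = MechanoThresholds(lazy_zone=(1.275e-3, 1.875e-3))


@dataclass(frozen=True)
class GuidanceSpec:
    """Enhanced cellular activity in the plate-adjacent zone.

    ``zone_width`` is the distance from the plate surface (um) within which the
    enhancement applies.  In the healthy group all rates are multiplied by
    ``healthy_multiplier``; in the diabetic group the zone instead uses the
    full healthy rate set.
    """

    zone_width: float = 30.0
    healthy_multiplier: float = 1.10

    def __post_init__(self) -> None:
        if self.zone_width <= 0:
            raise ValueError("zone_width must be > 0")
        if self.healthy_multiplier < 1:
            raise ValueError("healthy_multiplier must be >= 1")


@dataclass(frozen=True)
class Scenario:
    label: str
    rates: CellularRates
    thresholds: MechanoThresholds
    group: str  # "healthy" | "t2dm": selects geometry fixture and load schedule
    guidance: Optional[GuidanceSpec] = None
    factor_levels: Optional[dict[str, int]] = None  # recorded for DoE scenarios

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "t2dm"):
            raise ValueError(f"group must be 'healthy' or 't2dm', got {self.group!r}")

    def guidance_rates(self) -> CellularRates:
        """Rates effective inside the plate-adjacent zone (zone disabled -> same)."""
        if self.guidance is None:
            return self.rates
        if self.group == "healthy":
            m = self.guidance.healthy_multiplier
            return CellularRates(**{
                k: min(v * m, 1.0) if k in RATE_FIELDS[:2] else v * m
                for k, v in self.rates.as_dict().items()
            })
        return HEALTHY_RATES


def build_healthy_scenario(guidance: bool = False) -> Scenario:
    """Healthy preset: healthy rates, unshifted windows, healthy geometry/loads."""
    return Scenario(
        label="healthy_sg" if guidance else "healthy",
        rates=HEALTHY_RATES,
        thresholds=HEALTHY_THRESHOLDS,
        group="healthy",
        guidance=GuidanceSpec() if guidance else None,
    )


def build_t2dm_scenario(guidance: bool = False) -> Scenario:
    """Diabetic preset: altered rates, shifted windows + lazy zone, diabetic
    geometry and loads."""
    return Scenario(
        label="t2dm_sg" if guidance else "t2dm",
        rates=T2DM_RATES,
        thresholds=T2DM_THRESHOLDS,
        group="t2dm",
        guidance=GuidanceSpec() if guidance else None,
    )


# ---------------------------------------------------------------------------
# Screening-design factors
# ---------------------------------------------------------------------------

#: The 19 design columns in tabulated order; three dummies carry no parameter.
DOE_FACTORS = (
    "initial_msc_density_periosteum",
    "initial_msc_density_marrow",
    "msc_migration",
    "fibroblast_migration",
    "dummy_1",
    "fibroblast_differentiation",
    "chondrocyte_differentiation",
    "osteoblast_differentiation",
    "dummy_2",
    "msc_proliferation",
    "fibroblast_proliferation",
    "chondrocyte_proliferation",
    "osteoblast_proliferation",
    "dummy_3",
    "msc_apoptosis",
    "fibroblast_apoptosis",
    "chondrocyte_apoptosis",
    "osteoblast_apoptosis",
    "mechanosensitivity",
)

DUMMY_FACTORS = ("dummy_1", "dummy_2", "dummy_3")

#: Design factors that map one-to-one onto a CellularRates field.
FACTOR_FIELDS = tuple(f for f in DOE_FACTORS
                      if f not in DUMMY_FACTORS and f != "mechanosensitivity")


def set_factor_level(base_healthy: Scenario, base_t2dm: Scenario,
                     factor_id: str, level: int,
                     scenario: Optional[Scenario] = None) -> Scenario:
    """Set one design factor of ``scenario`` to its healthy (+1) or diabetic
    (-1) level.

    ``scenario`` defaults to ``base_t2dm``.  Rate factors copy the single
    corresponding rate; the mechanosensitivity factor switches the whole
    threshold block; dummy factors change nothing beyond the recorded level.
    """
    if factor_id not in DOE_FACTORS:
        raise KeyError(f"unknown design factor {factor_id!r}")
    if level not in (+1, -1):
        raise ValueError("level must be +1 or -1")
    if scenario is None:
        scenario = base_t2dm
    source = base_healthy if level == +1 else base_t2dm
    levels = dict(scenario.factor_levels or {})
    levels[factor_id] = level
    rates = scenario.rates
    thresholds = scenario.thresholds
    if factor_id == "mechanosensitivity":
        thresholds = source.thresholds
    elif factor_id not in DUMMY_FACTORS:
        rates = rates.replace(**{factor_id: getattr(source.rates, factor_id)})
    return dataclasses.replace(scenario, rates=rates, thresholds=thresholds,
                               factor_levels=levels)


def scenario_from_levels(base_healthy: Scenario, base_t2dm: Scenario,
                         levels: dict[str, int], label: str,
                         group: str = "t2dm") -> Scenario:
    """Assemble a screening-design scenario from a full factor->level map.

    The screening is run on the diabetic model (geometry and loads), so
    ``group`` defaults to ``"t2dm"``; guidance is disabled.
    """
    scenario = dataclasses.replace(base_t2dm, label=label, group=group,
                                   guidance=None, factor_levels={})
    for factor_id, level in levels.items():
        scenario = set_factor_level(base_healthy, base_t2dm, factor_id, level,
                                    scenario=scenario)
    return dataclasses.replace(scenario, label=label)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _scenario_to_dict(s: Scenario) -> dict:
    d = {
        "label": s.label,
        "group": s.group,
        "rates": s.rates.as_dict(),
        "thresholds": {
            "quiescent_upper": s.thresholds.quiescent_upper,
            "bone_upper": s.thresholds.bone_upper,
            "cartilage_upper": s.thresholds.cartilage_upper,
            "shift": s.thresholds.shift,
            "lazy_zone": list(s.thresholds.lazy_zone),
        },
    }
    if s.guidance is not None:
        d["guidance"] = {"zone_width": s.guidance.zone_width,
                         "healthy_multiplier": s.guidance.healthy_multiplier}
    if s.factor_levels:
        d["factor_levels"] = dict(s.factor_levels)
    return d


def _scenario_from_dict(d: dict) -> Scenario:
    th = d.get("thresholds", {})
    lazy = tuple(th.get("lazy_zone", (0.0, 0.0)))
    guidance = None
    if "guidance" in d:
        guidance = GuidanceSpec(**d["guidance"])
    return Scenario(
        label=d["label"],
        rates=CellularRates(**d["rates"]),
        thresholds=MechanoThresholds(
            quiescent_upper=th.get("quiescent_upper", 1.075e-3),
            bone_upper=th.get("bone_upper", 3.5e-3),
            cartilage_upper=th.get("cartilage_upper", 1.05e-2),
            shift=th.get("shift", 1.0),
            lazy_zone=lazy,
        ),
        group=d["group"],
        guidance=guidance,
        factor_levels=d.get("factor_levels"),
    )


def save_scenario(scenario: Scenario, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path: str) -> Scenario:
    """Load a scenario from YAML, or resolve a preset name.

    Accepts the preset names ``healthy``, ``t2dm``, ``healthy_sg``, ``t2dm_sg``
    or a path to a YAML file produced by :func:`save_scenario`.
    """
    presets = {
        "healthy": lambda: build_healthy_scenario(),
        "healthy_sg": lambda: build_healthy_scenario(guidance=True),
        "t2dm": lambda: build_t2dm_scenario(),
        "t2dm_sg": lambda: build_t2dm_scenario(guidance=True),
    }
    if path in presets:
        return presets[path]()
    with open(path) as fh:
        return _scenario_from_dict(yaml.safe_load(fh))
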