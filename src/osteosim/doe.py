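"""20-run Plackett-Burman screening of the 16 cellular-activity factors.

Each of the 19 design columns is a cellular parameter at two levels, healthy
(+1) or diabetic (-1); three columns are dummies without physical meaning
that estimate noise/interaction effects.  Every row defines one healing
simulation; the response is the final BV/TV in the gap.  Factor importance is
the two-level factorial sum of squares, SS = N/4 * (mean(+1) - mean(-1))^2,
equivalently 10 * (mean(+1) - grand_mean)^2 + 10 * (mean(-1) - grand_mean)^2
for the balanced 20-run design.  The column-independent total sum of squares
sum_i (X_i - mean)^2 is also available for transparency.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .scenario import (DOE_FACTORS, DUMMY_FACTORS, Scenario,
                       scenario_from_levels)

__all__ = [
    "plackett_burman_design",
    "validate_design",
    "run_doe",
    "sum_of_squares",
    "effect_table",
    "rank_factors",
    "top_factor_scenarios",
]

# The canonical 20-run two-level screening array (rows = experiments,
# columns = the 19 factors in tabulated order; dummies at columns 5, 9, 14).
_DESIGN_20x19 = np.array([
    [-1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1],
    [+1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1],
    [+1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1],
    [-1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1],
    [-1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1],
    [+1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1],
    [+1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1],
    [+1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1],
    [+1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1],
    [-1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1, +1],
    [+1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1, -1],
    [-1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1, +1],
    [+1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1, -1],
    [-1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1, -1],
    [-1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1, -1],
    [-1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1, -1],
    [-1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1, +1],
    [+1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1, +1],
    [+1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1, -1],
    [-1, +1, +1, -1, -1, -1, -1, +1, -1, +1, -1, +1, +1, +1, +1, -1, -1, +1, +1],
], dtype=int)


def plackett_burman_design(n_factors: int = 19) -> pd.DataFrame:
    """The canonical 20-run screening matrix as a factor-labelled DataFrame.

    ``n_factors`` may be lowered to take a left-subset of columns; it cannot
    exceed the 19 columns the 20-run design resolves.
    """
    if not 1 <= n_factors <= 19:
        raise ValueError("the 20-run design resolves between 1 and 19 factors")
    df = pd.DataFrame(_DESIGN_20x19, columns=list(DOE_FACTORS),
                      index=pd.RangeIndex(1, 21, name="experiment"))
    validate_design(df.to_numpy())
    return df.iloc[:, :n_factors]


def validate_design(design: np.ndarray) -> None:
    """Generator cross-check: two balanced orthogonal levels per column."""
    d = np.asarray(design)
    if not np.all(np.isin(d, (-1, 1))):
        raise ValueError("design entries must be +/-1")
    if np.any(d.sum(axis=0) != 0):
        raise ValueError("design columns must be balanced")
    gram = d.T @ d
    if np.any(gram - np.diag(np.diag(gram))):
        raise ValueError("design columns must be mutually orthogonal")


def sum_of_squares(responses: Sequence[float], design: np.ndarray,
                   column: int, method: str = "factorial") -> float:
    """Importance of one design column for the response vector.

    ``factorial`` (the operative definition used for ranking) is the
    two-level factorial sum of squares N/4 * (mean+ - mean-)^2.  ``total``
    is the literal column-independent sum sum_i (X_i - mean)^2.
    """
    x = np.asarray(responses, dtype=float)
    d = np.asarray(design)
    if len(x) != d.shape[0]:
        raise ValueError("one response per design row required")
    if method == "total":
        return float(np.sum((x - x.mean()) ** 2))
    if method != "factorial":
        raise ValueError("method must be 'factorial' or 'total'")
    col = d[:, column]
    plus, minus = x[col == +1], x[col == -1]
    if len(plus) != len(minus):
        raise ValueError("unbalanced design column")
    return float(len(x) / 4.0 * (plus.mean() - minus.mean()) ** 2)


def effect_table(responses: Sequence[float],
                 design: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-factor contrast effects, factorial SS, and descending-SS ranks."""
    if design is None:
        design = plackett_burman_design()
    d = design.to_numpy()
    x = np.asarray(responses, dtype=float)
    rows = []
    for c, name in enumerate(design.columns):
        col = d[:, c]
        eff = x[col == +1].mean() - x[col == -1].mean()
        rows.append({"factor": name,
                     "effect": eff,
                     "ss": sum_of_squares(x, d, c),
                     "dummy": name in DUMMY_FACTORS})
    table = pd.DataFrame(rows).set_index("factor")
    # ties broken by tabulated order, reported as average-free integer ranks
    order = np.argsort(-table["ss"].to_numpy(), kind="stable")
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["grand_mean"] = x.mean()
    return table


def rank_factors(table: pd.DataFrame) -> list[str]:
    """Factor names in descending order of importance (SS)."""
    return list(table.sort_values(["rank"]).index)


def run_doe(base_healthy: Scenario, base_t2dm: Scenario,
            seeds: Iterable[int] = (0, 1, 2), preset: str = "desk",
            days: int = 84,
            design: Optional[pd.DataFrame] = None,
            runner=None) -> pd.DataFrame:
    """Run every design row and return per-row mean final BV/TV.

    Each row builds its scenario by switching every design column to the
    healthy (+1) or diabetic (-1) level on the diabetic base model; the
    response is the final BV/TV averaged over ``seeds``.  ``runner`` may
    replace :func:`pipeline.run_simulation` (same signature subset) e.g. for
    cached sweeps.
    """
    from .pipeline import run_simulation
    if design is None:
        design = plackett_burman_design()
    if runner is None:
        def runner(scn, seed):
            return run_simulation(scn, preset=preset, seed=seed, days=days,
                                  keep_fields=False).final_bvtv
    records = []
    for i, (_, row) in enumerate(design.iterrows(), start=1):
        levels = {f: int(v) for f, v in row.items()}
        scn = scenario_from_levels(base_healthy, base_t2dm, levels,
                                   label=f"doe_{i:02d}")
        try:
            vals = [runner(scn, seed) for seed in seeds]
        except Exception as exc:
            raise RuntimeError(f"screening run failed at design row {i}") from exc
        records.append({"experiment": i, "bvtv": float(np.mean(vals)),
                        **levels})
    return pd.DataFrame(records).set_index("experiment")


def top_factor_scenarios(base_healthy: Scenario, base_t2dm: Scenario,
                         factors: Sequence[str]) -> dict[str, Scenario]:
    """All-healthy scenarios with every non-empty combination of ``factors``
    switched to the diabetic level (singletons, pairs, ..., full set)."""
    if not factors:
        raise ValueError("factor subset must be non-empty")
    for f in factors:
        if f not in DOE_FACTORS:
            raise KeyError(f"unknown design factor {f!r}")
    out: dict[str, Scenario] = {}
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            levels = {f: (-1 if f in combo else +1) for f in DOE_FACTORS}
            label = "t2dm_only[" + "+".join(combo) + "]"
            out[label] = scenario_from_levels(base_healthy, base_t2dm,
                                              levels, label=label)
    return out
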