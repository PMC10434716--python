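"""Summary statistics mirroring the study's analysis conventions.

Proportions are reported with SEMs computed over eight pseudo-subject blocks
(trials partitioned by index), mirroring the eight-observer error bars of the
psychophysical data; no inferential F statistics are computed.  Ascending and
descending hysteresis curves use the study's asymmetric plotting conventions:
ascending trials (initially invisible) contribute the proportion with at
least one invisible-to-visible switch, descending trials (initially visible)
the proportion remaining visible throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "MissingCellError",
    "SwitchCurve",
    "HysteresisTable",
    "N_PSEUDO_SUBJECTS",
    "HYSTERESIS_COMPARISON_RANGE",
    "aggregate_proportions",
    "switch_curves",
    "fit_constant_switch_probability",
    "predicted_switch_curve",
    "hysteresis_gap",
    "psychometric_table",
]


class MissingCellError(ValueError):
    """A requested design cell contains no trials."""


#: Number of pseudo-subject blocks used for SEMs (the human panels had n=8).
N_PSEUDO_SUBJECTS = 8

#: End contrasts common to ascending and descending ladders.
HYSTERESIS_COMPARISON_RANGE = (0.017, 0.065)


@dataclass
class SwitchCurve:
    """Proportion of trials with >= 1 switch as a function of N presentations."""

    N: np.ndarray
    prop_switch: np.ndarray
    initial_state: str          # 'visible' | 'invisible'
    n_trials: np.ndarray | None = None
    fitted_p: float | None = None

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=int)
        self.prop_switch = np.asarray(self.prop_switch, dtype=float)
        if np.any((self.prop_switch < 0) | (self.prop_switch > 1)):
            raise ValueError("switch proportions must lie in [0, 1]")


@dataclass
class HysteresisTable:
    """Descending-vs-ascending visibility on the common end-contrast range."""

    table: pd.DataFrame  # end_contrast, visible_prop_descending/ascending, gap, sems

    @property
    def mean_gap(self) -> float:
        return float(self.table["gap"].mean())


def _block_sem(values: np.ndarray, n_blocks: int = N_PSEUDO_SUBJECTS) -> float:
    """SEM of the proportion across pseudo-subject blocks."""
    values = np.asarray(values, dtype=float)
    k = min(n_blocks, len(values))
    if k < 2:
        return 0.0
    blocks = np.array_split(values, k)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(k))


def aggregate_proportions(
    results: pd.DataFrame, grouping: list[str], value: str = "initial_visible"
) -> pd.DataFrame:
    """Proportion and pseudo-subject SEM of a boolean outcome per cell."""
    if results.empty:
        raise MissingCellError("no trials to aggregate")
    rows = []
    for keys, sub in results.groupby(grouping, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = sub[value].to_numpy(dtype=float)
        rows.append(
            {
                **dict(zip(grouping, keys)),
                "proportion": float(vals.mean()),
                "sem": _block_sem(vals),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def switch_curves(results: pd.DataFrame) -> dict[str, SwitchCurve]:
    """Per-initial-state switch curves from constant-contrast trials."""
    out = {}
    for state, mask in (
        ("visible", results["initial_visible"]),
        ("invisible", ~results["initial_visible"]),
    ):
        sub = results[mask]
        grouped = sub.groupby("n_presentations")["any_switch"]
        props = grouped.mean()
        curve = SwitchCurve(
            N=props.index.to_numpy(),
            prop_switch=props.to_numpy(),
            initial_state=state,
            n_trials=grouped.size().to_numpy(),
        )
        curve.fitted_p = fit_constant_switch_probability(curve)
        out[state] = curve
    return out


def predicted_switch_curve(p: float, N: np.ndarray) -> np.ndarray:
    """Probability of >= 1 switch in N-1 presentations at constant hazard p."""
    return 1.0 - (1.0 - p) ** (np.asarray(N) - 1)


def fit_constant_switch_probability(curve: SwitchCurve) -> float:
    """Least-squares per-presentation switch probability on [0, 1].

    Fits ``1 - (1 - p)^(N-1)`` to the proportion-with-switch curve; exact
    inverse on noiseless closed-form curves.
    """
    if len(curve.N) < 2:
        raise ValueError("need >= 2 presentation counts to fit")
    N = curve.N.astype(float)
    y = curve.prop_switch

    def sse(p):
        return float(np.sum((y - predicted_switch_curve(p, N)) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    p = float(res.x)
    # the bounded minimizer never lands exactly on a boundary; snap if better
    for boundary in (0.0, 1.0):
        if sse(boundary) <= sse(p):
            p = boundary
    return p


def _direction_stat(sub: pd.DataFrame, direction: str) -> pd.Series:
    if direction == "ascending":
        sub = sub[~sub["initial_visible"]]
        became_visible = sub["per_frame_visible"].str.contains("V")
        return became_visible.groupby(sub["end_contrast"]).mean()
    sub = sub[sub["initial_visible"]]
    stayed = ~sub["per_frame_visible"].str.contains("-")
    return stayed.groupby(sub["end_contrast"]).mean()


def hysteresis_gap(
    results: pd.DataFrame,
    comparison_range: tuple = HYSTERESIS_COMPARISON_RANGE,
) -> HysteresisTable:
    """Descending-minus-ascending visibility on the common contrast range.

    Ascending trials are filtered to those starting invisible and contribute
    P(>= 1 invisible-to-visible switch); descending trials are filtered to
    those starting visible and contribute P(visible throughout).
    """
    for direction in ("ascending", "descending"):
        if not (results["condition"] == direction).any():
            raise MissingCellError(f"no {direction} trials present")
    lo, hi = comparison_range
    rows = []
    for c in sorted(results["end_contrast"].unique()):
        if not (lo - 1e-9 <= c <= hi + 1e-9):
            continue
        row = {"end_contrast": c}
        ok = True
        for direction in ("ascending", "descending"):
            sub = results[
                (results["condition"] == direction)
                & (np.abs(results["end_contrast"] - c) < 1e-9)
            ]
            if direction == "ascending":
                sub = sub[~sub["initial_visible"]]
                vals = sub["per_frame_visible"].str.contains("V").to_numpy(dtype=float)
            else:
                sub = sub[sub["initial_visible"]]
                vals = (~sub["per_frame_visible"].str.contains("-")).to_numpy(dtype=float)
            if len(vals) == 0:
                ok = False
                break
            row[f"visible_prop_{direction}"] = float(vals.mean())
            row[f"sem_{direction}"] = _block_sem(vals)
        if ok:
            row["gap"] = (
                row["visible_prop_descending"] - row["visible_prop_ascending"]
            )
            rows.append(row)
    if not rows:
        raise MissingCellError("no end contrasts on the comparison range")
    return HysteresisTable(table=pd.DataFrame(rows))


def psychometric_table(results: pd.DataFrame) -> pd.DataFrame:
    """Visible proportion per probe contrast and condition (pair designs).

    The judged stimulus is the probe, scored on its own frame; each condition
    is paired with the baseline to give facilitation/suppression deltas.
    """
    probe_visible = results["per_frame_visible"].str.endswith("V")
    tab = (
        results.assign(probe_visible=probe_visible)
        .groupby(["condition", "probe_contrast"])["probe_visible"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "proportion", "size": "n"})
        .reset_index()
    )
    base = tab[tab["condition"] == "baseline"].set_index("probe_contrast")[
        "proportion"
    ]
    tab["delta_vs_baseline"] = tab.apply(
        lambda r: r["proportion"] - base.get(r["probe_contrast"], np.nan),
        axis=1,
    )
    return tab
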