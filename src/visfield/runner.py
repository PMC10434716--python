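"""Seeded Monte-Carlo replication of the ten experimental designs.

Every experiment runs from the same shared :class:`FieldParams` instance;
only the stimulus protocols differ.  Trial seeds are derived deterministically
from the master seed (bound to cell and trial indices, so results are
invariant to execution order), and ablations zero out a single mechanism's
gain while leaving everything else untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field as dc_field

import numpy as np
import pandas as pd

from .field_core import FieldGrid, FieldParams, InvalidParameterError, simulate_frames
from .readout import score_trial, staircase_threshold
from .stimuli import (
    EXP9_CONTRASTS,
    LADDER_CONTRASTS,
    PAIR_PROBE_CONTRASTS,
    TrialProtocol,
    build_ladder_trial,
    build_pair_trial,
    build_stability_trial,
)

__all__ = ["ExperimentRun", "run_experiment", "ablate", "ABLATABLE"]

#: Mechanisms that can be removed from the model, and the parameter each
#: ablation zeroes.
ABLATABLE = {
    "no_adaptation": "adapt_gain",
    "no_trace": "trace_gain",
    "no_noise": ("noise_slow_amp", "noise_fast_amp"),
    "no_self_excitation": "w_uu_amp",
}

EXP2_ISIS = (107, 200, 307, 400, 507, 600, 707, 800)


def ablate(params: FieldParams, component: str) -> FieldParams:
    """Return params with one mechanism's gain/amplitude set to zero."""
    try:
        target = ABLATABLE[component]
    except KeyError:
        raise InvalidParameterError(
            f"unknown ablation {component!r}; choose from {sorted(ABLATABLE)}"
        ) from None
    names = target if isinstance(target, tuple) else (target,)
    return replace(params, **{name: 0.0 for name in names})


@dataclass
class ExperimentRun:
    """Scored results of one Monte-Carlo experiment replication."""

    experiment_id: int
    n_trials: int
    master_seed: int
    params: FieldParams
    params_hash: str
    ablations: tuple = ()
    results: pd.DataFrame = dc_field(default_factory=pd.DataFrame)


def _cells(experiment_id: int) -> list[dict]:
    """Enumerate an experiment's design cells."""
    if experiment_id == 1:
        return [
            {"condition": cond, "probe_contrast": c}
            for cond in ("baseline", "object_low", "object_high")
            for c in PAIR_PROBE_CONTRASTS
        ]
    if experiment_id == 2:
        return [
            {"condition": cond, "isi_ms": isi}
            for cond in ("baseline", "object")
            for isi in EXP2_ISIS
        ]
    if experiment_id == 3:
        return [
            {"condition": cond, "probe_contrast": c}
            for cond in ("baseline", "object")
            for c in PAIR_PROBE_CONTRASTS
        ]
    if experiment_id == 4:
        return [{"n_presentations": n} for n in range(2, 10)]
    if experiment_id in (5, 8):
        blank = 614.0 if experiment_id == 8 else 0.0
        return [
            {"direction": d, "end_contrast": c, "blank_ms": blank}
            for d in ("ascending", "descending")
            for c in _ladder_ends(d, LADDER_CONTRASTS)
        ]
    if experiment_id == 6:
        return [
            {"direction": d, "end_contrast": c, "start_reps": r}
            for d in ("ascending", "descending")
            for c in _ladder_ends(d, LADDER_CONTRASTS)
            for r in (1, 4)
        ]
    if experiment_id == 7:
        return [
            {"direction": d, "end_contrast": c, "end_reps": r}
            for d in ("ascending", "descending")
            for c in _ladder_ends(d, LADDER_CONTRASTS)
            for r in (1, 4)
        ]
    if experiment_id == 9:
        return [
            {"direction": d, "end_contrast": c, "frame_ms": 116.0}
            for d in ("ascending", "descending")
            for c in _ladder_ends(d, EXP9_CONTRASTS)
        ]
    if experiment_id == 10:
        return [
            {"condition": cond, "gap_arcmin": g}
            for cond in ("baseline", "object_low", "object_high")
            for g in (3.3, 6.6, 9.9, 13.2)
        ]
    raise InvalidParameterError(f"unknown experiment {experiment_id}")


def _ladder_ends(direction: str, contrast_set: tuple) -> tuple:
    """End contrasts reachable in >= 1 step (8 per direction)."""
    return contrast_set[1:] if direction == "ascending" else contrast_set[:-1]


def _build_protocol(
    experiment_id: int, cell: dict, rng: np.random.Generator
) -> TrialProtocol:
    if experiment_id == 1:
        cond = cell["condition"]
        return build_pair_trial(
            1,
            "baseline" if cond == "baseline" else "object",
            cell["probe_contrast"],
            object_contrast=0.24 if cond == "object_high" else 0.071,
            rng=rng,
        )
    if experiment_id == 2:
        return build_pair_trial(
            2, cell["condition"], 0.008, isi_ms=cell["isi_ms"],
            object_contrast=0.073, rng=rng,
        )
    if experiment_id == 3:
        return build_pair_trial(
            3, cell["condition"], cell["probe_contrast"], rng=rng
        )
    if experiment_id == 4:
        return build_stability_trial(cell["n_presentations"], rng)
    if experiment_id in (5, 6, 7, 8, 9):
        return build_ladder_trial(
            cell["direction"],
            cell["end_contrast"],
            rng,
            start_reps=cell.get("start_reps", 1),
            end_reps=cell.get("end_reps", 1),
            blank_ms=cell.get("blank_ms", 0.0),
            frame_ms=cell.get("frame_ms", 360.0),
            contrast_set=EXP9_CONTRASTS if experiment_id == 9 else LADDER_CONTRASTS,
            experiment_id=experiment_id,
        )
    raise InvalidParameterError(f"unknown experiment {experiment_id}")


def _trial_seed(master_seed: int, experiment_id: int, cell_idx: int, trial_idx: int):
    return np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(int(experiment_id), int(cell_idx), int(trial_idx)),
    )


def run_experiment(
    experiment_id: int,
    params: FieldParams,
    n_trials_per_cell: int = 200,
    master_seed: int = 0,
    ablations: tuple = (),
    grid: FieldGrid | None = None,
    record_stride_ms: float = 5.0,
) -> ExperimentRun:
    """Simulate and score every cell of one experiment's design.

    Fully reproducible from ``(params, master_seed)``; the ablated parameter
    set is derived on the fly so the shared base parameters stay identical
    across experiments.
    """
    from .io import params_hash

    base = params
    for component in ablations:
        base = ablate(base, component)
    grid = grid or FieldGrid()

    rows = []
    if experiment_id == 10:
        for cell_idx, cell in enumerate(_cells(10)):
            cond = cell["condition"]
            object_contrast = {
                "baseline": None, "object_low": 0.071, "object_high": 0.24
            }[cond]
            for trial_idx in range(n_trials_per_cell):
                ss = _trial_seed(master_seed, 10, cell_idx, trial_idx)
                seed = int(ss.generate_state(1)[0] % (2**31))
                thr, ceiling = staircase_threshold(
                    cell["gap_arcmin"],
                    "baseline" if cond == "baseline" else "object",
                    base,
                    seed,
                    object_contrast=object_contrast,
                    grid=grid,
                )
                rows.append(
                    {
                        "experiment_id": 10,
                        "condition": cond,
                        "gap_arcmin": cell["gap_arcmin"],
                        "threshold_contrast": thr,
                        "at_ceiling": ceiling,
                        "seed": seed,
                        "trial_index": trial_idx,
                    }
                )
    else:
        for cell_idx, cell in enumerate(_cells(experiment_id)):
            for trial_idx in range(n_trials_per_cell):
                ss = _trial_seed(master_seed, experiment_id, cell_idx, trial_idx)
                rng = np.random.default_rng(ss)
                protocol = _build_protocol(experiment_id, cell, rng)
                record = simulate_frames(
                    protocol, base, rng, grid=grid,
                    record_stride_ms=record_stride_ms,
                )
                result = score_trial(
                    record, protocol, base.input_width,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                )
                row = result.to_row()
                row.update(cell)
                row["trial_index"] = trial_idx
                rows.append(row)

    return ExperimentRun(
        experiment_id=experiment_id,
        n_trials=n_trials_per_cell,
        master_seed=master_seed,
        params=base,
        params_hash=params_hash(base),
        ablations=tuple(ablations),
        results=pd.DataFrame(rows),
    )
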