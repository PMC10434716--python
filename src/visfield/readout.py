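"""Model observer: map field activation to visibility judgments.

A stimulus counts as visible during a frame when the excitatory field
exceeds the zero threshold near the stimulus location for a sustained
fraction of the frame (default one quarter of its sampled instants).  The
sustained criterion avoids scoring transient noise spikes as percepts;
activation exactly at threshold is classified as not visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_core import ActivationRecord, FieldGrid, FieldParams, simulate_frames
from .stimuli import TrialProtocol, build_threshold_presentation

__all__ = [
    "TrialResult",
    "InvalidQueryError",
    "DEFAULT_CRITERION",
    "frame_visible",
    "score_trial",
    "staircase_threshold",
]


class InvalidQueryError(ValueError):
    """The queried frame carries no stimulus to judge."""


#: Fraction of a frame's sampled instants that must be suprathreshold.
DEFAULT_CRITERION = 0.25


@dataclass
class TrialResult:
    """Visibility judgments for one simulated trial."""

    initial_visible: bool
    per_frame_visible: list
    n_switches: int
    first_switch_direction: str  # 'vis->invis' | 'invis->vis' | 'none'
    any_switch: bool
    experiment_id: int = 0
    condition: str = ""
    end_contrast: float = float("nan")
    seed: int = -1
    meta: dict = dc_field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "condition": self.condition,
            "end_contrast": self.end_contrast,
            "seed": self.seed,
            "initial_visible": self.initial_visible,
            "any_switch": self.any_switch,
            "n_switches": self.n_switches,
            "first_switch_direction": self.first_switch_direction,
            "per_frame_visible": "".join(
                "V" if x else "-" for x in self.per_frame_visible
            ),
            **self.meta,
        }


def frame_visible(
    record: ActivationRecord,
    frame_index: int,
    stimulus_center: float,
    input_width: float,
    criterion: float = DEFAULT_CRITERION,
) -> bool:
    """Sustained suprathreshold detection of one stimulus frame.

    True iff ``u`` exceeds zero at some grid point within half the input
    width of the stimulus center for at least ``criterion`` of the frame's
    sampled instants.
    """
    samples = record.frame_samples(frame_index)
    if samples.size == 0:
        raise InvalidQueryError(
            f"frame {frame_index} has no recorded samples"
        )
    x = record.grid.positions
    window = np.abs(x - stimulus_center) <= input_width / 2.0
    if not window.any():
        raise InvalidQueryError("stimulus center lies outside the grid")
    above = (samples[:, window] > 0.0).any(axis=1)
    return bool(above.mean() >= criterion)


def _judged_centers(protocol: TrialProtocol) -> list[tuple[int, float]]:
    out = []
    for i in protocol.judged_frames():
        frame = protocol.frames[i]
        if not frame.inputs:
            raise InvalidQueryError(f"judged frame {i} carries no stimulus")
        # the judged stimulus is the last-listed input of the frame (the
        # probe in pair trials; the object elsewhere)
        out.append((i, frame.inputs[-1][0]))
    return out


def score_trial(
    record: ActivationRecord,
    protocol: TrialProtocol,
    input_width: float,
    criterion: float = DEFAULT_CRITERION,
    seed: int = -1,
) -> TrialResult:
    """Score every judged stimulus frame and derive switch statistics."""
    visible = [
        frame_visible(record, i, center, input_width, criterion)
        for i, center in _judged_centers(protocol)
    ]
    switches = [
        (a, b) for a, b in zip(visible[:-1], visible[1:]) if a != b
    ]
    if switches:
        first = "vis->invis" if switches[0][0] else "invis->vis"
    else:
        first = "none"
    return TrialResult(
        initial_visible=visible[0],
        per_frame_visible=visible,
        n_switches=len(switches),
        first_switch_direction=first,
        any_switch=len(switches) > 0,
        experiment_id=protocol.experiment_id,
        condition=protocol.condition,
        end_contrast=protocol.end_contrast,
        seed=seed,
        meta=dict(protocol.meta.get("result_meta", {})),
    )


def staircase_threshold(
    gap_arcmin: float,
    condition: str,
    params: FieldParams,
    seed: int,
    start_contrast: float = 0.071,
    step_down: float = 0.008,
    object_contrast: float | None = None,
    grid: FieldGrid | None = None,
    criterion: float = DEFAULT_CRITERION,
) -> tuple[float, bool]:
    """Descend probe contrast until the probe is first invisible.

    Simulates single presentations at fresh random locations, lowering probe
    contrast by ``step_down`` after each visible outcome.  Returns
    ``(threshold_contrast, at_ceiling)``; ``at_ceiling`` is True when the
    probe was already invisible at ``start_contrast``.
    """
    if step_down <= 0:
        raise InvalidQueryError("step_down must be > 0")
    if condition == "object" and object_contrast is None:
        object_contrast = 0.071
    if condition == "baseline":
        object_contrast = None
    rng = np.random.default_rng(seed)
    contrast = float(start_contrast)
    first = True
    while True:
        protocol = build_threshold_presentation(
            gap_arcmin, object_contrast, contrast, rng=rng
        )
        record = simulate_frames(
            protocol, params, rng, grid=grid
        )
        result = score_trial(record, protocol, params.input_width, criterion)
        if not result.per_frame_visible[-1]:
            return contrast, first
        first = False
        if contrast - step_down <= 0:
            return 0.0, False
        contrast -= step_down
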