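"""Synthetic stimulus protocols for the ten psychophysical experiments.

Each experiment is reconstructed as a :class:`TrialProtocol`: an ordered list
of frames, each with a duration and a set of localized inputs (center in
field units, amplitude in activation units).  Contrast is mapped to input
amplitude by a piecewise-linear calibration anchored on the printed ladder
(Michelson contrast 0.008 -> amplitude 3.8, 0.073 -> 5.4) with per-stimulus
overrides for the anchored object/probe amplitudes (low-contrast object 5.0,
high-contrast object 10.0, brief probe 4.5, constant-contrast object 4.7).

Geometry: the visual field is calibrated so the 6.6-arcmin center-to-center
object--probe distance equals 8 field units.  Stimulus locations are drawn
uniformly within +/-12.8 arcmin per dimension (a 2-D square window);
relocation displacements are the Euclidean distances between consecutive 2-D
draws, mapped onto the 1-D field with a random sign and reflected at the
window edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_core import InvalidParameterError

__all__ = [
    "StimulusFrame",
    "TrialProtocol",
    "ContrastCalibration",
    "LADDER_CONTRASTS",
    "EXP9_CONTRASTS",
    "LADDER_CAL",
    "UNITS_PER_ARCMIN",
    "contrast_to_amplitude",
    "arcmin_to_units",
    "sample_relocation",
    "RelocationWalk",
    "build_pair_trial",
    "build_stability_trial",
    "build_ladder_trial",
    "build_threshold_presentation",
]

# 6.6 arcmin center-to-center object--probe distance == 8 field units.
UNITS_PER_ARCMIN = 8.0 / 6.6

#: Location window half-width (arcmin) for the randomized relocations.
WINDOW_ARCMIN = 12.8

#: Line-segment width (arcmin); the object--probe gap is measured between
#: inner edges, so center-to-center = gap + one line width.
LINE_WIDTH_ARCMIN = 3.3

#: Printed contrast ladder used by the hysteresis experiments (nominal step
#: 0.008; the printed grid rounds to these values).
LADDER_CONTRASTS = (0.008, 0.017, 0.025, 0.033, 0.041, 0.049, 0.057, 0.065, 0.073)

#: Contrast set of the brief-frame, doubled-distance variant.
EXP9_CONTRASTS = (0.008, 0.016, 0.025, 0.032, 0.040, 0.048, 0.056, 0.064, 0.071)

#: Probe contrasts of the object--probe pair experiments.
PAIR_PROBE_CONTRASTS = EXP9_CONTRASTS

OBJECT_AMP_LOW = 5.0       # contrast 0.071/0.073 object
OBJECT_AMP_HIGH = 10.0     # contrast 0.24 object
EXP2_PROBE_AMP = 4.5       # contrast 0.008 brief probe
EXP4_OBJECT_AMP = 4.7      # contrast 0.041 constant object


@dataclass(frozen=True)
class StimulusFrame:
    """One display frame: duration plus localized inputs.

    ``inputs`` is a list of ``(center_units, amplitude)``; blank frames have
    an empty list.  ``label`` records the frame's role.
    """

    duration: float
    inputs: tuple = ()
    label: str = "object"

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidParameterError("frame duration must be > 0")
        for _, amp in self.inputs:
            if amp < 0:
                raise InvalidParameterError("input amplitude must be >= 0")


@dataclass(frozen=True)
class TrialProtocol:
    """Ordered stimulus frames encoding one experimental trial."""

    frames: tuple
    experiment_id: int
    condition: str
    end_contrast: float = float("nan")
    judged_label: str = "object"
    meta: dict = dc_field(default_factory=dict)

    @property
    def total_duration(self) -> float:
        return sum(f.duration for f in self.frames)

    def judged_frames(self) -> list[int]:
        """Indices of the frames whose stimulus the observer reports on."""
        return [
            i for i, f in enumerate(self.frames) if f.label == self.judged_label
        ]

    def to_frame(self):
        """Tidy per-frame table (frame_index, duration, label, inputs)."""
        import pandas as pd

        rows = []
        for i, f in enumerate(self.frames):
            if f.inputs:
                for c, amp in f.inputs:
                    rows.append(
                        {"frame_index": i, "duration_ms": f.duration,
                         "label": f.label, "center_units": c, "amplitude": amp}
                    )
            else:
                rows.append(
                    {"frame_index": i, "duration_ms": f.duration,
                     "label": f.label, "center_units": np.nan, "amplitude": 0.0}
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastCalibration:
    """Monotone piecewise-linear contrast -> amplitude map with overrides.

    Printed amplitude anchors take precedence over interpolation; outside the
    anchor range the map extrapolates linearly (clipped below at zero).
    """

    anchors: tuple = ((0.008, 3.8), (0.073, 5.4))
    overrides: tuple = ()

    def __post_init__(self):
        cs = [c for c, _ in self.anchors]
        amps = [a for _, a in self.anchors]
        if sorted(cs) != cs or sorted(amps) != amps:
            raise InvalidParameterError("calibration anchors must be monotone")


LADDER_CAL = ContrastCalibration()

#: Object amplitudes printed for the simulations of the pair experiments.
OBJECT_CAL = ContrastCalibration(
    overrides=((0.071, OBJECT_AMP_LOW), (0.073, OBJECT_AMP_LOW),
               (0.24, OBJECT_AMP_HIGH))
)


def contrast_to_amplitude(
    contrast: float, cal: ContrastCalibration = LADDER_CAL
) -> float:
    """Map Michelson contrast to stimulus-initiated input amplitude."""
    if contrast < 0:
        raise InvalidParameterError("contrast must be >= 0")
    for c, amp in cal.overrides:
        if abs(contrast - c) < 1e-9:
            return float(amp)
    (c0, a0), (c1, a1) = cal.anchors[0], cal.anchors[-1]
    for (cl, al), (cr, ar) in zip(cal.anchors[:-1], cal.anchors[1:]):
        if cl <= contrast <= cr:
            c0, a0, c1, a1 = cl, al, cr, ar
            break
    else:  # linear extrapolation from the nearest segment
        if contrast < cal.anchors[0][0]:
            (c0, a0), (c1, a1) = cal.anchors[0], cal.anchors[1]
        else:
            (c0, a0), (c1, a1) = cal.anchors[-2], cal.anchors[-1]
    amp = a0 + (contrast - c0) * (a1 - a0) / (c1 - c0)
    return max(0.0, float(amp))


def arcmin_to_units(d: float) -> float:
    """Convert arcmin of visual angle to field units (6.6 arcmin == 8 units)."""
    if d < 0:
        raise InvalidParameterError("distance must be >= 0")
    return d * UNITS_PER_ARCMIN


def _fold(x: float, half_width: float) -> float:
    """Reflect a coordinate into [-half_width, half_width]."""
    if half_width <= 0:
        return 0.0
    period = 4.0 * half_width
    y = (x + half_width) % period
    if y > 2.0 * half_width:
        y = period - y
    return y - half_width


class RelocationWalk:
    """Stateful 1-D mapping of the 2-D random relocation sequence.

    Internally maintains 2-D positions drawn uniformly in the square window;
    each relocation moves the 1-D field position by the Euclidean consecutive
    distance with a random sign, reflected at the window edges.
    """

    def __init__(self, rng: np.random.Generator, window_arcmin: float = WINDOW_ARCMIN):
        if window_arcmin < 0:
            raise InvalidParameterError("window must be >= 0")
        self.rng = rng
        self.window = window_arcmin
        self.half_units = arcmin_to_units(window_arcmin)
        self._xy = rng.uniform(-window_arcmin, window_arcmin, size=2)
        self.position = (
            float(rng.uniform(-self.half_units, self.half_units))
            if window_arcmin > 0
            else 0.0
        )

    def relocate(self) -> float:
        """Advance to the next random location; return the new 1-D position."""
        new_xy = self.rng.uniform(-self.window, self.window, size=2)
        dist = float(np.hypot(*(new_xy - self._xy)))
        self._xy = new_xy
        sign = 1.0 if self.rng.random() < 0.5 else -1.0
        self.position = _fold(
            self.position + sign * arcmin_to_units(dist), self.half_units
        )
        return self.position


def sample_relocation(
    rng: np.random.Generator, window_arcmin: float = WINDOW_ARCMIN
) -> float:
    """One signed relocation displacement in field units.

    Draws two independent uniform 2-D locations in the +/-window square and
    returns their Euclidean separation with a random sign.  The mean absolute
    displacement is 0.52141 x (2 x window) arcmin, converted to field units
    (doubling the window doubles the mean).
    """
    if window_arcmin == 0:
        return 0.0
    if window_arcmin < 0:
        raise InvalidParameterError("window must be >= 0")
    a = rng.uniform(-window_arcmin, window_arcmin, size=2)
    b = rng.uniform(-window_arcmin, window_arcmin, size=2)
    dist = float(np.hypot(*(a - b)))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * arcmin_to_units(dist)


# ---------------------------------------------------------------------------
# Protocol builders
# ---------------------------------------------------------------------------

#: Center-to-center object--probe distance in field units (6.6 arcmin).
PAIR_DISTANCE_UNITS = 8.0


def _trial_location(rng: np.random.Generator | None) -> float:
    if rng is None:
        return 0.0
    half = arcmin_to_units(WINDOW_ARCMIN)
    return float(rng.uniform(-half, half))


def build_pair_trial(
    experiment: int,
    condition: str,
    probe_contrast: float,
    isi_ms: float | None = None,
    object_contrast: float = 0.071,
    rng: np.random.Generator | None = None,
) -> TrialProtocol:
    """Object--probe trials of the three pair experiments.

    Experiment 1: object and probe simultaneously for 360 ms, 8 units apart.
    Experiment 2: object 360 ms, blank interstimulus interval, brief probe at
    the same location.  Experiment 3: object 360 ms, 612-ms blank, brief
    probe displaced 8 units.  The baseline condition models the marker as no
    field input (probe only).
    """
    if condition not in ("object", "baseline"):
        raise InvalidParameterError(f"invalid condition {condition!r}")
    if experiment not in (1, 2, 3):
        raise InvalidParameterError("pair trials exist for experiments 1-3")

    loc = _trial_location(rng)
    obj_amp = contrast_to_amplitude(object_contrast, OBJECT_CAL)
    meta = {"location_units": loc, "object_contrast": object_contrast}

    if experiment == 1:
        probe_amp = contrast_to_amplitude(probe_contrast, LADDER_CAL)
        inputs = [(loc, probe_amp)]
        if condition == "object":
            inputs.insert(0, (loc - PAIR_DISTANCE_UNITS, obj_amp))
        frames = (StimulusFrame(360.0, tuple(inputs), "probe"),)
    elif experiment == 2:
        if isi_ms is None or not (107 <= isi_ms <= 800):
            raise InvalidParameterError("experiment 2 requires isi in [107, 800] ms")
        probe_amp = contrast_to_amplitude(
            probe_contrast,
            ContrastCalibration(overrides=((0.008, EXP2_PROBE_AMP),)),
        )
        first = (
            StimulusFrame(360.0, ((loc, obj_amp),), "object")
            if condition == "object"
            else StimulusFrame(360.0, (), "blank")
        )
        frames = (
            first,
            StimulusFrame(float(isi_ms), (), "blank"),
            StimulusFrame(107.0, ((loc, probe_amp),), "probe"),
        )
    else:  # experiment 3
        isi = 612.0 if isi_ms is None else float(isi_ms)
        probe_amp = contrast_to_amplitude(probe_contrast, LADDER_CAL)
        first = (
            StimulusFrame(360.0, ((loc, obj_amp),), "object")
            if condition == "object"
            else StimulusFrame(360.0, (), "blank")
        )
        frames = (
            first,
            StimulusFrame(isi, (), "blank"),
            StimulusFrame(106.0, ((loc + PAIR_DISTANCE_UNITS, probe_amp),), "probe"),
        )

    return TrialProtocol(
        frames=frames,
        experiment_id=experiment,
        condition=condition,
        end_contrast=probe_contrast,
        judged_label="probe",
        meta=meta,
    )


def build_stability_trial(
    n_presentations: int,
    rng: np.random.Generator,
    contrast: float = 0.041,
) -> TrialProtocol:
    """Constant-contrast relocation trial (614 ms then 360-ms relocations)."""
    if not 2 <= n_presentations <= 9:
        raise InvalidParameterError("n_presentations must be in 2..9")
    amp = (
        EXP4_OBJECT_AMP
        if abs(contrast - 0.041) < 1e-9
        else contrast_to_amplitude(contrast)
    )
    walk = RelocationWalk(rng)
    frames = [StimulusFrame(614.0, ((walk.position, amp),), "object")]
    locations = [walk.position]
    for _ in range(n_presentations - 1):
        frames.append(StimulusFrame(360.0, ((walk.relocate(), amp),), "object"))
        locations.append(walk.position)
    return TrialProtocol(
        frames=tuple(frames),
        experiment_id=4,
        condition="constant",
        end_contrast=contrast,
        judged_label="object",
        meta={"locations_units": locations, "n_presentations": n_presentations},
    )


def build_ladder_trial(
    direction: str,
    end_contrast: float,
    rng: np.random.Generator,
    start_reps: int = 1,
    end_reps: int = 1,
    blank_ms: float = 0.0,
    frame_ms: float = 360.0,
    contrast_set: tuple = LADDER_CONTRASTS,
    experiment_id: int = 5,
) -> TrialProtocol:
    """Modified-method-of-limits trial with contrast changing per relocation.

    Ascending trials start at the lowest ladder contrast, descending at the
    highest; each step relocates the stimulus.  ``start_reps``/``end_reps``
    repeat the first/last contrast at distinct locations; ``blank_ms`` > 0
    inserts blank frames between presentations; ``frame_ms`` = 116 selects
    the brief-frame variant with a doubled relocation window.
    """
    if direction not in ("ascending", "descending"):
        raise InvalidParameterError(f"invalid direction {direction!r}")
    if start_reps not in (1, 4) or end_reps not in (1, 4):
        raise InvalidParameterError("start/end repetitions must be 1 or 4")
    grid = list(contrast_set)
    idx = [i for i, c in enumerate(grid) if abs(c - end_contrast) < 1e-9]
    if not idx:
        raise InvalidParameterError(
            f"end contrast {end_contrast} is not on the ladder"
        )
    end_idx = idx[0]
    if direction == "ascending":
        if end_idx == 0:
            raise InvalidParameterError("ascending trials must take >= 1 step")
        seq = grid[: end_idx + 1]
    else:
        if end_idx == len(grid) - 1:
            raise InvalidParameterError("descending trials must take >= 1 step")
        seq = grid[end_idx:][::-1]
    seq = [seq[0]] * (start_reps - 1) + seq + [seq[-1]] * (end_reps - 1)

    window = 2 * WINDOW_ARCMIN if frame_ms == 116.0 else WINDOW_ARCMIN
    first_ms = 116.0 if frame_ms == 116.0 else 614.0
    walk = RelocationWalk(rng, window_arcmin=window)

    frames = []
    locations = []
    for k, c in enumerate(seq):
        pos = walk.position if k == 0 else walk.relocate()
        if k > 0 and blank_ms > 0:
            frames.append(StimulusFrame(float(blank_ms), (), "blank"))
        amp = contrast_to_amplitude(c, LADDER_CAL)
        frames.append(
            StimulusFrame(
                first_ms if k == 0 else float(frame_ms),
                ((pos, amp),),
                "object",
            )
        )
        locations.append(pos)

    condition = direction
    return TrialProtocol(
        frames=tuple(frames),
        experiment_id=experiment_id,
        condition=condition,
        end_contrast=end_contrast,
        judged_label="object",
        meta={
            "contrast_sequence": seq,
            "locations_units": locations,
            "start_reps": start_reps,
            "end_reps": end_reps,
            "blank_ms": blank_ms,
            "frame_ms": frame_ms,
        },
    )


def build_threshold_presentation(
    gap_arcmin: float,
    object_contrast: float | None,
    probe_contrast: float,
    rng: np.random.Generator | None = None,
) -> TrialProtocol:
    """Single 360-ms presentation for the threshold-vs-distance staircase.

    Center-to-center separation is the inner-edge gap plus one line width
    (gap 3.3 arcmin -> 6.6 arcmin -> 8 field units).
    """
    if gap_arcmin < 0:
        raise InvalidParameterError("gap must be >= 0")
    loc = _trial_location(rng)
    probe_amp = contrast_to_amplitude(probe_contrast, LADDER_CAL)
    inputs = [(loc, probe_amp)]
    condition = "baseline"
    if object_contrast is not None:
        sep = arcmin_to_units(gap_arcmin + LINE_WIDTH_ARCMIN)
        obj_amp = contrast_to_amplitude(object_contrast, OBJECT_CAL)
        inputs.insert(0, (loc - sep, obj_amp))
        condition = "object"
    return TrialProtocol(
        frames=(StimulusFrame(360.0, tuple(inputs), "probe"),),
        experiment_id=10,
        condition=condition,
        end_contrast=probe_contrast,
        judged_label="probe",
        meta={"gap_arcmin": gap_arcmin, "object_contrast": object_contrast},
    )
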