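"""Heel-strike detection and step segmentation from pelvis acceleration.

Heel strikes are detected as the dominant local maxima of the vertical
acceleration channel — at impact the pelvis experiences a sharp vertical
transient that stands well above the smooth gait oscillation.  Consecutive
steps are the half-open intervals between successive heel strikes, and each
step is subdivided into the phase windows used by the feature extractor:

* ``initial10`` — first 10% of the step (the loading transient),
* ``double_stance`` — first 20% of the step (both feet grounded),
* ``mid_stance`` — 30%–60% of the step (single support).

All indices are 0-based and all windows half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.signal import find_peaks

from .errors import SegmentationError, WindowDegeneracyError

__all__ = [
    "PhaseFractions",
    "StepSegmentation",
    "detect_steps",
    "phase_windows",
    "default_prominence",
]

#: Minimum step-window length (samples) below which phase windows degenerate.
MIN_WINDOW_SAMPLES = 10


@dataclass(frozen=True)
class PhaseFractions:
    """Fractional phase boundaries within a step window.

    Defaults follow typical gait-cycle proportions: double stance occupies
    roughly the first fifth of a step, and mid-stance the 30–60% band.
    """

    initial: float = 0.10
    double_stance: float = 0.20
    mid_stance_start: float = 0.30
    mid_stance_stop: float = 0.60

    def __post_init__(self) -> None:
        if not (0 < self.initial <= 1 and 0 < self.double_stance <= 1):
            raise ValueError("phase fractions must lie in (0, 1]")
        if not (0 <= self.mid_stance_start < self.mid_stance_stop <= 1):
            raise ValueError("mid-stance fractions must satisfy 0 <= start < stop <= 1")


@dataclass
class StepSegmentation:
    """Detected heel strikes and derived per-step windows for one trial.

    ``n_steps = len(heel_strike_indices) - 1``: the last heel strike closes
    the final step window but does not open a new one.  ``side_labels[i]``
    names the stance side of step ``i`` (the foot that just struck).
    """

    heel_strike_indices: np.ndarray
    side_labels: list[str]
    sampling_rate: float
    fractions: PhaseFractions = field(default_factory=PhaseFractions)

    def __post_init__(self) -> None:
        self.heel_strike_indices = np.asarray(self.heel_strike_indices, dtype=np.int64)
        if np.any(np.diff(self.heel_strike_indices) <= 0):
            raise SegmentationError("heel-strike indices must be strictly increasing")
        if len(self.side_labels) != self.n_steps:
            raise SegmentationError(
                f"expected {self.n_steps} side labels, got {len(self.side_labels)}"
            )

    @property
    def n_steps(self) -> int:
        return max(len(self.heel_strike_indices) - 1, 0)

    @property
    def step_windows(self) -> list[tuple[int, int]]:
        hs = self.heel_strike_indices
        return [(int(hs[i]), int(hs[i + 1])) for i in range(self.n_steps)]

    def right_heel_strikes(self) -> np.ndarray:
        """Heel-strike indices that open a right-side step."""
        return np.array(
            [self.heel_strike_indices[i] for i, s in enumerate(self.side_labels) if s == "right"],
            dtype=np.int64,
        )

    def to_dict(self) -> dict:
        return {
            "heel_strike_indices": self.heel_strike_indices.tolist(),
            "side_labels": list(self.side_labels),
            "sampling_rate": self.sampling_rate,
            "fractions": {
                "initial": self.fractions.initial,
                "double_stance": self.fractions.double_stance,
                "mid_stance_start": self.fractions.mid_stance_start,
                "mid_stance_stop": self.fractions.mid_stance_stop,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepSegmentation":
        return cls(
            heel_strike_indices=np.asarray(d["heel_strike_indices"], dtype=np.int64),
            side_labels=list(d["side_labels"]),
            sampling_rate=float(d["sampling_rate"]),
            fractions=PhaseFractions(**d.get("fractions", {})),
        )


def default_prominence(acc_vt: np.ndarray) -> float:
    """Scale-aware peak-prominence threshold.

    Half the spread between the 95th percentile and the median of the
    vertical channel: large enough to reject the baseline gait oscillation,
    small enough to keep every impact transient, and invariant in *relative*
    terms under rescaling of the signal.
    """
    acc_vt = np.asarray(acc_vt, dtype=float)
    return 0.5 * float(np.percentile(acc_vt, 95) - np.median(acc_vt))


def detect_steps(
    signal,
    min_step_time: float = 0.4,
    min_peak_prominence: float | None = None,
    fractions: PhaseFractions | None = None,
) -> StepSegmentation:
    """Detect heel strikes on the vertical channel and label step sides.

    Parameters
    ----------
    signal : TrialSignal
        Trial with ``acc_vt`` (vertical) and ``acc_ml`` (lateral) channels.
    min_step_time : float
        Minimum time between consecutive heel strikes, seconds.
    min_peak_prominence : float, optional
        Required peak prominence in m/s^2.  Default: :func:`default_prominence`.

    Returns
    -------
    StepSegmentation
        Strictly increasing heel-strike indices with alternating side labels.
        The first step's side is read off the sign of its mean lateral
        acceleration (positive = rightward by convention).

    Raises
    ------
    SegmentationError
        If fewer than two peaks survive the thresholds.
    """
    fs = float(signal.sampling_rate)
    acc_vt = np.asarray(signal.acc_vt, dtype=float)
    if min_step_time <= 0:
        raise ValueError("min_step_time must be positive")
    if acc_vt.size < 2 * fs:
        raise SegmentationError(
            f"trial {getattr(signal, 'subject_id', '?')}: signal shorter than 2 s"
        )
    prominence = (
        default_prominence(acc_vt) if min_peak_prominence is None else float(min_peak_prominence)
    )
    distance = max(int(round(min_step_time * fs)), 1)
    peaks, _ = find_peaks(acc_vt, distance=distance, prominence=max(prominence, 1e-12))
    if peaks.size < 2:
        raise SegmentationError(
            f"trial {getattr(signal, 'subject_id', '?')} "
            f"(condition {getattr(signal, 'condition', '?')}): "
            f"found {peaks.size} heel-strike peak(s); need at least 2"
        )

    acc_ml = np.asarray(signal.acc_ml, dtype=float)
    first_mean_ml = float(np.mean(acc_ml[peaks[0] : peaks[1]]))
    first_side = "right" if first_mean_ml >= 0 else "left"
    other = {"right": "left", "left": "right"}
    labels: list[str] = []
    side = first_side
    for _ in range(peaks.size - 1):
        labels.append(side)
        side = other[side]

    return StepSegmentation(
        heel_strike_indices=peaks,
        side_labels=labels,
        sampling_rate=fs,
        fractions=fractions or PhaseFractions(),
    )


def phase_windows(
    segmentation: StepSegmentation, step_index: int
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Half-open ``(initial10, double_stance, mid_stance)`` windows of a step.

    Window boundaries are ``floor(fraction * length)`` offsets from the step
    start, so a 100-sample step yields initial10 = [0, 10), double stance =
    [0, 20) and mid-stance = [30, 60) relative to the step.

    Raises
    ------
    WindowDegeneracyError
        If the step spans fewer than ``MIN_WINDOW_SAMPLES`` samples.
    IndexError
        If ``step_index`` is out of range.
    """
    if not (0 <= step_index < segmentation.n_steps):
        raise IndexError(f"step_index {step_index} out of range [0, {segmentation.n_steps})")
    start, stop = segmentation.step_windows[step_index]
    length = stop - start
    if length < MIN_WINDOW_SAMPLES:
        raise WindowDegeneracyError(
            f"step {step_index} spans {length} samples (< {MIN_WINDOW_SAMPLES}); "
            "phase windows are degenerate"
        )
    f = segmentation.fractions
    initial10 = (start, start + max(int(length * f.initial), 1))
    double_stance = (start, start + max(int(length * f.double_stance), 1))
    mid_stance = (
        start + int(length * f.mid_stance_start),
        start + int(length * f.mid_stance_stop),
    )
    if mid_stance[1] <= mid_stance[0]:
        raise WindowDegeneracyError(f"step {step_index}: empty mid-stance window")
    return initial10, double_stance, mid_stance
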