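"""Per-step gait features and their trial-level aggregation.

Twenty base features are computed for every step from the tri-axial pelvis
acceleration (see :mod:`rollgait.registry` for the list).  "Vector magnitude"
features are means of the instantaneous resultant ``sqrt(ml^2 + vt^2 + ap^2)``
(or of a single axis' absolute value) over a phase window; heel-strike
magnitudes are the signed axis values at the heel-strike sample; the ``*HS``
features are the within-window standard deviation of one axis over the
initial 10% of the step; ``ST`` is the step time in seconds.

Trial-level aggregation maps each base feature X to

* ``aX`` — mean across all steps,
* ``sX`` — symmetry index ``|mean_left - mean_right| / |0.5 (mean_left + mean_right)|``
  (0 when the denominator is 0),
* ``vX`` — standard deviation across all steps (sample SD, ddof=1),

yielding the 60-entry feature vector.  Feature tables are centered per column
across trials; outcomes are attached uncentered.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientStepsError, RollgaitError
from .events import StepSegmentation, detect_steps, phase_windows
from .registry import BASE_FEATURES, FEATURE_NAMES, METADATA_COLUMNS, OUTCOME_NAMES

__all__ = [
    "step_features",
    "trial_features",
    "build_feature_table",
    "extract_trial_vector",
    "center_feature_table",
]


def _window_magnitude(ml, vt, ap, mode: str) -> float:
    mag = np.sqrt(ml * ml + vt * vt + ap * ap)
    return float(np.sqrt(np.mean(mag * mag))) if mode == "rms" else float(np.mean(mag))


def _axis_magnitude(x, mode: str) -> float:
    return float(np.sqrt(np.mean(x * x))) if mode == "rms" else float(np.mean(np.abs(x)))


def step_features(
    signal,
    segmentation: StepSegmentation,
    step_index: int,
    magnitude: str = "mean",
) -> dict[str, float]:
    """The 20 base features of one step.

    ``magnitude`` selects how windowed magnitudes are summarised: ``"mean"``
    (default) or ``"rms"``.  Within-window SDs (LHS/VHS/AHS) are population
    SDs (ddof=0) so they remain defined for very short initial windows.
    """
    if magnitude not in ("mean", "rms"):
        raise ValueError("magnitude must be 'mean' or 'rms'")
    (i0, i1), (d0, d1), (m0, m1) = phase_windows(segmentation, step_index)
    start, stop = segmentation.step_windows[step_index]
    fs = segmentation.sampling_rate

    ml = np.asarray(signal.acc_ml, dtype=float)
    vt = np.asarray(signal.acc_vt, dtype=float)
    ap = np.asarray(signal.acc_ap, dtype=float)

    def win(a, lo, hi):
        return a[lo:hi]

    out = {
        "M": _window_magnitude(win(ml, start, stop), win(vt, start, stop), win(ap, start, stop), magnitude),
        "M10": _window_magnitude(win(ml, i0, i1), win(vt, i0, i1), win(ap, i0, i1), magnitude),
        "LM": _axis_magnitude(win(ml, start, stop), magnitude),
        "VM": _axis_magnitude(win(vt, start, stop), magnitude),
        "AM": _axis_magnitude(win(ap, start, stop), magnitude),
        "MD": _window_magnitude(win(ml, d0, d1), win(vt, d0, d1), win(ap, d0, d1), magnitude),
        "LMD": _axis_magnitude(win(ml, d0, d1), magnitude),
        "VMD": _axis_magnitude(win(vt, d0, d1), magnitude),
        "AMD": _axis_magnitude(win(ap, d0, d1), magnitude),
        "M30": _window_magnitude(win(ml, m0, m1), win(vt, m0, m1), win(ap, m0, m1), magnitude),
        "LM30": _axis_magnitude(win(ml, m0, m1), magnitude),
        "VM30": _axis_magnitude(win(vt, m0, m1), magnitude),
        "AM30": _axis_magnitude(win(ap, m0, m1), magnitude),
        "LHM": float(ml[start]),
        "LHS": float(np.std(win(ml, i0, i1))),
        "VHM": float(vt[start]),
        "VHS": float(np.std(win(vt, i0, i1))),
        "AHM": float(ap[start]),
        "AHS": float(np.std(win(ap, i0, i1))),
        "ST": (stop - start) / fs,
    }
    return out


def _symmetry_index(mean_left: float, mean_right: float) -> float:
    denom = abs(0.5 * (mean_left + mean_right))
    if denom == 0.0:
        return 0.0
    return abs(mean_left - mean_right) / denom


def trial_features(
    per_step: Sequence[Mapping[str, float]],
    side_labels: Sequence[str],
    variability: str = "sd",
) -> dict[str, float]:
    """Aggregate per-step base features into the 60 trial-level features.

    Requires at least two steps on each side so that symmetry and
    variability are well defined.  ``variability`` is ``"sd"`` (default) or
    ``"cv"`` (SD divided by |mean|).
    """
    if variability not in ("sd", "cv"):
        raise ValueError("variability must be 'sd' or 'cv'")
    if len(per_step) != len(side_labels):
        raise ValueError("per_step and side_labels lengths differ")
    sides = np.asarray(side_labels)
    n_left = int(np.sum(sides == "left"))
    n_right = int(np.sum(sides == "right"))
    if n_left < 2 or n_right < 2:
        raise InsufficientStepsError(
            f"need >= 2 steps per side, got left={n_left}, right={n_right}"
        )

    values = {base: np.array([s[base] for s in per_step], dtype=float) for base in BASE_FEATURES}
    left = sides == "left"
    right = sides == "right"

    out: dict[str, float] = {}
    for base, x in values.items():
        mean_all = float(np.mean(x))
        sd_all = float(np.std(x, ddof=1))
        out[f"a{base}"] = mean_all
        out[f"s{base}"] = _symmetry_index(float(np.mean(x[left])), float(np.mean(x[right])))
        if variability == "cv":
            out[f"v{base}"] = sd_all / abs(mean_all) if mean_all != 0 else 0.0
        else:
            out[f"v{base}"] = sd_all
    return {name: out[name] for name in FEATURE_NAMES}


def extract_trial_vector(
    signal,
    segmentation: StepSegmentation | None = None,
    magnitude: str = "mean",
    variability: str = "sd",
    min_step_time: float = 0.4,
    min_peak_prominence: float | None = None,
) -> dict[str, float]:
    """Detect steps (unless a segmentation is supplied) and return the
    60-entry uncentered feature vector of one trial."""
    if segmentation is None:
        segmentation = detect_steps(
            signal, min_step_time=min_step_time, min_peak_prominence=min_peak_prominence
        )
    per_step = [
        step_features(signal, segmentation, i, magnitude=magnitude)
        for i in range(segmentation.n_steps)
    ]
    return trial_features(per_step, segmentation.side_labels, variability=variability)


def center_feature_table(table: pd.DataFrame, means: pd.Series | None = None) -> pd.DataFrame:
    """Center the 60 feature columns; outcomes and metadata untouched.

    ``means`` supplies pre-computed column means (e.g. training-set means for
    leakage-free test-set centering); by default the table's own means.
    """
    table = table.copy()
    cols = list(FEATURE_NAMES)
    if means is None:
        means = table[cols].mean()
    table[cols] = table[cols] - means[cols]
    return table


def build_feature_table(
    trials: Iterable,
    magnitude: str = "mean",
    variability: str = "sd",
    min_step_time: float = 0.4,
    min_peak_prominence: float | None = None,
    center: bool = True,
    compute_outcomes: bool = True,
) -> pd.DataFrame:
    """Extract the 60-feature table (one row per trial) from a cohort.

    Each trial is segmented with the peak detector, its per-step features
    aggregated, and — when the trial carries gold-standard kinematics and
    ``compute_outcomes`` is true — the two stability outcomes are attached
    uncentered.  Feature columns are centered across trials unless
    ``center=False``.

    Raises
    ------
    RollgaitError
        Listing every trial whose extraction failed.
    """
    from .stability import outcomes as stability_outcomes  # local: avoid cycle

    rows: list[dict] = []
    failures: list[str] = []
    for trial in trials:
        label = f"{trial.subject_id}/cond={trial.condition}"
        try:
            seg = detect_steps(
                trial, min_step_time=min_step_time, min_peak_prominence=min_peak_prominence
            )
            row: dict = {"subject": trial.subject_id, "condition": trial.condition}
            row.update(
                extract_trial_vector(trial, seg, magnitude=magnitude, variability=variability)
            )
            if compute_outcomes:
                res = stability_outcomes(trial, seg)
                row["peak_com_excursion"] = res.peak_com_excursion
                row["mos_variability"] = res.mos_variability
            rows.append(row)
        except RollgaitError as exc:
            failures.append(f"{label}: {exc}")
    if failures:
        raise RollgaitError(
            "feature extraction failed for trial(s):\n  " + "\n  ".join(failures)
        )
    columns = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    if compute_outcomes:
        columns += list(OUTCOME_NAMES)
    table = pd.DataFrame(rows, columns=columns)
    if center:
        table = center_feature_table(table)
    return table
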