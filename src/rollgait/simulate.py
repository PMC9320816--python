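"""Synthetic ship-roll walking trials with planted ground truth.

The generator emulates 2-minute treadmill walking under lateral platform
roll at 0–20 degrees, producing tri-axial pelvis acceleration at 100 Hz
together with the gold-standard kinematics a motion-capture system would
provide (mediolateral COM trajectory, COM velocity, and the lateral
base-of-support boundary of every right foot placement).

Waveform model (per trial):

* **vertical** — gravity offset + a cosine at step frequency whose crests
  are phase-locked to heel strikes + a Gaussian impact transient at every
  heel strike whose amplitude is more than twice the oscillation amplitude,
  so the highest-peak step detector is well posed;
* **lateral** — one half-sine "sway hump" per step, signed by stance side
  (positive = rightward), whose per-step amplitude jitter grows linearly
  with roll amplitude, plus an independently jittered late-swing bump and a
  slow sinusoid at the platform roll period whose amplitude is proportional
  to roll;
* **anterior-posterior** — a sinusoid at step frequency plus a second
  harmonic and a heel-strike transient, each with its own subject-specific
  amplitude (so whole-step, double-stance and mid-stance AP features carry
  distinct information).

Ground truth is planted end to end: heel-strike indices and sides; the two
stability outcomes as an exact linear function of three designated gait
features (extracted from the noise-free signal) plus optional noise; and COM
/ BOS kinematics constructed so that the stability module recovers the
planted outcomes to floating-point precision.

Randomness is fanned out from a single seed.  Subject-level parameters and
all per-step draws depend on (seed, subject) only — conditions of one
subject share the same draws, so the effect of roll amplitude is a pure
amplitude scaling (common random numbers) and lateral-sway variability is
monotone in roll by construction.  Outcome noise is drawn per
(seed, subject, condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .events import StepSegmentation
from .features import extract_trial_vector
from .registry import OUTCOME_NAMES, validate_feature_names
from .stability import GRAVITY

__all__ = [
    "SimulationConfig",
    "TrialSignal",
    "GroundTruth",
    "simulate_trial",
    "simulate_cohort",
    "DEFAULT_PLANTED_FEATURES",
    "DEFAULT_INTERCEPTS",
]

# Default planted linear models for the two outcomes.  The three features
# tap independent sources of between-trial variation: aST follows subject
# cadence, vLM follows roll-driven sway variability, aAM follows the
# subject's anterior-posterior effort.  Intercepts place the outcomes near
# typical rolling-platform magnitudes (peak excursion ~0.36 m, MOS
# variability ~0.02 m).
DEFAULT_PLANTED_FEATURES: Mapping[str, Mapping[str, float]] = {
    "peak_com_excursion": {"aST": 1.00, "vLM": 0.45, "aAM": 0.35},
    "mos_variability": {"aST": 0.080, "vLM": 0.020, "aAM": 0.030},
}
DEFAULT_INTERCEPTS: Mapping[str, float] = {
    "peak_com_excursion": -0.628,
    "mos_variability": -0.0539,
}
DEFAULT_OUTCOME_NOISE_SD: Mapping[str, float] = {
    "peak_com_excursion": 0.02,
    "mos_variability": 0.0012,
}

_ROLL_PERIOD_S = 8.0  # platform roll period
_ROLL_ACC_GAIN = 0.05  # lateral acceleration amplitude per degree of roll, m/s^2
_ROLL_COM_GAIN = 0.004  # lateral COM amplitude per degree of roll, m (pre-scaling)
_SWAY_JITTER_GAIN = 0.8  # per-step sway amplitude jitter at 20 degrees
_IMPACT_SIGMA_S = 0.03  # impact transient width
_OUTCOME_FLOORS = {"peak_com_excursion": 0.02, "mos_variability": 1e-5}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Cadence and leg length are drawn per subject from uniform ranges
    (1.6–2.0 steps/s, 0.80–1.00 m) — conventional self-selected treadmill
    walking values.  ``planted_features`` maps each outcome to the sparse
    linear model generating it from noise-free extracted features.
    """

    n_subjects: int = 30
    conditions: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    trial_duration: float = 120.0
    sampling_rate: float = 100.0
    cadence_range: tuple[float, float] = (1.6, 2.0)
    leg_length_range: tuple[float, float] = (0.8, 1.0)
    noise_sd: float = 0.3
    planted_features: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PLANTED_FEATURES.items()}
    )
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS)
    )
    outcome_noise_sd: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_NOISE_SD)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be positive")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.conditions:
            raise ConfigError("conditions must be non-empty")
        for c in self.conditions:
            if not (0.0 <= float(c) <= 20.0):
                raise ConfigError(f"roll amplitude {c} outside [0, 20] degrees")
        lo, hi = self.cadence_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid cadence_range")
        lo, hi = self.leg_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid leg_length_range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for outcome, coefs in self.planted_features.items():
            if outcome not in OUTCOME_NAMES:
                raise ConfigError(f"unknown outcome {outcome!r}")
            try:
                validate_feature_names(coefs)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def outcome_noise(self, outcome: str) -> float:
        if isinstance(self.outcome_noise_sd, Mapping):
            return float(self.outcome_noise_sd.get(outcome, 0.0))
        return float(self.outcome_noise_sd)


@dataclass
class TrialSignal:
    """One trial's pelvis acceleration plus optional gold-standard kinematics.

    Acceleration series are in m/s^2 (vertical includes the gravity offset);
    COM series in m and m/s; ``right_bos_boundary`` holds one lateral
    boundary position per right heel strike.  ``true_heel_strikes`` /
    ``true_side_labels`` are simulation-only plant markers.
    """

    subject_id: str
    condition: float
    sampling_rate: float
    acc_ml: np.ndarray
    acc_vt: np.ndarray
    acc_ap: np.ndarray
    leg_length: float
    com_ml: np.ndarray | None = None
    com_ml_velocity: np.ndarray | None = None
    right_bos_boundary: np.ndarray | None = None
    true_heel_strikes: np.ndarray | None = None
    true_side_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.leg_length <= 0:
            raise ConfigError("leg_length must be positive")
        n = len(self.acc_ml)
        if not (len(self.acc_vt) == len(self.acc_ap) == n):
            raise ConfigError("acceleration channels have unequal lengths")
        if n < 2 * self.sampling_rate:
            raise ConfigError("trial must span at least 2 seconds")

    @property
    def n_samples(self) -> int:
        return len(self.acc_ml)


@dataclass
class GroundTruth:
    """Planted truth for one simulated trial."""

    heel_strike_indices: np.ndarray
    side_labels: list[str]
    peak_com_excursion: float
    mos_values: np.ndarray
    mos_variability: float
    true_outcome_coefficients: dict
    clean_features: dict[str, float]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.heel_strike_indices) <= 0):
            raise ConfigError("planted heel strikes must be strictly increasing")
        if self.mos_variability < 0 or self.peak_com_excursion < 0:
            raise ConfigError("planted outcomes must be non-negative")


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + subject_index]))


def _trial_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    # Condition-independent: all conditions of a subject share these draws.
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + subject_index, 77]))


def _outcome_rng(config, subject_index: int, condition_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 1000 + subject_index, condition_index, 7])
    )


def _draw_subject_params(config: SimulationConfig, subject_index: int) -> dict[str, float]:
    rng = _subject_rng(config, subject_index)
    return {
        "cadence": rng.uniform(*config.cadence_range),
        "leg_length": rng.uniform(*config.leg_length_range),
        "vt_osc_amp": rng.uniform(0.8, 1.2),
        "impact_amp": rng.uniform(2.5, 3.5),
        "ap_amp": rng.uniform(0.8, 1.5),
        "ap_harmonic_amp": rng.uniform(0.2, 0.6),
        "ap_impact_amp": rng.uniform(0.5, 1.2),
        "sway_amp": rng.uniform(0.9, 1.1),
        "bump_amp": rng.uniform(0.25, 0.45),
        "com_stride_amp": rng.uniform(0.010, 0.020),
        "mos_mean": rng.uniform(0.04, 0.08),
    }


def _planted_strikes(config: SimulationConfig, cadence: float) -> np.ndarray:
    """Planted heel-strike sample indices; count = round(cadence * duration)."""
    fs, T = config.sampling_rate, config.trial_duration
    n_hs = int(np.floor(cadence * T - 0.5)) + 1
    times = (np.arange(n_hs) + 0.5) / cadence  # half-step offset from trial start
    idx = np.round(times * fs).astype(np.int64)
    # keep the full impact transient inside the trial: an edge-truncated
    # impact has reduced peak prominence and would not be detectable
    margin = int(round(4 * _IMPACT_SIGMA_S * fs)) + 2
    return idx[idx < int(round(T * fs)) - margin]


def simulate_trial(
    config: SimulationConfig, subject_id: str | int, condition: float
) -> tuple[TrialSignal, GroundTruth]:
    """Simulate one subject x roll-condition trial.

    Returns the (noisy) trial signal with gold-standard kinematics attached,
    and the planted ground truth.  Identical ``(config, subject, condition)``
    yields bit-identical output.
    """
    ids = config.subject_ids()
    if isinstance(subject_id, int):
        subject_index, subject_id = subject_id, ids[subject_id]
    else:
        try:
            subject_index = ids.index(subject_id)
        except ValueError:
            raise ConfigError(f"unknown subject_id {subject_id!r}") from None
    condition = float(condition)
    if condition not in [float(c) for c in config.conditions]:
        raise ConfigError(
            f"condition {condition} not in configured conditions {config.conditions}"
        )
    condition_index = [float(c) for c in config.conditions].index(condition)

    p = _draw_subject_params(config, subject_index)
    fs = config.sampling_rate
    n = int(round(config.trial_duration * fs))
    t = np.arange(n) / fs
    cadence = p["cadence"]

    hs = _planted_strikes(config, cadence)
    n_steps = len(hs) - 1
    sides = ["right" if k % 2 == 0 else "left" for k in range(n_steps)]
    t0 = hs[0] / fs

    rng_t = _trial_rng(config, subject_index)
    impact_jitter = rng_t.standard_normal(len(hs))
    sway_jitter = rng_t.standard_normal(n_steps)
    bump_jitter = rng_t.standard_normal(n_steps)
    ap_impact_jitter = rng_t.standard_normal(len(hs))
    n_right = sum(1 for s in sides if s == "right")
    mos_z = rng_t.standard_normal(n_right)
    noise = rng_t.standard_normal((3, n))

    # --- vertical: gravity + step-locked cosine + impact transients -------
    acc_vt = GRAVITY + p["vt_osc_amp"] * np.cos(2 * np.pi * cadence * (t - t0))
    sigma = _IMPACT_SIGMA_S
    half = int(round(4 * sigma * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (kernel_t / sigma) ** 2)
    for k, idx in enumerate(hs):
        amp = p["impact_amp"] * (1.0 + 0.08 * impact_jitter[k])
        lo, hi = max(idx - half, 0), min(idx + half + 1, n)
        acc_vt[lo:hi] += amp * kernel[(lo - (idx - half)) : (hi - (idx - half))]

    # --- lateral: signed per-step sway humps + late-swing bumps + roll ----
    acc_ml = np.zeros(n)
    roll_scale = condition / 20.0
    for k in range(n_steps):
        lo, hi = hs[k], hs[k + 1]
        amp = p["sway_amp"] * (1.0 + _SWAY_JITTER_GAIN * roll_scale * abs(sway_jitter[k]))
        bump = p["bump_amp"] * (1.0 + _SWAY_JITTER_GAIN * roll_scale * abs(bump_jitter[k]))
        sign = 1.0 if sides[k] == "right" else -1.0
        phase = (t[lo:hi] - t[lo]) / ((hi - lo) / fs)  # in [0, 1)
        acc_ml[lo:hi] = sign * (
            amp * np.sin(np.pi * phase)
            + bump * np.exp(-0.5 * ((phase - 0.75) / 0.12) ** 2)
        )
    acc_ml += _ROLL_ACC_GAIN * condition * np.sin(2 * np.pi * t / _ROLL_PERIOD_S)

    # --- anterior-posterior: fundamental + harmonic + strike transient ----
    acc_ap = p["ap_amp"] * np.sin(2 * np.pi * cadence * (t - t0) + 1.0)
    acc_ap += p["ap_harmonic_amp"] * np.sin(4 * np.pi * cadence * (t - t0) + 0.5)
    for k, idx in enumerate(hs):
        amp = p["ap_impact_amp"] * (1.0 + 0.08 * ap_impact_jitter[k])
        lo, hi = max(idx - half, 0), min(idx + half + 1, n)
        acc_ap[lo:hi] += amp * kernel[(lo - (idx - half)) : (hi - (idx - half))]

    clean = TrialSignal(
        subject_id=subject_id,
        condition=condition,
        sampling_rate=fs,
        acc_ml=acc_ml.copy(),
        acc_vt=acc_vt.copy(),
        acc_ap=acc_ap.copy(),
        leg_length=p["leg_length"],
        true_heel_strikes=hs.copy(),
        true_side_labels=list(sides),
    )

    # --- plant outcomes: exact linear model on noise-free features --------
    planted_seg = StepSegmentation(
        heel_strike_indices=hs, side_labels=list(sides), sampling_rate=fs
    )
    clean_features = extract_trial_vector(clean, planted_seg)
    rng_o = _outcome_rng(config, subject_index, condition_index)
    truth_models: dict[str, dict] = {}
    planted_outcomes: dict[str, float] = {}
    for outcome in OUTCOME_NAMES:
        coefs = dict(config.planted_features.get(outcome, {}))
        intercept = float(config.intercepts.get(outcome, 0.0))
        value = intercept + sum(c * clean_features[f] for f, c in coefs.items())
        value += rng_o.normal(0.0, config.outcome_noise(outcome))
        floor = _OUTCOME_FLOORS[outcome]
        if value < floor:
            warnings.warn(
                f"{subject_id}/cond={condition}: planted {outcome} {value:.4g} "
                f"clipped to {floor}; consider smaller outcome noise",
                stacklevel=2,
            )
            value = floor
        planted_outcomes[outcome] = value
        truth_models[outcome] = {"intercept": intercept, "coefficients": coefs}

    # --- kinematics realizing the planted outcomes exactly ----------------
    f_stride = cadence / 2.0
    raw_com = p["com_stride_amp"] * np.sin(2 * np.pi * f_stride * (t - t0) + 0.3)
    raw_com += _ROLL_COM_GAIN * condition * np.sin(2 * np.pi * t / _ROLL_PERIOD_S + 0.8)
    raw_vel = p["com_stride_amp"] * 2 * np.pi * f_stride * np.cos(
        2 * np.pi * f_stride * (t - t0) + 0.3
    )
    raw_vel += (
        _ROLL_COM_GAIN
        * condition
        * (2 * np.pi / _ROLL_PERIOD_S)
        * np.cos(2 * np.pi * t / _ROLL_PERIOD_S + 0.8)
    )
    dev = raw_com - raw_com.mean()
    scale = planted_outcomes["peak_com_excursion"] / np.max(np.abs(dev))
    com_ml = scale * dev
    com_vel = scale * raw_vel

    right_idx = hs[:-1][np.asarray(sides) == "right"]
    if n_right >= 2 and np.std(mos_z[: len(right_idx)], ddof=1) > 0:
        z = mos_z[: len(right_idx)]
        mos_values = p["mos_mean"] + planted_outcomes["mos_variability"] * (
            (z - z.mean()) / np.std(z, ddof=1)
        )
        realized_mos_sd = planted_outcomes["mos_variability"]
    else:  # degenerate tiny trial: constant margins
        mos_values = np.full(len(right_idx), p["mos_mean"])
        realized_mos_sd = 0.0
    omega0 = np.sqrt(GRAVITY / p["leg_length"])
    xcom_at_rhs = com_ml[right_idx] + com_vel[right_idx] / omega0
    boundary = xcom_at_rhs + mos_values

    signal = TrialSignal(
        subject_id=subject_id,
        condition=condition,
        sampling_rate=fs,
        acc_ml=acc_ml + config.noise_sd * noise[0],
        acc_vt=acc_vt + config.noise_sd * noise[1],
        acc_ap=acc_ap + config.noise_sd * noise[2],
        leg_length=p["leg_length"],
        com_ml=com_ml,
        com_ml_velocity=com_vel,
        right_bos_boundary=boundary,
        true_heel_strikes=hs,
        true_side_labels=list(sides),
    )
    truth = GroundTruth(
        heel_strike_indices=hs,
        side_labels=list(sides),
        peak_com_excursion=planted_outcomes["peak_com_excursion"],
        mos_values=np.asarray(mos_values, dtype=float),
        mos_variability=realized_mos_sd,
        true_outcome_coefficients=truth_models,
        clean_features=clean_features,
    )
    return signal, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[TrialSignal], list[GroundTruth]]:
    """One trial per subject x condition; n_subjects must be >= 2."""
    if config.n_subjects < 2:
        raise ConfigError("simulate_cohort requires n_subjects >= 2")
    signals: list[TrialSignal] = []
    truths: list[GroundTruth] = []
    for i, sid in enumerate(config.subject_ids()):
        for cond in config.conditions:
            sig, gt = simulate_trial(config, sid, float(cond))
            signals.append(sig)
            truths.append(gt)
    return signals, truths
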