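import numpy as np
import pytest

from rollgait.errors import InsufficientStepsError
from rollgait.events import StepSegmentation
from rollgait.features import build_feature_table, step_features, trial_features
from rollgait.registry import BASE_FEATURES, FEATURE_NAMES
from rollgait.simulate import TrialSignal


def _signal(ml, vt, ap, fs=100.0):
    return TrialSignal(
        subject_id="T",
        condition=0.0,
        sampling_rate=fs,
        acc_ml=np.asarray(ml, dtype=float),
        acc_vt=np.asarray(vt, dtype=float),
        acc_ap=np.asarray(ap, dtype=float),
        leg_length=0.9,
    )


def _segmentation(hs, fs=100.0):
    n_steps = len(hs) - 1
    sides = ["right" if i % 2 == 0 else "left" for i in range(n_steps)]
    return StepSegmentation(heel_strike_indices=np.asarray(hs), side_labels=sides, sampling_rate=fs)


def test_constant_acceleration_gives_unit_lateral_magnitude():
    n = 400
    sig = _signal(np.ones(n), np.zeros(n), np.zeros(n))
    seg = _segmentation([0, 100, 200, 300])
    f = step_features(sig, seg, 0)
    assert f["LM"] == pytest.approx(1.0)
    assert f["VM"] == pytest.approx(0.0)
    assert f["AM"] == pytest.approx(0.0)
    assert f["M"] == pytest.approx(1.0)
    assert f["LHM"] == pytest.approx(1.0)
    assert f["LHS"] == pytest.approx(0.0)


def test_step_time_from_strike_spacing():
    n = 400
    sig = _signal(np.zeros(n), np.zeros(n), np.zeros(n))
    seg = _segmentation([0, 100, 200])
    assert step_features(sig, seg, 0)["ST"] == pytest.approx(1.0)


def test_initial_window_sd_matches_arithmetic_sequence_formula():
    # ramp of slope s: population SD of k consecutive values = s*sqrt((k^2-1)/12)
    n, slope = 400, 0.05
    sig = _signal(slope * np.arange(n), np.zeros(n), np.zeros(n))
    seg = _segmentation([0, 100, 200])
    k = 10  # initial 10% of a 100-sample step
    expected = slope * np.sqrt((k**2 - 1) / 12.0)
    assert step_features(sig, seg, 0)["LHS"] == pytest.approx(expected, rel=1e-12)


def _steps(values_by_side):
    """Build identical per-step dicts with one distinguishing feature value."""
    steps, sides = [], []
    for side, vals in values_by_side.items():
        for v in vals:
            steps.append({b: v for b in BASE_FEATURES})
            sides.append(side)
    return steps, sides


def test_identical_steps_have_zero_variability_and_symmetry():
    steps, sides = _steps({"left": [2.0, 2.0], "right": [2.0, 2.0]})
    out = trial_features(steps, sides)
    assert all(out[f"v{b}"] == 0.0 for b in BASE_FEATURES)
    assert all(out[f"s{b}"] == 0.0 for b in BASE_FEATURES)
    assert all(out[f"a{b}"] == 2.0 for b in BASE_FEATURES)


def test_symmetry_index_formula():
    steps, sides = _steps({"left": [1.2, 1.2], "right": [0.8, 0.8]})
    out = trial_features(steps, sides)
    # |1.2 - 0.8| / (0.5 * (1.2 + 0.8)) = 0.4
    assert all(out[f"s{b}"] == pytest.approx(0.4) for b in BASE_FEATURES)


def test_symmetry_zero_when_sides_balance():
    steps, sides = _steps({"left": [1.0, 3.0], "right": [2.0, 2.0]})
    out = trial_features(steps, sides)
    assert all(out[f"s{b}"] == pytest.approx(0.0) for b in BASE_FEATURES)


def test_aggregates_invariant_to_step_order_and_side_swap():
    steps, sides = _steps({"left": [1.0, 2.0], "right": [3.0, 4.0]})
    out = trial_features(steps, sides)
    perm = [2, 0, 3, 1]
    out_perm = trial_features([steps[i] for i in perm], [sides[i] for i in perm])
    swap = {"left": "right", "right": "left"}
    out_swap = trial_features(steps, [swap[s] for s in sides])
    for b in BASE_FEATURES:
        assert out[f"a{b}"] == pytest.approx(out_perm[f"a{b}"])
        assert out[f"v{b}"] == pytest.approx(out_perm[f"v{b}"])
        assert out[f"v{b}"] == pytest.approx(out_swap[f"v{b}"])
        assert out[f"s{b}"] == pytest.approx(out_swap[f"s{b}"])


def test_too_few_steps_per_side_rejected():
    steps, sides = _steps({"left": [1.0], "right": [1.0, 1.0]})
    with pytest.raises(InsufficientStepsError):
        trial_features(steps, sides)


def test_axis_offset_changes_only_that_axis_features():
    n = 600
    rng = np.random.default_rng(0)
    ml, vt, ap = rng.normal(size=(3, n))
    seg = _segmentation([0, 100, 200, 300, 400, 500])
    base = [step_features(_signal(ml, vt, ap), seg, i) for i in range(5)]
    shifted = [step_features(_signal(ml + 5.0, vt, ap), seg, i) for i in range(5)]
    for b, s in zip(base, shifted):
        assert s["ST"] == b["ST"]
        assert s["VM"] == b["VM"] and s["AM"] == b["AM"]
        assert s["VHM"] == b["VHM"] and s["AHM"] == b["AHM"]
        assert s["LHM"] == pytest.approx(b["LHM"] + 5.0)
        assert s["LHS"] == pytest.approx(b["LHS"])  # SD is offset-invariant
        assert s["LM"] != b["LM"]


def test_feature_table_has_sixty_centered_columns(small_table):
    feature_cols = [c for c in small_table.columns if c in FEATURE_NAMES]
    assert len(feature_cols) == 60
    assert not small_table[feature_cols].isna().any().any()
    assert np.all(np.abs(small_table[feature_cols].mean()) < 1e-10)


def test_single_trial_table_centers_to_zero(clean_trial):
    signal, _ = clean_trial
    table = build_feature_table([signal], compute_outcomes=False)
    assert np.allclose(table[list(FEATURE_NAMES)].to_numpy(), 0.0)


def test_variability_and_symmetry_features_nonnegative(small_cohort):
    trials, _ = small_cohort
    raw = build_feature_table(trials[:4], center=False)
    v_cols = [f"v{b}" for b in BASE_FEATURES]
    s_cols = [f"s{b}" for b in BASE_FEATURES]
    assert (raw[v_cols] >= 0).all().all()
    assert (raw[s_cols] >= 0).all().all()
    assert np.isfinite(raw[list(FEATURE_NAMES)].to_numpy()).all()
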