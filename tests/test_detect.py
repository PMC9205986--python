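"""Velocity-threshold detector: constructed-input recovery, brute-force
oracle equivalence, labelling/classification rules, rate summaries, the
latency median split and the binocular 2-D detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_epoch
from msalpha import StudyConfig, generate_study
from msalpha.detect import (
    DetectionDiagnostics,
    GazeShiftEvent,
    classify_trial,
    compute_velocity,
    detect_engbert_kliegl,
    detect_shifts,
    label_direction,
    rate_magnitude_map,
    shift_rate_timecourse,
    split_by_latency,
)
from msalpha.preprocess import build_calibration_reference, mark_usable, preprocess_trial
from msalpha.synth import PlannedShift, generate_calibration, generate_gaze_trial
from reference import brute_force_detect


def detect_on(epoch, **kwargs):
    return detect_shifts(compute_velocity(epoch), epoch, **kwargs)


class TestComputeVelocity:
    def test_constant_trace_zero_velocity(self):
        v = compute_velocity(make_epoch(np.full(500, 3.0), t0=0.0))
        assert np.nanmax(np.abs(v)) == 0.0

    def test_linear_ramp_preserved_by_smoothing(self):
        x = 0.5 * np.arange(500.0)
        v = compute_velocity(make_epoch(x, t0=0.0))
        assert np.allclose(v[10:-10], 0.5, atol=1e-9)

    def test_step_pulse_mass_matches_unsmoothed_diff(self):
        x = np.zeros(500)
        x[250:] = 10.0
        epoch = make_epoch(x, t0=0.0)
        v = compute_velocity(epoch)
        oracle = np.abs(np.diff(x))  # unsmoothed |diff| sums to the step size
        assert np.nansum(v[245:256]) == pytest.approx(float(oracle.sum()), rel=1e-6)

    def test_nan_support_propagates(self):
        x = np.zeros(500)
        x[100] = np.nan
        v = compute_velocity(make_epoch(x, t0=0.0))
        assert np.isnan(v[98:105]).all()  # kernel half-width 3 around the diff pair
        assert np.isfinite(v[110:]).all()

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compute_velocity(make_epoch(np.full(100, np.nan), t0=0.0))


class TestDetectShifts:
    def test_recovers_injected_step(self, step_epoch):
        events = detect_on(step_epoch)
        assert len(events) == 1
        assert events[0].onset_ms == pytest.approx(300.0, abs=10.0)
        assert events[0].magnitude_pct == pytest.approx(5.0, abs=0.5)

    def test_refractory_keeps_single_event_for_close_steps(self):
        x = np.zeros(3000)
        t = -1000.0 + np.arange(3000.0)
        x[t >= 300.0] += 5.0
        x[t >= 350.0] += 5.0
        events = detect_on(make_epoch(x))
        assert len(events) == 1

    def test_subfloor_step_yields_no_event(self):
        x = np.zeros(3000)
        t = -1000.0 + np.arange(3000.0)
        x[t >= 300.0] = 0.5
        diag = DetectionDiagnostics()
        events = detect_on(make_epoch(x), diagnostics=diag)
        assert events == []
        assert diag.n_subfloor >= 1

    def test_well_separated_steps_all_found(self):
        x = np.zeros(3000)
        t = -1000.0 + np.arange(3000.0)
        for onset, mag in ((-500.0, 4.0), (300.0, -6.0), (800.0, 3.0)):
            x[t >= onset] += mag
        events = detect_on(make_epoch(x))
        assert [round(e.onset_ms, -1) for e in events] == [-500.0, 300.0, 800.0]
        signs = [np.sign(e.magnitude_pct) for e in events]
        assert signs == [1.0, -1.0, 1.0]


def random_trace(rng, n=1500):
    """Short noisy trace with a random number of injected steps and NaN gaps."""
    t0 = -500.0
    x = np.cumsum(rng.normal(0, 0.05, n))
    for _ in range(rng.integers(0, 4)):
        onset = rng.uniform(t0 + 150, t0 + n - 150)
        mag = rng.choice([-1, 1]) * rng.uniform(0.5, 12.0)
        x[int(onset - t0) :] += mag
    if rng.random() < 0.4:
        g0 = rng.integers(0, n - 60)
        x[g0 : g0 + rng.integers(10, 60)] = np.nan
    return make_epoch(x, t0=t0)


class TestOracleEquivalence:
    def test_matches_brute_force_event_for_event(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            epoch = random_trace(rng)
            v = compute_velocity(epoch)
            got = detect_shifts(v, epoch)
            expected = brute_force_detect(v, epoch.position_pct, epoch.time_ms)
            assert len(got) == len(expected)
            for e, (onset, mag) in zip(got, expected):
                assert e.onset_ms == onset
                assert e.magnitude_pct == pytest.approx(mag, rel=1e-9)


class TestLabelDirection:
    def test_sign_convention(self):
        ev = [GazeShiftEvent(300.0, -5.0, 0.2), GazeShiftEvent(500.0, 5.0, 0.2)]
        labs = [e.direction for e in label_direction(ev, "left")]
        assert labs == ["toward", "away"]

    def test_flipping_cued_side_flips_labels(self):
        ev = [GazeShiftEvent(300.0, -5.0, 0.2), GazeShiftEvent(500.0, 2.0, 0.1)]
        left = [e.direction for e in label_direction(ev, "left")]
        right = [e.direction for e in label_direction(ev, "right")]
        assert all(a != b for a, b in zip(left, right))

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError, match="cued_side"):
            label_direction([], "up")


class TestClassifyTrial:
    def ev(self, onset, direction):
        mag = -5.0 if direction == "toward" else 5.0
        return GazeShiftEvent(onset, mag, 0.3, direction=direction)

    def test_first_in_window_event_wins(self):
        events = [self.ev(300.0, "toward"), self.ev(500.0, "away")]
        cls = classify_trial(events, usable=True)
        assert cls.label == "toward"
        assert cls.first_shift_latency_ms == 300.0

    def test_event_before_window_ignored(self):
        assert classify_trial([self.ev(150.0, "away")], usable=True).label == "none"

    def test_unusable_overrides_events(self):
        assert classify_trial([self.ev(300.0, "toward")], usable=False).label == "unusable"

    def test_window_boundaries_closed(self):
        assert classify_trial([self.ev(200.0, "away")], usable=True).label == "away"
        assert classify_trial([self.ev(600.0, "away")], usable=True).label == "away"
        assert classify_trial([self.ev(600.001, "away")], usable=True).label == "none"


class TestRateTimecourse:
    def test_no_events_zero_everywhere(self):
        times, rate = shift_rate_timecourse([[], [], []], np.arange(-500.0, 500.0))
        assert (rate == 0).all()

    def test_synchronous_events_give_20_per_second(self):
        trials = [[300.0] for _ in range(100)]
        times, rate = shift_rate_timecourse(trials, np.arange(-1000.0, 2000.0))
        covering = (times > 300.0 - 25.0) & (times < 300.0 + 25.0)
        assert np.allclose(rate[covering], 20.0)  # 1 event / 0.05 s
        assert rate[np.abs(times - 1000.0) < 20].max() == 0.0

    def test_window_counting_bookkeeping(self):
        rng = np.random.default_rng(5)
        trials = [sorted(rng.uniform(-800, 1800, rng.integers(0, 5)).tolist()) for _ in range(30)]
        times, rate = shift_rate_timecourse(trials, np.arange(-1000.0, 2000.0))
        # every interior event is covered by exactly 50 sliding windows
        total_events = sum(len(tr) for tr in trials)
        window_sum = rate.sum() * 0.05 * len(trials)  # undo rate scaling
        assert window_sum == pytest.approx(50 * total_events, rel=1e-9)

    def test_empty_trial_set_rejected(self):
        with pytest.raises(ValueError, match="trial"):
            shift_rate_timecourse([], np.arange(100.0))


class TestRateMagnitudeMap:
    def test_single_event_bin_membership(self):
        trials = [[(300.0, 3.0)]]
        times, bins, rate = rate_magnitude_map(trials, np.arange(-1000.0, 2000.0))
        t_idx = np.argmin(np.abs(times - 300.0))
        occupied = bins[rate[:, t_idx] > 0]
        # |mag| = 3 falls in half-open bins [b, b+5) for left edges 1, 2, 3 only
        assert occupied.tolist() == [1.0, 2.0, 3.0]

    def test_balanced_directions_difference_map_near_zero(self):
        rng = np.random.default_rng(6)
        toward, away = [], []
        for _ in range(200):
            toward.append([(rng.uniform(0, 1000), rng.uniform(1, 20))])
            away.append([(rng.uniform(0, 1000), rng.uniform(1, 20))])
        t_axis = np.arange(-1000.0, 2000.0)
        _, _, r_t = rate_magnitude_map(toward, t_axis)
        _, _, r_a = rate_magnitude_map(away, t_axis)
        assert abs((r_t - r_a).mean()) < 0.01


class TestSplitByLatency:
    def test_median_split_example(self):
        split = split_by_latency({0: [(10, 250.0), (11, 350.0), (12, 450.0), (13, 550.0)]})
        early, late = split[0]
        assert sorted(early) == [10, 11] and sorted(late) == [12, 13]

    def test_ties_alternate_for_balance(self):
        split = split_by_latency({0: [(i, 400.0) for i in range(6)]})
        early, late = split[0]
        assert len(early) == 3 and len(late) == 3

    def test_bimodal_latencies_recovered(self):
        rng = np.random.default_rng(8)
        items = [(i, float(rng.normal(300, 10))) for i in range(30)]
        items += [(i + 30, float(rng.normal(500, 10))) for i in range(30)]
        split = split_by_latency({0: items})
        early, late = split[0]
        lat = dict(items)
        assert np.mean([lat[i] for i in early]) == pytest.approx(300, abs=15)
        assert np.mean([lat[i] for i in late]) == pytest.approx(500, abs=15)

    def test_single_trial_participant_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            split = split_by_latency({0: [(0, 300.0)], 1: [(0, 250.0), (1, 450.0)]})
        assert 0 not in split and 1 in split


class TestEngbertKliegl:
    def make_binocular_epoch(self, saccade=True, noise=0.0, vertical_mag=0.0):
        rng = np.random.default_rng(9)
        n = 2000
        t0 = -500.0
        x = rng.normal(0, noise, n).cumsum() if noise else np.zeros(n)
        y = rng.normal(0, noise, n).cumsum() if noise else np.zeros(n)
        if saccade:
            idx = int(300.0 - t0)
            ramp = np.clip((np.arange(n) - idx) / 15.0, 0, 1)
            x = x + 6.0 * ramp
            y = y + vertical_mag * ramp
        jitter = lambda: rng.normal(0, noise, n) if noise else 0.0
        eyes = {"lx": x + jitter(), "ly": y + jitter(), "rx": x + jitter(), "ry": y + jitter()}
        return make_epoch(x, t0=t0, vertical=y, eyes=eyes)

    def test_injected_2d_saccade_detected_binocularly(self):
        epoch = self.make_binocular_epoch(vertical_mag=3.0)
        events = detect_engbert_kliegl(epoch)
        assert len(events) == 1
        assert events[0].onset_ms == pytest.approx(300.0, abs=10.0)

    def test_subthreshold_noise_yields_nothing(self):
        epoch = self.make_binocular_epoch(saccade=False, noise=0.01)
        assert detect_engbert_kliegl(epoch) == []

    def test_agrees_with_primary_detector_on_horizontal_saccade(self):
        epoch = self.make_binocular_epoch(noise=0.005)
        ek = detect_engbert_kliegl(epoch)
        primary = detect_on(epoch)
        assert len(ek) == 1 and len(primary) == 1
        assert abs(ek[0].onset_ms - primary[0].onset_ms) <= 10.0

    def test_monocular_fallback_warns(self):
        epoch = self.make_binocular_epoch()
        epoch.eyes_pct = None
        with pytest.warns(UserWarning, match="monocular"):
            events = detect_engbert_kliegl(epoch)
        assert len(events) == 1


class TestRecoveryFromStudy:
    def test_toward_fraction_within_binomial_99ci(self):
        """Detected first-in-window toward:away ratio recovers the generative
        bias on a small synthetic study."""
        cfg = StudyConfig(n_participants=4, n_trials=120, seed=21)
        study = generate_study(cfg)
        n_toward = n_away = 0
        for p in study.participants:
            ref = build_calibration_reference(p.calibration)
            for t_idx, trial in enumerate(p.gaze):
                epoch = preprocess_trial(trial, ref, p.trials.iloc[t_idx]["cued_side"])
                if not mark_usable(epoch) or not np.isfinite(epoch.position_pct).any():
                    continue
                events = label_direction(detect_on(epoch), epoch.cued_side)
                cls = classify_trial(events, usable=True)
                n_toward += cls.label == "toward"
                n_away += cls.label == "away"
        n = n_toward + n_away
        lo, hi = sps.binom.interval(0.99, n, cfg.p_toward_given_shift)
        assert lo <= n_toward <= hi


# ---------------------------------------------------------------------------
# property-based invariants


@st.composite
def noisy_traces(draw):
    n = draw(st.integers(600, 1200))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    x = rng.normal(0, draw(st.floats(0.01, 0.2)), n).cumsum()
    for _ in range(draw(st.integers(0, 3))):
        onset = rng.integers(50, n - 50)
        x[onset:] += rng.choice([-1, 1]) * rng.uniform(0.5, 15.0)
    return make_epoch(x, t0=-200.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(noisy_traces())
def test_refractory_and_floor_invariants(epoch):
    """No detected pair closer than 100 ms; no magnitude below 1%."""
    events = detect_on(epoch)
    onsets = [e.onset_ms for e in events]
    assert all(b - a > 100.0 for a, b in zip(onsets, onsets[1:]))
    assert all(abs(e.magnitude_pct) >= 1.0 for e in events)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(noisy_traces(), st.floats(3.0, 10.0))
def test_raising_threshold_never_adds_events(epoch, higher):
    base = detect_on(epoch, threshold_multiplier=3.0)
    strict = detect_on(epoch, threshold_multiplier=higher)
    assert len(strict) <= len(base)
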