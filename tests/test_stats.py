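"""Permutation inference: cluster tests against the exhaustive brute-force
oracle, half-peak latency geometry, latency permutation behaviour, and the
behavioural trimming/ANOVA machinery."""

import numpy as np
import pandas as pd
import pytest

from msalpha.stats import (
    UndefinedLatencyError,
    behaviour_class_stats,
    cluster_permutation_test,
    half_peak_latency,
    latency_permutation_test,
    trim_behaviour,
)
from reference import brute_force_sign_flip_test


class TestClusterPermutationTest:
    def test_null_data_without_suprathreshold_points(self):
        res = cluster_permutation_test(np.zeros((8, 30)), n_permutations=100, seed=0)
        assert res.clusters == []
        assert res.min_p == 1.0

    def test_constant_effect_spans_axis_with_minimal_p(self):
        rng = np.random.default_rng(1)
        X = 5.0 + 0.1 * rng.normal(size=(8, 30))
        res = cluster_permutation_test(X, n_permutations=1000, seed=0)
        assert res.exhaustive  # 2^8 = 256 <= 1000
        assert len(res.clusters) == 1
        assert res.clusters[0].mask.all()
        # two-sided sign-flip null: only the all-plus and all-minus
        # assignments reach the observed mass
        assert res.clusters[0].p == pytest.approx(2.0 / 256.0)

    def test_matches_exhaustive_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(0.4, 1.0, size=(7, 25))
            res = cluster_permutation_test(X, n_permutations=200, seed=0)
            assert res.exhaustive
            got = sorted((round(c.mass, 9), round(c.p, 12)) for c in res.clusters)
            expected = sorted(
                (round(m, 9), round(p, 12)) for m, p in brute_force_sign_flip_test(X)
            )
            assert got == expected

    def test_paired_contrast_equals_difference_test(self):
        rng = np.random.default_rng(3)
        A = rng.normal(1.0, 1.0, (9, 20))
        B = rng.normal(0.0, 1.0, (9, 20))
        r1 = cluster_permutation_test(A, B, n_permutations=400, seed=5)
        r2 = cluster_permutation_test(A - B, n_permutations=400, seed=5)
        assert [(c.mass, c.p) for c in r1.clusters] == [(c.mass, c.p) for c in r2.clusters]

    def test_2d_grid_separates_disconnected_blobs(self):
        rng = np.random.default_rng(4)
        X = 0.2 * rng.normal(size=(10, 12, 12))
        X[:, 2:4, 2:4] += 4.0
        X[:, 8:10, 8:10] -= 4.0
        res = cluster_permutation_test(X, n_permutations=300, seed=0)
        # the two blob clusters dominate; incidental noise clusters are small
        top = res.clusters[:2]
        signs = sorted(np.sign(c.mass) for c in top)
        assert signs == [-1.0, 1.0]
        for c in top:
            assert c.p < 0.05
            assert c.mask.sum() == 4  # 2x2 blob, no diagonal bridging
        pos = next(c for c in top if c.mass > 0)
        assert pos.mask[2:4, 2:4].all()

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            cluster_permutation_test(np.zeros((1, 10)))


class TestHalfPeakLatency:
    def test_linear_ramp_analytic(self):
        t = np.arange(0.0, 1001.0)
        v = np.interp(t, [0, 300, 500, 1000], [0, 0, -20, -20])
        assert half_peak_latency(t, v) == pytest.approx(400.0)

    def test_instantaneous_step_returns_step_time(self):
        t = np.arange(0.0, 1001.0)
        v = np.where(t >= 350.0, -10.0, 0.0)
        hp = half_peak_latency(t, v)
        assert 349.0 <= hp <= 350.0  # interpolation inside the single-step sample

    def test_constant_zero_undefined(self):
        t = np.arange(0.0, 1001.0)
        with pytest.raises(UndefinedLatencyError):
            half_peak_latency(t, np.zeros_like(t))

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 1001.0)
        v = -np.clip((t - 300) / 200.0, 0, 1) + 0.05 * rng.normal(size=t.size)
        a = half_peak_latency(t, v)
        b = half_peak_latency(t, 37.5 * v)
        assert a == pytest.approx(b)

    def test_peak_sign_selects_negative_extremum(self):
        t = np.arange(0.0, 1001.0)
        v = np.sin(2 * np.pi * t / 1000.0) * -10  # negative lobe first
        hp_auto = half_peak_latency(t, v)
        hp_neg = half_peak_latency(t, v, peak_sign=-1)
        assert hp_auto == hp_neg


def ramp_timecourse(onset, t, depth=-20.0, ramp=200.0, noise=0.0, rng=None):
    v = depth * np.clip((t - onset) / ramp, 0.0, 1.0)
    if noise and rng is not None:
        v = v + rng.normal(0, noise, t.size)
    return v


class TestLatencyPermutationTest:
    t = np.arange(0.0, 1001.0)

    def test_identical_conditions_null(self):
        rng = np.random.default_rng(6)
        base = np.array([ramp_timecourse(300 + 20 * k, self.t) for k in range(8)])
        res = latency_permutation_test(base, base.copy(), self.t, n_permutations=500, seed=1)
        assert res.observed_diff_ms == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.4  # exchangeable: large p

    def test_programmed_difference_recovered(self):
        rng = np.random.default_rng(7)
        early = np.array(
            [ramp_timecourse(340 + 10 * k, self.t, noise=0.3, rng=rng) for k in range(8)]
        )
        late = np.array(
            [ramp_timecourse(440 + 10 * k, self.t, noise=0.3, rng=rng) for k in range(8)]
        )
        res = latency_permutation_test(early, late, self.t, n_permutations=1000, seed=2)
        assert res.observed_diff_ms == pytest.approx(100.0, abs=20.0)
        assert res.p < 0.05

    def test_permutation_distribution_symmetric_under_null(self):
        """With exchangeable conditions the late-minus-early difference is as
        often positive as negative across permutations."""
        rng = np.random.default_rng(8)
        a = np.array([ramp_timecourse(350 + 15 * k, self.t, noise=0.2, rng=rng) for k in range(8)])
        b = np.array([ramp_timecourse(350 + 15 * k, self.t, noise=0.2, rng=rng) for k in range(8)])
        res_fwd = latency_permutation_test(a, b, self.t, n_permutations=600, seed=3)
        res_rev = latency_permutation_test(b, a, self.t, n_permutations=600, seed=3)
        # two-sided coverage: one-sided p-values of the two orientations sum ~ 1
        assert res_fwd.p + res_rev.p == pytest.approx(1.0, abs=0.15)

    def test_flat_timecourses_abort(self):
        flat = np.zeros((6, self.t.size))
        with pytest.raises(UndefinedLatencyError):
            latency_permutation_test(flat, flat, self.t, n_permutations=100, seed=0)


class TestTrimBehaviour:
    def frame(self, rts, participant=0):
        return pd.DataFrame(
            {"participant": participant, "rt_ms": rts, "error_deg": 10.0}
        )

    def test_rt_above_3000_removed_first(self):
        df = self.frame([800.0, 900.0, 3500.0, 1000.0])
        out = trim_behaviour(df)
        assert 3500.0 not in out["rt_ms"].values
        assert len(out) == 3

    def test_identical_rts_survive_sd_step(self):
        df = self.frame([900.0] * 10)
        assert len(trim_behaviour(df)) == 10

    def test_outlier_beyond_2p5_sd_removed(self):
        rng = np.random.default_rng(9)
        rts = rng.normal(900, 50, 60).tolist()
        mu, sd = np.mean(rts), np.std(rts, ddof=1)
        rts.append(mu + 3.2 * sd)
        out = trim_behaviour(self.frame(rts))
        assert len(out) <= 60
        assert out["rt_ms"].max() < mu + 3.0 * sd

    def test_reapplication_fixed_point_when_no_outliers(self):
        """Bounded RT distributions (max |z| < 2.5) are untouched by the SD
        step, so re-running the procedure is a no-op."""
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(4), 80),
                "rt_ms": rng.uniform(600, 1200, 320),  # uniform: max |z| ~ 1.73
                "error_deg": rng.normal(14, 5, 320),
            }
        )
        once = trim_behaviour(df)
        twice = trim_behaviour(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_steps_are_order_dependent(self):
        """A 3200-ms RT is removed by the hard cut-off before it can inflate
        the per-participant SD; reversing the steps would keep an extra
        outlier."""
        rng = np.random.default_rng(13)
        rts = rng.normal(900, 50, 50).tolist() + [3200.0]
        mu, sd = np.mean(rts), np.std(rts, ddof=1)
        extra = mu + 2.0 * sd  # inside 2.5 SD of the inflated spread only
        out = trim_behaviour(self.frame(rts + [extra]))
        assert 3200.0 not in out["rt_ms"].values
        assert extra not in out["rt_ms"].values


class TestBehaviourClassStats:
    def make_trials(self, shift=1.0, n_participants=8, rng=None):
        rng = rng or np.random.default_rng(11)
        rows = []
        for p in range(n_participants):
            base = rng.normal(14.0, 1.0)
            for cls, mean in (("toward", base), ("none", base + shift / 2), ("away", base + shift)):
                for _ in range(20):
                    rows.append(
                        {
                            "participant": p,
                            "trial_class": cls,
                            "error_deg": rng.normal(mean, 2.0),
                            "rt_ms": rng.normal(900, 100),
                        }
                    )
        return pd.DataFrame(rows)

    def test_squared_paired_t_equals_two_level_F(self):
        """For two conditions, the repeated-measures F is the square of the
        paired t (checked numerically)."""
        from scipy import stats as sps
        import pingouin as pg

        rng = np.random.default_rng(12)
        df = self.make_trials(rng=rng)
        cell = df.groupby(["participant", "trial_class"])["error_deg"].mean().unstack()
        t, _ = sps.ttest_rel(cell["toward"], cell["away"])
        long = cell[["toward", "away"]].reset_index().melt(
            id_vars="participant", var_name="trial_class", value_name="error_deg"
        )
        aov = pg.rm_anova(
            data=long, dv="error_deg", within="trial_class", subject="participant"
        )
        assert float(aov["F"].iloc[0]) == pytest.approx(t**2, rel=1e-9)

    def test_programmed_direction_recovered(self):
        out = behaviour_class_stats(self.make_trials(shift=2.0))
        assert out["class_means"]["toward"] < out["class_means"]["away"]
        assert out["pairwise"]["toward_vs_away"]["t"] < 0
        assert out["anova"]["p"] < 0.05

    def test_missing_class_drops_participant_with_warning(self):
        df = self.make_trials()
        df = df[~((df["participant"] == 0) & (df["trial_class"] == "away"))]
        with pytest.warns(UserWarning, match="dropped"):
            out = behaviour_class_stats(df)
        assert out["n_participants"] == 7

    def test_bonferroni_capped_at_one(self):
        out = behaviour_class_stats(self.make_trials(shift=0.0))
        for pair in out["pairwise"].values():
            assert 0.0 <= pair["p_bonferroni"] <= 1.0
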