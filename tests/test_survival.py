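import numpy as np
import pandas as pd
import pytest

from gedipipe import (
    FluorescenceTrace,
    compare_group_statistic,
    cox_fit,
    cumulative_risk,
    fit_log_decay,
    fit_rise,
    generate_decay_trace,
    generate_survival_cohort,
    km_estimator,
)


def make_records(times, events, group="g"):
    return pd.DataFrame(
        {"id": range(len(times)), "group": group, "time": times, "event": events}
    )


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """4 subjects: events at t=1 and t=2, censored at 1.5 and 3.
        S(1) = 3/4; at t=2 two remain at risk, one dies: S(2) = 3/4 * 1/2."""
        rec = make_records([1.0, 1.5, 2.0, 3.0], [True, False, True, False])
        curve = km_estimator(rec)["g"]
        assert np.allclose(curve.times, [1.0, 2.0])
        assert curve.survival[0] == pytest.approx(0.75)
        assert curve.survival[1] == pytest.approx(0.375)
        assert list(curve.at_risk) == [4, 2]

    def test_all_censored_is_flat(self):
        rec = make_records([5.0, 6.0, 7.0], [False] * 3)
        curve = km_estimator(rec)["g"]
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_matches_empirical_survival(self, rng):
        times = rng.exponential(10, size=200)
        rec = make_records(times, [True] * 200)
        curve = km_estimator(rec)["g"]
        for t in [1.0, 5.0, 15.0]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_monotone_and_bounded_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 60))
            rec = make_records(rng.exponential(20, n).round(1), rng.uniform(size=n) < 0.7)
            curve = km_estimator(rec)["g"]
            s = np.concatenate([[1.0], curve.survival])
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimator(make_records([-1.0, 2.0], [True, True]))

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = np.ceil(rng.exponential(30, 150))
        events = rng.uniform(size=150) < 0.8
        rec = make_records(times, events)
        curve = km_estimator(rec)["g"]
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


class TestCumulativeRisk:
    def test_flat_curve_zero_risk(self):
        rec = make_records([5.0], [False])
        curve = km_estimator(rec)["g"]
        crd = cumulative_risk(curve)
        assert len(crd) == 0

    def test_incidence_and_hazard_on_fixture(self):
        rec = make_records([1.0, 1.5, 2.0, 3.0], [True, False, True, False])
        crd = cumulative_risk(km_estimator(rec)["g"])
        assert crd["cumulative_incidence"].iloc[-1] == pytest.approx(1 - 0.375)
        # Nelson-Aalen: 1/4 + 1/2
        assert crd["cumulative_hazard"].iloc[-1] == pytest.approx(0.75)


class TestCoxFit:
    def test_mirrored_groups_hr_one(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        rec = pd.concat(
            [make_records(times, [True] * 5, "a"), make_records(times, [True] * 5, "b")],
            ignore_index=True,
        )
        res = cox_fit(rec, "a")[0]
        assert res.hr == pytest.approx(1.0, abs=1e-8)

    def test_label_reversal_inverts_hr(self):
        rec = generate_survival_cohort([80, 80], 0.02, 2.5, 100.0, seed=3)
        fwd = cox_fit(rec, "control")[0]
        rev = cox_fit(rec, "group1")[0]
        assert fwd.beta == pytest.approx(-rev.beta, abs=1e-6)
        assert fwd.hr == pytest.approx(1.0 / rev.hr, rel=1e-6)

    def test_recovers_generator_hazard_ratio(self):
        rec = generate_survival_cohort([1000, 1000], 0.01, 2.0, 168.0, seed=42)
        res = cox_fit(rec, "control")[0]
        assert 1.8 <= res.hr <= 2.2
        assert res.ci_low <= res.hr <= res.ci_high

    def test_rank_invariance_under_monotone_time_transform(self):
        rec = generate_survival_cohort([120, 120], 0.02, 1.6, 120.0, seed=5)
        cubed = rec.assign(time=rec["time"] ** 3)
        assert cox_fit(rec, "control")[0].beta == pytest.approx(
            cox_fit(cubed, "control")[0].beta, abs=1e-8
        )

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        rec = generate_survival_cohort([150, 120], 0.01, 1.9, 168.0, seed=9)
        rec["time"] = np.ceil(rec["time"] / 24.0) * 24.0  # heavy ties
        mine = cox_fit(rec, "control")[0]
        df = rec.assign(x=(rec["group"] != "control").astype(float))[["time", "event", "x"]]
        cph = lifelines.CoxPHFitter().fit(df, "time", "event")
        assert mine.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert mine.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_cluster_bootstrap_changes_se_not_estimate(self):
        rec = generate_survival_cohort([120, 120], 0.02, 1.8, 120.0, seed=21)
        rec["well"] = np.tile(["w1", "w2", "w3", "w4"], 60)
        plain = cox_fit(rec, "control")[0]
        robust = cox_fit(rec, "control", cluster="well", n_boot=60)[0]
        assert robust.beta == plain.beta
        assert robust.se != plain.se
        assert robust.ci_low <= robust.hr <= robust.ci_high

    def test_no_events_in_group_rejected(self):
        rec = pd.concat(
            [make_records([1, 2, 3], [True] * 3, "a"), make_records([1, 2, 3], [False] * 3, "b")],
            ignore_index=True,
        )
        with pytest.raises(ValueError):
            cox_fit(rec, "a")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(make_records([1, 2], [True, True]), "g")


class TestDecayFit:
    def test_exact_recovery_noise_free(self):
        tr = generate_decay_trace(1000.0, 20.45, np.arange(0, 97, 3.0))
        fit = fit_log_decay(tr)
        assert fit.half_life == pytest.approx(20.45, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_trace_infinite_half_life(self):
        tr = FluorescenceTrace(np.arange(5.0), np.full(5, 3.0), (0, 1))
        fit = fit_log_decay(tr)
        assert fit.slope == 0.0
        assert np.isinf(fit.half_life)

    def test_scale_invariant_slope(self):
        t = np.arange(0, 50, 2.0)
        a = generate_decay_trace(100.0, 12.0, t)
        b = generate_decay_trace(700.0, 12.0, t)
        assert fit_log_decay(a).slope == pytest.approx(fit_log_decay(b).slope, rel=1e-12)

    def test_nonpositive_samples_dropped_with_warning(self):
        tr = FluorescenceTrace(np.arange(6.0), np.array([8.0, 4.0, 2.0, 1.0, 0.0, -1.0]), (0, 1))
        with pytest.warns(UserWarning):
            fit = fit_log_decay(tr)
        assert fit.half_life == pytest.approx(1.0, rel=1e-10)

    def test_too_few_samples_rejected(self):
        tr = FluorescenceTrace(np.arange(3.0), np.array([1.0, 0.0, 0.0]), (0, 1))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                fit_log_decay(tr)

    def test_noise_bias_small(self, rng):
        """At 5% noise, the mean recovered half-life is within 2% of truth."""
        t = np.arange(0, 97, 3.0)
        half_lives = [
            fit_log_decay(generate_decay_trace(1000.0, 20.0, t, noise_sd=1.0, seed=rng)).half_life
            for _ in range(500)
        ]
        assert np.mean(half_lives) == pytest.approx(20.0, rel=0.02)


class TestRiseFit:
    def test_exact_recovery(self):
        t = np.linspace(0, 20, 120)
        true = (0.0, 1.0, 5.0, 2.0)
        v = np.where(t < true[2], true[0], true[0] + (true[1] - true[0]) * (1 - np.exp(-(t - true[2]) / true[3])))
        fit = fit_rise(FluorescenceTrace(t, v, (0, 5)))
        assert fit.f0 == pytest.approx(true[0], abs=1e-6)
        assert fit.plateau == pytest.approx(true[1], rel=1e-6)
        assert fit.t0 == pytest.approx(true[2], rel=1e-4)
        assert fit.tau == pytest.approx(true[3], rel=1e-4)

    def test_flat_trace_flagged(self):
        t = np.linspace(0, 10, 40)
        fit = fit_rise(FluorescenceTrace(t, np.full_like(t, 2.0), (0, 5)))
        assert not fit.identifiable
        assert fit.plateau == pytest.approx(fit.f0)

    def test_tau_equivariance(self):
        t = np.linspace(0, 30, 200)

        def curve(tau):
            return np.where(t < 5, 0.1, 0.1 + 0.9 * (1 - np.exp(-(t - 5) / tau)))

        tau_full = fit_rise(FluorescenceTrace(t, curve(4.0), (0, 5))).tau
        tau_half = fit_rise(FluorescenceTrace(t, curve(2.0), (0, 5))).tau
        assert tau_full == pytest.approx(2 * tau_half, rel=1e-3)


class TestCompareGroups:
    def test_identical_samples_high_p(self, rng):
        a = rng.normal(size=30)
        out = compare_group_statistic(a, a.copy())
        assert out["p_value"] > 0.9

    def test_separated_samples_low_p(self):
        out = compare_group_statistic(np.arange(20.0), np.arange(100.0, 120.0))
        assert out["p_value"] < 1e-3

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            compare_group_statistic([1.0], [2.0], test="anova-ish")

    def test_singletons_warn(self):
        with pytest.warns(UserWarning):
            out = compare_group_statistic([1.0], [2.0])
        assert np.isfinite(out["statistic"])
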