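import math

import numpy as np
import pytest
from scipy import optimize, stats

from metafrag import (
    ScenarioSpec,
    TooFewStudiesError,
    estimate_tau2_dl,
    estimate_tau2_reml,
    i_squared,
    pool,
    pool_fixed,
    pool_random,
    q_statistic,
)
from metafrag.effects import StudyEffect


def effects(ys, ss):
    return [StudyEffect(y, s, False, True) for y, s in zip(ys, ss)]


class TestFixedEffect:
    def test_identical_studies(self):
        r = pool_fixed(effects([0.5, 0.5], [0.1, 0.1]))
        assert r.theta_hat == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1 / math.sqrt(2))
        assert r.tau2 == 0.0

    def test_weighted_mean_by_hand(self):
        r = pool_fixed(effects([0.0, 2.0], [1.0, 1.0]))
        assert r.theta_hat == pytest.approx(1.0)
        assert r.se == pytest.approx(1 / math.sqrt(2))
        assert r.ci_low == pytest.approx(1.0 - 1.959963984540054 / math.sqrt(2))

    def test_single_study_rejected(self):
        with pytest.raises(TooFewStudiesError):
            pool_fixed(effects([0.3], [0.1]))

    def test_noninformative_studies_ignored(self):
        effs = effects([0.0, 2.0], [1.0, 1.0]) + [StudyEffect(0.0, math.inf, False, False)]
        r = pool_fixed(effs)
        assert r.theta_hat == pytest.approx(1.0)
        assert r.n_informative == 2


class TestHeterogeneityStatistics:
    @pytest.mark.parametrize(
        "ys, ss, expected_q, expected_df",
        [
            ([1.0, 1.0], [0.5, 0.5], 0.0, 1),
            ([0.0, 2.0], [1.0, 1.0], 2.0, 1),
            ([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], 2.0, 2),
        ],
    )
    def test_q_hand_values(self, ys, ss, expected_q, expected_df):
        Q, df, p = q_statistic(effects(ys, ss))
        assert Q == pytest.approx(expected_q, abs=1e-10)
        assert df == expected_df
        assert p == pytest.approx(stats.chi2.sf(expected_q, expected_df))

    @pytest.mark.parametrize(
        "Q, df, expected",
        [(2.0, 1, 0.5), (1.0, 2, 0.0), (0.0, 1, 0.0), (10.0, 4, 0.6)],
    )
    def test_i_squared(self, Q, df, expected):
        assert i_squared(Q, df) == pytest.approx(expected)

    def test_i_squared_rejects_bad_input(self):
        with pytest.raises(ValueError):
            i_squared(-1.0, 1)
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestTau2Estimators:
    def test_dl_hand_value(self):
        assert estimate_tau2_dl(effects([0.0, 2.0], [1.0, 1.0])) == pytest.approx(1.0, abs=1e-10)

    def test_dl_truncates_at_zero(self):
        assert estimate_tau2_dl(effects([0.5, 0.5], [0.1, 0.1])) == 0.0
        # Q = df boundary: three unit-variance studies at 0, 1, 2
        assert estimate_tau2_dl(effects([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])) == 0.0

    def test_dl_matches_statsmodels(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(3)
        y = rng.normal(0.3, 0.5, size=8)
        v = rng.uniform(0.05, 0.4, size=8)
        res = combine_effects(y, v, method_re="dl")
        ours = estimate_tau2_dl(effects(y, np.sqrt(v)))
        assert ours == pytest.approx(res.tau2, rel=1e-8)
        pooled = pool_random(effects(y, np.sqrt(v)), ours, ci_method="normal")
        df_sm = res.summary_frame()
        assert pooled.theta_hat == pytest.approx(
            df_sm.loc["random effect", "eff"], rel=1e-8
        )

    def test_reml_equal_variance_closed_form(self):
        tau2, converged = estimate_tau2_reml(effects([0.0, 2.0], [1.0, 1.0]))
        assert converged
        assert tau2 == pytest.approx(1.0, abs=1e-6)

    def test_reml_identical_studies(self):
        tau2, converged = estimate_tau2_reml(effects([0.7, 0.7, 0.7], [0.2, 0.2, 0.2]))
        assert converged
        assert tau2 == pytest.approx(0.0, abs=1e-10)

    def test_reml_matches_direct_likelihood_maximisation(self, rng):
        """Fixed-point REML equals a bounded numerical maximiser of the
        explicit restricted log-likelihood, an independent route."""

        def neg_restricted_ll(tau2, y, v):
            w = 1.0 / (v + tau2)
            theta = np.sum(w * y) / np.sum(w)
            return 0.5 * (
                np.sum(np.log(v + tau2))
                + np.log(np.sum(w))
                + np.sum(w * (y - theta) ** 2)
            )

        for _ in range(25):
            k = int(rng.integers(3, 12))
            y = rng.normal(0.2, 0.6, size=k)
            v = rng.uniform(0.02, 0.5, size=k)
            ours, converged = estimate_tau2_reml(effects(y, np.sqrt(v)))
            assert converged
            ref = optimize.minimize_scalar(
                neg_restricted_ll, bounds=(0.0, 20.0), args=(y, v), method="bounded",
                options={"xatol": 1e-10},
            ).x
            if ref < 1e-7:  # truncation boundary
                assert ours <= 1e-6
            else:
                assert ours == pytest.approx(ref, abs=5e-6)


class TestRandomEffectsPooling:
    def test_normal_interval_by_hand(self):
        r = pool_random(effects([0.0, 2.0], [1.0, 1.0]), tau2=1.0, ci_method="normal")
        assert r.theta_hat == pytest.approx(1.0)
        # se = (sum 1/(1+1))^(-1/2) = 1
        assert r.se == pytest.approx(1.0)
        assert r.ci_low == pytest.approx(1.0 - 1.959963984540054)
        assert r.ci_high == pytest.approx(1.0 + 1.959963984540054)

    def test_hksj_interval_by_hand(self):
        r = pool_random(effects([0.0, 2.0], [1.0, 1.0]), tau2=1.0, ci_method="hksj")
        assert r.theta_hat == pytest.approx(1.0)
        assert r.se == pytest.approx(1.0)
        t_crit = stats.t.ppf(0.975, 1)
        assert t_crit == pytest.approx(12.706204736, abs=1e-6)
        assert r.ci_high == pytest.approx(1.0 + t_crit)

    def test_hksj_degenerate_zero_dispersion(self):
        r = pool_random(effects([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]), tau2=0.0, ci_method="hksj")
        assert r.degenerate
        assert r.ci_low == r.ci_high == pytest.approx(0.5)

    def test_re_at_zero_tau2_reproduces_fe(self):
        ys, ss = [0.1, 0.4, 0.9], [0.2, 0.3, 0.25]
        fe = pool_fixed(effects(ys, ss))
        re = pool_random(effects(ys, ss), tau2=0.0, ci_method="normal")
        assert re.theta_hat == pytest.approx(fe.theta_hat, abs=1e-14)
        assert re.se == pytest.approx(fe.se, abs=1e-14)


class TestEstimatorInvariances:
    def test_translation_invariance_of_tau2(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 9))
            y = rng.normal(0, 1, size=k)
            s = rng.uniform(0.1, 0.8, size=k)
            shift = float(rng.normal(0, 5))
            dl_a = estimate_tau2_dl(effects(y, s))
            dl_b = estimate_tau2_dl(effects(y + shift, s))
            assert dl_b == pytest.approx(dl_a, abs=1e-9)
            re_a, _ = estimate_tau2_reml(effects(y, s))
            re_b, _ = estimate_tau2_reml(effects(y + shift, s))
            assert re_b == pytest.approx(re_a, abs=1e-7)

    def test_scale_invariance_of_q_and_i2(self, rng):
        y = rng.normal(0, 1, size=6)
        s = rng.uniform(0.1, 0.5, size=6)
        Q1, df1, _ = q_statistic(effects(y, s))
        c = 3.7
        Q2, df2, _ = q_statistic(effects(c * y, c * s))
        assert Q2 == pytest.approx(Q1, rel=1e-12)
        assert i_squared(Q2, df2) == pytest.approx(i_squared(Q1, df1), rel=1e-12)


class TestScenarioSpec:
    def test_five_configurations_expressible(self):
        assert ScenarioSpec.from_key("FE").model == "FE"
        s1 = ScenarioSpec.from_key("S1")
        assert (s1.tau2_estimator, s1.ci_method) == ("REML", "hksj")
        s4 = ScenarioSpec.from_key("S4")
        assert (s4.tau2_estimator, s4.ci_method) == ("DL", "normal")
        for key in ("FE", "S1", "S2", "S3", "S4"):
            assert ScenarioSpec.from_key(key).key == key

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec.from_key("S5")

    def test_pool_under_full_scenario(self):
        r = pool(effects([0.0, 2.0], [1.0, 1.0]), ScenarioSpec.from_key("S4"))
        # DL tau2 = 1, then the same normal machinery as pool_random
        manual = pool_random(effects([0.0, 2.0], [1.0, 1.0]), tau2=1.0, ci_method="normal")
        assert r.theta_hat == pytest.approx(manual.theta_hat)
        assert r.se == pytest.approx(manual.se)
        assert r.tau2 == pytest.approx(1.0, abs=1e-10)
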