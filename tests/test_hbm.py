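import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bayesbasket.hbm import (
    BHMConfig,
    HierarchicalBenefitModel,
    fit_bhm,
    independent_conjugate,
    shrinkage_report,
)
from bayesbasket.roster import CohortData

from .oracles import logit_normal_exceedance, pooled_exceedance_and_mean


def cohort(r, n, p0, tumor="t0", arm="buparlisib"):
    return CohortData(arm, tumor, n, r, p0)


class TestIndependentConjugate:
    @pytest.mark.parametrize(
        "r,n,p0,expected",
        [
            (0, 14, 0.15, 0.85**15),   # Beta(1,15) tail above 0.15
            (0, 10, 0.30, 0.70**11),
            (0, 0, 0.5, 0.5),          # uniform prior symmetry
        ],
    )
    def test_closed_forms(self, r, n, p0, expected):
        assert independent_conjugate(r, n, (1, 1), p0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_p0_domain_error(self):
        with pytest.raises(ValueError, match="p0"):
            independent_conjugate(1, 5, (1, 1), 1.0)

    @given(
        n=st.integers(1, 60),
        r=st.integers(0, 59),
        p0=st.floats(0.05, 0.6),
    )
    def test_monotone_in_responses_and_sample_size(self, n, r, p0):
        r = min(r, n - 1)
        up = independent_conjugate(r + 1, n, (1, 1), p0)
        base = independent_conjugate(r, n, (1, 1), p0)
        down = independent_conjugate(r, n + 1, (1, 1), p0)
        # strict monotonicity, except where float precision saturates
        if 1e-10 < base < 1.0 - 1e-10:
            assert up > base
            assert down < base
        else:
            assert up >= base >= down


class TestHierarchicalSampler:
    def test_no_borrowing_single_cohort_matches_quadrature(self):
        """tau fixed large: posterior is the independent logit-normal model."""
        cfg = BHMConfig(tau_fixed=10.0, chains=2, iterations=4000,
                        burn_in=1000, seed=11)
        summary = fit_bhm([cohort(0, 14, 0.15)], [0], cfg)
        oracle = logit_normal_exceedance(
            0, 14, 0.15, prior_sd=math.sqrt(cfg.s0**2 + 10.0**2)
        )
        assert summary.exceedance_prob[0] == pytest.approx(oracle, abs=0.02)

    def test_strong_concordant_cluster_all_exceed(self):
        cohorts = [cohort(30, 100, 0.15, tumor=f"t{i}") for i in range(5)]
        summary = fit_bhm(cohorts, [0] * 5,
                          BHMConfig(chains=2, iterations=3000, burn_in=1000, seed=2))
        assert (summary.exceedance_prob > 0.99).all()

    def test_empty_cohort_posterior_is_proper(self):
        """A no-data cohort inherits the cluster prior predictive."""
        cohorts = [cohort(8, 20, 0.2, "a"), cohort(0, 0, 0.2, "b")]
        summary = fit_bhm(cohorts, [0, 0],
                          BHMConfig(chains=2, iterations=3000, burn_in=1000, seed=5))
        assert 0.0 < summary.exceedance_prob[1] < 1.0
        # shrinkage target: pulled toward its cluster-mate, not the raw 0/0
        assert 0.05 < summary.posterior_mean[1] < 0.9

    def test_full_pooling_limit_matches_pooled_oracle(self):
        rs, ns, p0 = [2, 5, 9], [20, 25, 30], 0.2
        cohorts = [cohort(r, n, p0, tumor=f"t{i}") for i, (r, n) in
                   enumerate(zip(rs, ns))]
        cfg = BHMConfig(tau_fixed=1e-4, chains=2, iterations=4000,
                        burn_in=1500, seed=8)
        summary = fit_bhm(cohorts, [0, 0, 0], cfg)
        exc, mean = pooled_exceedance_and_mean(rs, ns, p0, prior_sd=cfg.s0)
        assert np.allclose(summary.exceedance_prob, exc, atol=0.02)
        assert np.allclose(summary.posterior_mean, mean, atol=0.02)
        assert np.ptp(summary.posterior_mean) < 0.02  # one shared rate

    def test_cross_cluster_independence(self):
        """Perturbing cluster A's data leaves cluster B's posterior alone."""
        cfg = BHMConfig(chains=2, iterations=4000, burn_in=1500, seed=13)
        b_cohorts = [cohort(4, 20, 0.15, "b1"), cohort(6, 22, 0.15, "b2")]
        weak_a = [cohort(0, 15, 0.3, "a1")] + b_cohorts
        strong_a = [cohort(15, 15, 0.3, "a1")] + b_cohorts
        s1 = fit_bhm(weak_a, [0, 1, 1], cfg)
        s2 = fit_bhm(strong_a, [0, 1, 1], cfg)
        assert np.allclose(
            s1.exceedance_prob[1:], s2.exceedance_prob[1:], atol=0.02
        )
        assert np.allclose(s1.posterior_mean[1:], s2.posterior_mean[1:], atol=0.02)

    def test_determinism_same_seed_same_draws(self):
        cohorts = [cohort(3, 12, 0.2, "a"), cohort(5, 18, 0.25, "b")]
        cfg = BHMConfig(chains=2, iterations=500, burn_in=100, seed=42)
        a = fit_bhm(cohorts, [0, 1], cfg)
        b = fit_bhm(cohorts, [0, 1], cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_retained_draw_count_and_diagnostics(self):
        cfg = BHMConfig(chains=3, iterations=600, burn_in=200, seed=0)
        summary = fit_bhm([cohort(5, 20, 0.2)], [0], cfg)
        assert summary.draws.shape == (3, 400, 1)
        assert np.isfinite(summary.rhat).all()
        assert ((summary.draws > 0) & (summary.draws < 1)).all()

    def test_unassigned_cohort_is_configuration_error(self):
        with pytest.raises(ValueError, match="cluster assignment"):
            fit_bhm([cohort(1, 5, 0.2), cohort(1, 5, 0.2, "u")], [0])


class TestEstimatorInterface:
    def test_array_input_and_fitted_attributes(self):
        X = np.array([[2.0, 10.0, 0.2], [5.0, 12.0, 0.3]])
        model = HierarchicalBenefitModel(
            iterations=600, burn_in=200, random_state=1
        ).fit(X, cluster=[0, 0])
        assert model.exceedance_prob_.shape == (2,)
        assert model.summary_.to_frame().shape[0] == 2

    def test_conjugate_mode_matches_closed_form(self):
        X = np.array([[0.0, 14.0, 0.15]])
        model = HierarchicalBenefitModel(
            mode="independent_conjugate", iterations=60_000, burn_in=10_000,
            random_state=0,
        ).fit(X)
        assert model.exceedance_prob_[0] == pytest.approx(0.85**15, abs=0.01)

    def test_missing_p0_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            HierarchicalBenefitModel().fit(np.array([[1.0, 5.0, np.nan]]))


class TestShrinkage:
    def test_singleton_cluster_has_no_cluster_shrinkage(self):
        cohorts = [cohort(3, 15, 0.2, "solo")]
        summary = fit_bhm(cohorts, [0],
                          BHMConfig(chains=2, iterations=2000, burn_in=500, seed=3))
        report = shrinkage_report(summary, cohorts, [0])
        assert report.loc[0, "shrinkage"] == 0.0
        assert math.isnan(report.loc[0, "cluster_pooled_rate"])

    def test_outlier_shrinks_toward_concordant_cluster(self):
        cohorts = [cohort(0, 8, 0.2, "small_outlier")] + [
            cohort(12, 30, 0.2, f"big{i}") for i in range(3)
        ]
        summary = fit_bhm(cohorts, [0] * 4,
                          BHMConfig(chains=2, iterations=4000, burn_in=1000, seed=9))
        report = shrinkage_report(summary, cohorts, [0] * 4)
        raw = report.loc[0, "raw_rate"]
        pooled = report.loc[0, "cluster_pooled_rate"]
        post = report.loc[0, "posterior_mean"]
        assert raw < post < pooled
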