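import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstrait.ld import ld_scores
from crosstrait.mixture import (BivariateCausalMixture, MixtureParams, Q90,
                                fit_bivariate, model_vs_actual_qq, n_causal_90,
                                overlap_aic, pair_neg_log_likelihood,
                                prune_for_fit, venn_summary)
from crosstrait.simulate import GenerativeParams, simulate_ld_blocks, simulate_pair
from crosstrait.sumstats import harmonize_pair


def random_params(rng):
    w = rng.dirichlet([20, 1, 1, 1])
    return MixtureParams(pi0=w[0], pi_a=w[1], pi_b=w[2], pi_ab=w[3],
                         sigma_b2_a=rng.uniform(1e-5, 1e-3),
                         sigma_b2_b=rng.uniform(1e-5, 1e-3),
                         sigma0_2_a=rng.uniform(0.8, 1.3),
                         sigma0_2_b=rng.uniform(0.8, 1.3),
                         rho_beta=rng.uniform(-0.95, 0.95),
                         rho0=rng.uniform(-0.3, 0.3))


class TestLikelihood:
    def test_pure_null_closed_form(self):
        """With all causal weights zero and unit residuals the NLL is the
        standard bivariate normal's."""
        p = MixtureParams(pi0=1.0, pi_a=0.0, pi_b=0.0, pi_ab=0.0,
                          sigma_b2_a=1e-4, sigma_b2_b=1e-4,
                          sigma0_2_a=1.0, sigma0_2_b=1.0, rho_beta=0.0, rho0=0.0)
        rng = np.random.default_rng(0)
        z = rng.standard_normal((100, 2))
        expected = (np.log(2 * np.pi) + (z**2).sum(axis=1) / 2).sum()
        assert pair_neg_log_likelihood(p, z, 1e4, 1e4) == pytest.approx(expected,
                                                                        rel=1e-12)

    def test_matches_independent_density_oracle(self):
        """Mixture NLL equals a direct scipy multivariate-normal evaluation
        (independent oracle) to 1e-10 relative."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal((10, 2)) * 2
        for _ in range(5):
            p = random_params(rng)
            covs = p.component_covs(5e4, 8e4)
            dens = sum(w * stats.multivariate_normal(mean=[0, 0], cov=c).pdf(z)
                       for w, c in zip(p.weights, covs))
            oracle = -np.log(dens).sum()
            mine = pair_neg_log_likelihood(p, z, 5e4, 8e4)
            assert mine == pytest.approx(oracle, rel=1e-10)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            MixtureParams(pi0=0.5, pi_a=0.5, pi_b=0.1, pi_ab=0.1,
                          sigma_b2_a=1e-4, sigma_b2_b=1e-4, sigma0_2_a=1,
                          sigma0_2_b=1, rho_beta=0, rho0=0)

    def test_non_psd_component_rejected(self):
        p = MixtureParams(pi0=0.9, pi_a=0.0, pi_b=0.0, pi_ab=0.1,
                          sigma_b2_a=1e-4, sigma_b2_b=1e-4, sigma0_2_a=1,
                          sigma0_2_b=1, rho_beta=0.0, rho0=1.0)
        # rho0 = 1 makes the null covariance singular
        with pytest.raises(ValueError, match="positive definite"):
            p.component_covs(1e4, 1e4)


class TestPrune:
    def make_pair(self, ld):
        n = ld.n_snps
        return pd.DataFrame({"SNP": ld.snp_id, "CHR": ld.chrom, "BP": ld.pos,
                             "A1": "A", "A2": "G", "Z_A": 0.0, "Z_B": 0.0,
                             "N_A": 1e4, "N_B": 1e4, "P_A": 1.0, "P_B": 1.0})

    def test_identity_ld_keeps_all(self):
        ld = simulate_ld_blocks(10, 4, 0.0)
        pair = self.make_pair(ld)
        assert len(prune_for_fit(pair, ld, r2_max=0.1, seed=1)) == 40

    def test_strong_exchangeable_keeps_one_per_block(self):
        ld = simulate_ld_blocks(7, 6, 0.8)
        pair = self.make_pair(ld)
        assert len(prune_for_fit(pair, ld, r2_max=0.5, seed=1)) == 7

    def test_kept_set_satisfies_threshold_pairwise(self):
        ld = simulate_ld_blocks(4, 5, 0.31)  # r2 just below/above thresholds
        pair = self.make_pair(ld)
        kept = prune_for_fit(pair, ld, r2_max=0.09, seed=3)["SNP"].tolist()
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2(a, b) < 0.09


class TestNCausal90:
    def test_zero(self):
        assert n_causal_90(0) == 0

    def test_linearity(self):
        assert n_causal_90(2 * 137.0) == pytest.approx(2 * n_causal_90(137.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            n_causal_90(-1)

    def test_against_monte_carlo_order_statistics(self):
        """q* from the chi-square identity vs direct enumeration: draw 1e6
        chi2_1 effect variances and find the smallest top fraction whose sum
        reaches 90% of the total."""
        rng = np.random.default_rng(42)
        x = np.sort(rng.chisquare(1, size=1_000_000))[::-1]
        csum = np.cumsum(x)
        k = np.searchsorted(csum, 0.90 * csum[-1]) + 1
        assert k / x.size == pytest.approx(Q90, rel=0.01)


class TestVenn:
    def fake_fit(self, pi_a, pi_b, pi_ab):
        est = BivariateCausalMixture()
        est.params_ = MixtureParams(pi0=1 - pi_a - pi_b - pi_ab, pi_a=pi_a,
                                    pi_b=pi_b, pi_ab=pi_ab, sigma_b2_a=1e-4,
                                    sigma_b2_b=1e-4, sigma0_2_a=1.0,
                                    sigma0_2_b=1.0, rho_beta=0.5, rho0=0.0)
        return est

    def test_no_shared_component_gives_zero(self):
        v = venn_summary(self.fake_fit(1e-3, 1e-3, 0.0), 1_000_000)
        assert v["shared_k"] == 0.0

    def test_additivity_and_hand_arithmetic(self):
        m = 1_000_000
        v = venn_summary(self.fake_fit(2e-3, 1e-3, 3e-3), m)
        assert v["unique_a_k"] == pytest.approx(round(Q90 * 2e-3 * m / 1000, 1))
        assert v["shared_k"] == pytest.approx(round(Q90 * 3e-3 * m / 1000, 1))
        assert v["total_a_k"] == pytest.approx(v["unique_a_k"] + v["shared_k"], abs=0.2)


@pytest.fixture(scope="module")
def fitted_small():
    """One moderate no-LD fit shared by the fit-behaviour tests."""
    gp = GenerativeParams(m=30_000, n_blocks=30_000, block_size=1,
                          rho_within=0.0, pi_a=1e-3, pi_b=1e-3, pi_ab=2e-3,
                          rho_beta=0.9, sigma_b2_a=4e-4, sigma_b2_b=4e-4,
                          n_a=5e4, n_b=5e4, seed=202)
    sa, sb, _, _ = simulate_pair(gp)
    pair = harmonize_pair(sa, sb)
    est = fit_bivariate(pair, random_state=7)
    return gp, pair, est


class TestFit:
    def test_recovers_planted_overlap_roughly(self, fitted_small):
        gp, _, est = fitted_small
        assert est.params_.pi_ab * gp.m == pytest.approx(gp.pi_ab * gp.m, rel=0.5)
        assert np.sign(est.params_.rho_beta) == np.sign(gp.rho_beta)
        assert est.converged_

    def test_aic_identity(self, fitted_small):
        _, _, est = fitted_small
        assert est.aic_ == pytest.approx(2 * est.k_free_ + 2 * est.nll_)

    def test_deterministic_given_seed(self, fitted_small):
        gp, pair, est = fitted_small
        est2 = fit_bivariate(pair, random_state=7)
        assert est2.nll_ == est.nll_
        np.testing.assert_array_equal(est2.theta_, est.theta_)

    def test_constrained_nll_never_below_unconstrained(self, fitted_small):
        _, pair, est = fitted_small
        Z = pair[["Z_A", "Z_B"]].to_numpy()
        for fix in ({"pi_ab": 0.0}, {"pi_a": 0.0}):
            con = BivariateCausalMixture(n_starts=4, random_state=7)
            con.fit(Z, n_a=est.n_a_, n_b=est.n_b_, fix=fix)
            assert con.nll_ >= est.nll_ - 1e-6

    def test_implied_rg_close_to_generative(self, fitted_small):
        gp, _, est = fitted_small
        assert est.rg_implied() == pytest.approx(gp.rg(), abs=0.15)

    def test_model_vs_actual_qq_deterministic(self, fitted_small):
        _, pair, est = fitted_small
        m1, a1 = model_vs_actual_qq(est, pair, seed=3)
        m2, a2 = model_vs_actual_qq(est, pair, seed=3)
        pd.testing.assert_frame_equal(m1.table, m2.table)
        pd.testing.assert_frame_equal(a1.table, a2.table)

    def test_misfit_detected_in_model_qq(self, fitted_small):
        """Forcing pi12 = 0 on overlapping data separates the modelled
        conditional stratum from the actual one."""
        _, pair, est = fitted_small
        wrong = BivariateCausalMixture(n_starts=4, random_state=7)
        wrong.fit(pair[["Z_A", "Z_B"]].to_numpy(), n_a=est.n_a_, n_b=est.n_b_,
                  fix={"pi_ab": 0.0})
        qq_model, qq_actual = model_vs_actual_qq(wrong, pair, seed=5)
        sub_m = qq_model.stratum(0.001)
        sub_a = qq_actual.stratum(0.001)
        # actual conditioned tail is far above the zero-overlap model's
        assert sub_a["observed"].iloc[-1] > sub_m["observed"].iloc[-1] + 1.0

    def test_input_validation(self):
        est = BivariateCausalMixture()
        with pytest.raises(ValueError):
            est.fit(np.zeros((10, 3)), n_a=1e4, n_b=1e4)
        with pytest.raises(ValueError):
            est.fit(np.zeros((10, 2)), n_a=1e4, n_b=1e4, fix={"pi_ab": 0.5})
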