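import numpy as np
import pytest

import pathvc as pv
from conftest import design_matrix, pathway_kernel

from _oracles import naive_loglik


def small_problem(seed=0, n=20, two_kernels=False):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    K1 = A @ A.T / n
    K1 = K1 * (n / np.trace(K1))
    kernels = [K1]
    if two_kernels:
        B = rng.normal(size=(n, n))
        K2 = B @ B.T / n
        kernels.append(K2 * (n / np.trace(K2)))
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    return pv.MixedModelSpec(y, X, kernels, [f"K{i}" for i in range(len(kernels))])


class TestProfileLoglik:
    def test_closed_form_two_point_gaussian(self):
        # n=2, y=0, V=I: density is (2*pi)^-1 -> loglik = -log 2*pi
        spec = pv.MixedModelSpec(np.zeros(2), np.ones((2, 1)), [np.eye(2)], ["k"])
        ll = pv.profile_loglik(np.array([0.4, 0.6]), spec)
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_identity_kernel_ridge_nonidentifiability(self):
        # with K = I the likelihood depends only on the total variance
        rng = np.random.default_rng(1)
        n = 15
        spec = pv.MixedModelSpec(
            rng.normal(size=n), np.ones((n, 1)), [np.eye(n)], ["id"]
        )
        lls = [
            pv.profile_loglik(np.array([a, 2.0 - a]), spec) for a in (0.1, 0.9, 1.7)
        ]
        assert np.ptp(lls) < 1e-10

    @pytest.mark.parametrize("two_kernels", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agreement_with_naive_dense_oracle(self, seed, two_kernels):
        spec = small_problem(seed, two_kernels=two_kernels)
        rng = np.random.default_rng(seed + 100)
        for _ in range(3):
            theta = rng.uniform(0.2, 2.0, size=spec.n_components)
            expected = naive_loglik(theta, spec.y, spec.X, spec.kernels)
            assert pv.profile_loglik(theta, spec) == pytest.approx(expected, abs=1e-8)

    def test_permutation_invariance(self):
        spec = small_problem(3, two_kernels=True)
        rng = np.random.default_rng(4)
        perm = rng.permutation(spec.n)
        theta = np.array([0.5, 0.7, 0.9])
        spec_p = pv.MixedModelSpec(
            spec.y[perm], spec.X[perm], [K[np.ix_(perm, perm)] for K in spec.kernels]
        )
        assert pv.profile_loglik(theta, spec_p) == pytest.approx(
            pv.profile_loglik(theta, spec), abs=1e-9
        )

    def test_wrong_parameter_count_rejected(self):
        spec = small_problem(5)
        with pytest.raises(ValueError, match="variance parameters"):
            pv.profile_loglik(np.array([1.0]), spec)


class TestFitMl:
    def test_eig_and_dense_routes_agree_on_single_kernel(self):
        spec = small_problem(7)
        fit = pv.fit_ml(spec)  # internally uses the eigen fast path
        # dense check at the optimum
        assert pv.profile_loglik(fit.sigma2, spec) == pytest.approx(
            fit.loglik, abs=1e-6
        )
        assert fit.converged

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        cfg = pv.SimConfig(n_families=4, n_probes=5, trait_heritability=0.5,
                           n_replicates=1, seed=11)
        study = pv.simulate_study(cfg)
        X = design_matrix(study)
        y = study.phenotypes[0]
        f1 = pv.fit_ml(pv.MixedModelSpec(y, X, [study.kinship.Phi2], ["kin"]))
        f2 = pv.fit_ml(pv.MixedModelSpec(10 * y, X, [study.kinship.Phi2], ["kin"]))
        assert f2.sigma2 == pytest.approx(100 * f1.sigma2, rel=1e-3)
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-4)

    def test_heritability_recovery_h2_half(self):
        """Mean fitted h2 over replicates near the simulated 0.5."""
        cfg = pv.SimConfig(
            n_families=20, sibs_per_mating=2, n_probes=2,
            trait_heritability=0.5, n_replicates=40, seed=21,
        )
        study = pv.simulate_study(cfg)
        X = design_matrix(study)
        h2s = [
            pv.fit_ml(
                pv.MixedModelSpec(study.phenotypes[r], X, [study.kinship.Phi2], ["kin"])
            ).h2
            for r in range(cfg.n_replicates)
        ]
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.06)

    def test_pure_noise_h2_near_zero(self):
        cfg = pv.SimConfig(
            n_families=10, n_probes=2, trait_heritability=0.0,
            n_replicates=20, seed=22,
        )
        study = pv.simulate_study(cfg)
        X = design_matrix(study)
        h2s = [
            pv.fit_ml(
                pv.MixedModelSpec(study.phenotypes[r], X, [study.kinship.Phi2], ["kin"])
            ).h2
            for r in range(cfg.n_replicates)
        ]
        assert np.median(h2s) <= 0.1


class TestLrt:
    def _fit_with_loglik(self, ll, n_kernels=1):
        return pv.VarCompFit(
            beta=np.zeros(1),
            sigma2=np.ones(n_kernels + 1),
            component_names=["k"] * n_kernels + ["residual"],
            loglik=ll,
            converged=True,
            n_iter=1,
        )

    def test_equal_likelihoods_give_half(self):
        res = pv.lrt(self._fit_with_loglik(-10.0), self._fit_with_loglik(-10.0, 2))
        assert res.statistic == 0.0
        assert res.p_value == 0.5

    def test_boundary_mixture_critical_value(self):
        # Lambda = 2.706 is the chi2_1 upper 10% point; halved -> p = 0.05
        res = pv.lrt(
            self._fit_with_loglik(-10.0), self._fit_with_loglik(-10.0 + 2.706 / 2, 2)
        )
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_naive_chi2_mode(self):
        res = pv.lrt(
            self._fit_with_loglik(-10.0),
            self._fit_with_loglik(-10.0 + 2.706 / 2, 2),
            null_distribution="chi2_1",
        )
        assert res.p_value == pytest.approx(0.10, abs=1e-3)

    def test_negative_improvement_clipped_to_zero(self):
        res = pv.lrt(self._fit_with_loglik(-10.0), self._fit_with_loglik(-10.5, 2))
        assert res.statistic == 0.0

    def test_mismatched_phenotypes_rejected(self):
        spec_a = small_problem(30)
        spec_b = small_problem(31, two_kernels=True)
        fa, fb = pv.fit_ml(spec_a), pv.fit_ml(spec_b)
        with pytest.raises(ValueError, match="phenotype"):
            pv.lrt(fa, fb)

    def test_alternative_never_below_null(self):
        """Warm-started alternative keeps the LRT statistic non-negative."""
        cfg = pv.SimConfig(n_families=5, n_probes=10, trait_heritability=0.33,
                           n_replicates=5, seed=33)
        study = pv.simulate_study(cfg)
        sim = pathway_kernel(study)
        X = design_matrix(study)
        for r in range(5):
            nf, af = pv.fit_null_and_alternative(
                study.phenotypes[r], X, study.kinship.Phi2, sim.S
            )
            assert af.loglik >= nf.loglik - 1e-6


class TestVarianceExplained:
    def test_proportions(self):
        fit = pv.VarCompFit(
            beta=np.zeros(1),
            sigma2=np.array([1.0, 1.0, 2.0]),
            component_names=["kinship", "pathway", "residual"],
            loglik=0.0,
            converged=True,
            n_iter=1,
        )
        out = pv.variance_explained(fit)
        assert out == {"kinship": 0.25, "pathway": 0.25, "residual": 0.5}
        assert sum(out.values()) == pytest.approx(1.0)

    def test_boundary_component_zero_proportion(self):
        fit = pv.VarCompFit(
            beta=np.zeros(1),
            sigma2=np.array([0.5, 0.0, 0.5]),
            component_names=["kinship", "pathway", "residual"],
            loglik=0.0,
            converged=True,
            n_iter=1,
        )
        assert pv.variance_explained(fit)["pathway"] == 0.0
        assert fit.pathway_var == 0.0


class TestCalibrationAndPower:
    def test_type_i_error_controlled_across_alphas(self, null_calibration):
        """Null-trait rejection rates never exceed the nominal level.

        The boundary-mixture reference is conservative in finite samples
        (the point mass of the LRT at zero exceeds one half when the pathway
        kernel partly overlaps kinship), so the empirical size is checked
        against the upper 99% binomial bound at every alpha, and two-sided
        at the working level 0.05.
        """
        from scipy.stats import binom

        p = null_calibration["p_values"]
        n = null_calibration["n_replicates"]
        for alpha in (0.01, 0.05, 0.10):
            k = int((p < alpha).sum())
            _, hi = binom.interval(0.99, n, alpha)
            assert k <= hi, f"alpha={alpha}: {k} rejections exceed {hi}"
        k05 = int((p < 0.05).sum())
        lo, hi = binom.interval(0.99, n, 0.05)
        assert lo <= k05 <= hi

    def test_power_monotone_in_pathway_effect(self):
        """Rejection rate grows with the simulated pathway variance share."""
        cfg = pv.SimConfig(n_families=10, n_probes=15, trait_heritability=0.0,
                           n_replicates=1, seed=44)
        study = pv.simulate_study(cfg)
        sim = pathway_kernel(study)
        X = design_matrix(study)
        n = len(study.pedigree)
        rng = np.random.default_rng(45)
        n_reps = 40
        rates = []
        for share in (0.0, 0.15, 0.35):
            V = share * sim.S + 0.2 * study.kinship.Phi2 + (0.8 - share) * np.eye(n)
            L = np.linalg.cholesky(V)
            hits = 0
            for _ in range(n_reps):
                y = L @ rng.standard_normal(n)
                nf, af = pv.fit_null_and_alternative(y, X, study.kinship.Phi2, sim.S)
                hits += pv.lrt(nf, af).p_value < 0.05
            rates.append(hits / n_reps)
        slack = 0.1  # Monte-Carlo slack at 40 replicates
        assert rates[1] >= rates[0] - slack
        assert rates[2] >= rates[1] - slack
        assert rates[2] > rates[0]
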