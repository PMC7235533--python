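"""GLM hierarchy: activation, likelihoods, baseline, GP-MAP block fits."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from spikevar import (
    KernelSpec,
    ModelParams,
    SpikeRaster,
    activation,
    activation_matrix,
    build_design,
    fit_baseline,
    fit_map_block,
    generate_stimulus,
    poisson_loglik,
    saturated_loglik,
)
from spikevar.glm import LEVELS


def _raster(counts):
    return SpikeRaster(counts=np.asarray(counts), delta_t=0.04)


def _params(K, m, T, **kw):
    p = ModelParams.zeros(K, m, T)
    for key, val in kw.items():
        setattr(p, key, np.asarray(val, dtype=float) if key != "b0" else float(val))
    return p


class TestActivation:
    def test_baseline_level_is_constant(self):
        p = _params(2, 3, 4, b0=-1.2)
        z = activation_matrix(p, None, 2, 4)
        assert np.allclose(z, -1.2)

    def test_blocks_add(self):
        p = _params(2, 3, 4, b0=0.5, phi=[0.1, -0.1], rho=[0, 1, 2, 3])
        assert activation(p, None, 1, 2) == pytest.approx(0.5 - 0.1 + 2.0)

    def test_two_tap_dot_product(self):
        # b0=0, k=(1,-1), stimulus history (3, 2) -> z = 3 - 2 = 1
        stim = generate_stimulus(1, 4, 0.0, 1.0, 1.0, seed=0)
        stim.amplitudes[:] = [[2.0, 3.0, 5.0, 7.0]]
        design = build_design(stim, m=2, standardize=False)
        p = _params(1, 2, 4, k=[1.0, -1.0])
        assert activation(p, design, 0, 1) == pytest.approx(3.0 - 2.0)

    def test_index_out_of_range(self):
        p = _params(1, 2, 3)
        with pytest.raises(IndexError):
            activation(p, None, 0, 3)


class TestPoissonLoglik:
    def test_matches_exact_pmf_on_toy_rasters(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            counts = rng.poisson(1.0, size=(3, 4))
            p = _params(
                3, 2, 4,
                b0=rng.normal(), phi=rng.normal(size=3) * 0.5, rho=rng.normal(size=4) * 0.5,
            )
            z = activation_matrix(p, None, 3, 4)
            oracle = poisson.logpmf(counts, np.exp(z)).sum()
            assert poisson_loglik(p, _raster(counts)) == pytest.approx(oracle, abs=1e-10)

    def test_zero_raster_closed_form(self):
        mu = 0.37
        p = _params(2, 1, 5, b0=np.log(mu))
        assert poisson_loglik(p, _raster(np.zeros((2, 5)))) == pytest.approx(-2 * 5 * mu)

    def test_rate_equal_counts_attains_saturated_bound(self):
        from scipy.special import gammaln

        counts = np.array([[1, 2, 3], [4, 1, 2]])
        raster = _raster(counts)
        # a per-bin rate equal to the counts maximizes the LL: perturbing the
        # log-rates in any direction can only lower it
        z = np.log(counts.astype(float))
        ll = (counts * z - counts - gammaln(counts + 1.0)).sum()
        assert saturated_loglik(raster) == pytest.approx(ll, abs=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(5):
            dz = rng.normal(scale=0.1, size=counts.shape)
            ll_pert = (counts * (z + dz) - np.exp(z + dz) - gammaln(counts + 1.0)).sum()
            assert ll_pert <= saturated_loglik(raster) + 1e-12

    def test_clipping_warns(self):
        p = _params(1, 1, 2, b0=100.0)
        with pytest.warns(RuntimeWarning, match="clipped"):
            poisson_loglik(p, _raster([[0, 0]]))


class TestSaturated:
    def test_all_zero_raster_gives_zero(self):
        assert saturated_loglik(_raster(np.zeros((3, 4)))) == 0.0

    def test_single_bin_direct_value(self):
        assert saturated_loglik(_raster([[2]])) == pytest.approx(2 * np.log(2) - 2 - np.log(2))

    def test_dominates_any_model_loglik(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            counts = rng.poisson(0.8, size=(3, 6))
            raster = _raster(counts)
            p = _params(
                3, 1, 6,
                b0=rng.normal(scale=0.5),
                phi=rng.normal(size=3) * 0.3,
                rho=rng.normal(size=6) * 0.3,
            )
            assert saturated_loglik(raster) >= poisson_loglik(p, raster)


class TestBaseline:
    def test_mean_count_closed_form(self):
        # 900 spikes over 36 trials x 2500 bins -> 0.01 counts/bin
        counts = np.zeros((36, 2500), dtype=int)
        idx = np.random.default_rng(0).choice(36 * 2500, size=900, replace=False)
        counts.ravel()[idx] = 1
        p = fit_baseline(_raster(counts))
        assert np.exp(p.b0) == pytest.approx(0.01)

    def test_zero_spikes_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floored"):
            p = fit_baseline(_raster(np.zeros((2, 10))))
        assert np.exp(p.b0) == pytest.approx(1.0 / (10 * 20))

    def test_maximizes_constant_model_loglik(self):
        counts = np.random.default_rng(5).poisson(0.6, size=(4, 30))
        raster = _raster(counts)
        p = fit_baseline(raster)

        def neg_ll(b0):
            q = _params(4, 1, 30, b0=b0)
            return -poisson_loglik(q, raster)

        opt = minimize_scalar(neg_ll, bounds=(-10, 5), method="bounded")
        assert p.b0 == pytest.approx(opt.x, abs=1e-5)


class TestMapBlockFit:
    def test_zero_scale_prior_pins_block(self):
        raster = _raster(np.random.default_rng(0).poisson(0.5, size=(3, 20)))
        base = fit_baseline(raster)
        fit = fit_map_block(raster, None, base, "phi", KernelSpec("matern", 0.0, length=5.0))
        assert (fit.phi == 0).all() and fit.level == "NS"

    def test_weak_prior_single_trial_recovers_trial_mean(self):
        counts = np.random.default_rng(1).poisson(1.2, size=(1, 500))
        raster = _raster(counts)
        base = fit_baseline(raster)
        fit = fit_map_block(
            raster, None, base, "phi", KernelSpec("matern", 1e3, length=1.0)
        )
        assert fit.b0 + fit.phi[0] == pytest.approx(np.log(counts.mean()), abs=1e-3)

    def test_weak_prior_filter_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        stim = generate_stimulus(4, 200, frozen_fraction=1.0, seed=4)
        design = build_design(stim, m=5)
        rng = np.random.default_rng(4)
        k_true = np.array([0.4, 0.2, 0.0, -0.2, -0.1])
        mu = np.exp(-1.0 + design.X @ k_true)
        counts = rng.poisson(np.broadcast_to(mu, (4, 200)))
        raster = _raster(counts)
        base = fit_baseline(raster)
        fit = fit_map_block(
            raster, design, base, "k", KernelSpec("matern", 1e3, length=1.0)
        )
        Xrep = np.tile(design.X, (4, 1))
        sm_fit = sm.GLM(
            counts.ravel(), Xrep, family=sm.families.Poisson(),
            offset=np.full(counts.size, base.b0),
        ).fit()
        assert np.allclose(fit.k, sm_fit.params, atol=2e-3)

    def test_map_matches_dense_newton_for_ar1_rho(self):
        # banded AR(1) precision solve vs an explicit dense-covariance Newton
        T, K = 150, 3
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.7, size=(K, T))
        raster = _raster(counts)
        base = fit_baseline(raster)
        prior = KernelSpec("ar1", 0.5, corr=0.9, jitter=0.0)
        fit = fit_map_block(raster, None, base, "rho", prior, tol=1e-12)

        from spikevar.kernels import kernel_matrix

        P = np.linalg.inv(kernel_matrix(prior, T))

        def obj(r):
            z = base.b0 + r[None, :]
            return (counts * z - np.exp(z)).sum() - 0.5 * r @ P @ r

        rho = np.zeros(T)
        f = obj(rho)
        for _ in range(500):
            mu = np.exp(base.b0 + rho[None, :])
            g = (counts - mu).sum(axis=0) - P @ rho
            H = np.diag(mu.sum(axis=0)) + P
            step = np.linalg.solve(H, g)
            alpha = 1.0
            while obj(rho + alpha * step) < f and alpha > 1e-10:
                alpha *= 0.5
            rho = rho + alpha * step
            f = obj(rho)
            if np.abs(alpha * step).max() < 1e-12:
                break
        assert np.allclose(fit.rho, rho, atol=1e-6)

    def test_shrinkage_is_monotone_in_prior_scale(self):
        stim = generate_stimulus(4, 300, frozen_fraction=1.0, seed=9)
        design = build_design(stim, m=5)
        rng = np.random.default_rng(9)
        mu = np.exp(-1.0 + design.X @ np.array([0.5, 0.3, 0.0, -0.3, -0.2]))
        raster = _raster(rng.poisson(np.broadcast_to(mu, (4, 300))))
        base = fit_baseline(raster)
        norms = []
        for scale in (3.0, 1.0, 0.3, 0.1, 0.03):
            fit = fit_map_block(raster, design, base, "k", KernelSpec("matern", scale, length=2.0))
            norms.append(np.linalg.norm(fit.k))
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_nesting_zero_blocks_reproduce_predecessor(self):
        p_bs = _params(2, 3, 4, b0=-0.7)
        p_ns = ModelParams(b0=-0.7, phi=np.zeros(2), k=np.zeros(3), rho=np.zeros(4), level="NS")
        for lvl_params in (p_bs, p_ns):
            assert np.allclose(
                activation_matrix(lvl_params, None, 2, 4),
                activation_matrix(p_bs, None, 2, 4),
            )

    def test_parameter_recovery_at_study_scale(self):
        # NS-LNP truth: drift sd 0.5 + biphasic filter, 18 trials x 2500 bins
        from spikevar import draw_ground_truth, simulate_raster

        truth = draw_ground_truth(
            18, 2500, 25,
            phi_kernel=KernelSpec("matern", 0.5, length=5.0),
            rho_kernel=KernelSpec("ar1", 0.0, corr=0.9),
            seed=17,
        )
        stim = generate_stimulus(18, 2500, frozen_fraction=1.0, seed=17)
        raster = simulate_raster(truth, stim, seed=17)
        design = build_design(stim, m=25)
        base = fit_baseline(raster)
        with_phi = fit_map_block(
            raster, design, base, "phi", KernelSpec("matern", 1.0, length=5.0),
            trial_index=raster.trial_ids,
        )
        with_k = fit_map_block(
            raster, design, with_phi, "k", KernelSpec("matern", 1.0, length=5.0)
        )
        assert np.corrcoef(with_k.k, truth.filter_k)[0, 1] >= 0.9
        assert np.corrcoef(with_phi.phi, truth.phi)[0, 1] >= 0.8
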