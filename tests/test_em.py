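"""E-step, M-step and full EM behaviour."""

import math

import numpy as np
import pytest

from chromclust import (
    ChromatinDataset,
    Hyperparameters,
    MixtureModel,
    ShiftFlipConfig,
    default_alpha_fixtures,
    e_step,
    extract_window,
    fit,
    initialize,
    log_dirichlet_multinomial,
    m_step_alpha,
    m_step_weights,
    observed_log_likelihood,
    simulate_dmm,
)
from chromclust.em import (
    ResponsibilityTensor,
    _block_neg_objective,
    _block_stats,
    _caches,
    _loglik_tensor,
)


def _bruteforce_responsibilities(dataset, model):
    """Enumerate (k, s, f) per locus with scalar DM calls; normalise directly."""
    cfg = model.config
    S, L = cfg.n_shift_states, dataset.n_bins
    N, K = dataset.n_loci, model.n_components
    R = np.zeros((N, K, S, 2))
    for i in range(N):
        for k in range(K):
            for s in range(1, S + 1):
                for f in (1, 2):
                    p = model.pi[k] * model.xi[i, s - 1] * model.zeta[i, f - 1]
                    if p == 0:
                        continue
                    ll = 0.0
                    for m in range(dataset.n_features):
                        w = extract_window(model.alpha[k, m], s, f, L)
                        ll += log_dirichlet_multinomial(dataset.counts[m][i], w)
                    R[i, k, s - 1, f - 1] = p * math.exp(ll - 0)
        R[i] /= R[i].sum()
    return R


def _toy_model(dataset, K=2, shift=False, flip=False, seed=0):
    rng = np.random.default_rng(seed)
    cfg = ShiftFlipConfig(shift_enabled=shift, flip_enabled=flip,
                          max_shift_bp=40 if shift else 0, bin_size=40)
    S = cfg.n_shift_states
    L_ext = cfg.extended_length(dataset.n_bins)
    alpha = rng.gamma(2.0, 1.0, size=(K, dataset.n_features, L_ext)) + 0.2
    xi = np.tile(np.full(S, 1 / S), (dataset.n_loci, 1))
    zeta_row = [0.5, 0.5] if flip else [1.0, 0.0]
    zeta = np.tile(zeta_row, (dataset.n_loci, 1))
    pi = rng.dirichlet(np.ones(K))
    return MixtureModel(alpha=alpha, pi=pi, xi=xi, zeta=zeta, config=cfg)


class TestEStep:
    def test_single_component_no_alignment(self, tiny_dataset):
        model = _toy_model(tiny_dataset, K=1)
        resp = e_step(tiny_dataset, model)
        np.testing.assert_allclose(resp.values[:, 0, 0, 0], 1.0)

    def test_identical_components_split_evenly(self, tiny_dataset):
        model = _toy_model(tiny_dataset, K=2)
        model.alpha[1] = model.alpha[0]
        model.pi = np.array([0.5, 0.5])
        resp = e_step(tiny_dataset, model)
        np.testing.assert_allclose(resp.cluster_marginals, 0.5, atol=1e-12)

    @pytest.mark.parametrize("shift, flip", [(False, False), (True, True)])
    def test_matches_bruteforce_enumeration(self, tiny_dataset, shift, flip):
        model = _toy_model(tiny_dataset, K=2, shift=shift, flip=flip, seed=3)
        resp = e_step(tiny_dataset, model)
        expected = _bruteforce_responsibilities(tiny_dataset, model)
        np.testing.assert_allclose(resp.values, expected, atol=1e-10)


class TestMStepWeights:
    def test_point_and_uniform_cases(self):
        r = np.zeros((3, 2, 1, 2))
        r[:, 0, 0, 0] = 1.0
        np.testing.assert_allclose(
            m_step_weights(ResponsibilityTensor(r)), [1.0, 0.0])
        u = np.full((4, 2, 1, 2), 0.25)
        u[..., 1] = 0.0
        u *= 2
        np.testing.assert_allclose(
            m_step_weights(ResponsibilityTensor(u / u.sum(axis=(1, 2, 3), keepdims=True))),
            [0.5, 0.5])

    def test_matches_independent_loop(self, rng):
        r = rng.dirichlet(np.ones(12), size=5).reshape(5, 2, 3, 2)
        pi = m_step_weights(ResponsibilityTensor(r))
        for k in range(2):
            expected = sum(r[i, k].sum() for i in range(5)) / 5
            assert pi[k] == pytest.approx(expected, rel=1e-12)
        assert pi.sum() == pytest.approx(1.0)


class TestMStepAlpha:
    def test_block_objective_gradient_finite_differences(self, tiny_dataset, rng):
        """Analytic lambda-gradient vs central differences, shift+flip on."""
        model = _toy_model(tiny_dataset, K=2, shift=True, flip=True, seed=5)
        resp = e_step(tiny_dataset, model)
        caches = _caches(tiny_dataset)
        cfg = model.config
        stats = _block_stats(caches[0], resp.values[:, 0], tiny_dataset.n_bins,
                             cfg.n_shift_states,
                             cfg.extended_length(tiny_dataset.n_bins), True)
        hyper = Hyperparameters()
        lam = rng.normal(0.3, 0.4, size=model.extended_length)
        _, grad = _block_neg_objective(lam, stats, hyper)
        eps = 1e-6
        for j in range(lam.size):
            up, dn = lam.copy(), lam.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (_block_neg_objective(up, stats, hyper)[0]
                  - _block_neg_objective(dn, stats, hyper)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=2e-5, abs=1e-6)

    def test_block_objective_equals_direct_sum(self, tiny_dataset):
        """Histogram-condensed objective == loop over loci, states, features."""
        model = _toy_model(tiny_dataset, K=2, shift=True, flip=True, seed=7)
        resp = e_step(tiny_dataset, model)
        caches = _caches(tiny_dataset)
        cfg = model.config
        L = tiny_dataset.n_bins
        S = cfg.n_shift_states
        hyper = Hyperparameters(eta=1.1, nu=0.1, eta_h=None, nu_h=None)
        k, m = 1, 0
        stats = _block_stats(caches[m], resp.values[:, k], L, S,
                             cfg.extended_length(L), True)
        lam = np.log(model.alpha[k, m])
        neg_obj, _ = _block_neg_objective(lam, stats, hyper)
        direct = 0.0
        for i in range(tiny_dataset.n_loci):
            x = tiny_dataset.counts[m][i]
            coef = (math.lgamma(x.sum() + 1)
                    - sum(math.lgamma(v + 1) for v in x))
            for s in range(1, S + 1):
                for f in (1, 2):
                    w = extract_window(model.alpha[k, m], s, f, L)
                    direct += resp.values[i, k, s - 1, f - 1] * (
                        log_dirichlet_multinomial(x, w) - coef)
        a = model.alpha[k, m]
        direct += np.sum((hyper.eta - 1) * lam - hyper.nu * a) + lam.sum()
        assert -neg_obj == pytest.approx(direct, rel=1e-10)

    def test_tracks_empirical_proportions_with_weak_prior(self):
        # responsibilities concentrated on loci drawn from one smooth profile
        profile = np.array([1.0, 2.0, 5.0, 2.0, 1.0])
        p_true = profile / profile.sum()
        rng = np.random.default_rng(0)
        X = rng.multinomial(400, p_true, size=40)
        ds = ChromatinDataset(counts=[X])
        cfg = ShiftFlipConfig()
        model = MixtureModel(alpha=np.ones((1, 1, 5)), pi=[1.0],
                             xi=np.ones((40, 1)), zeta=np.tile([1.0, 0.0], (40, 1)),
                             config=cfg)
        resp = e_step(ds, model)
        weak = Hyperparameters(eta=1.0, nu=1e-4, eta_h=None, nu_h=None)
        alpha = m_step_alpha(ds, resp, model, weak)
        p_hat = alpha[0, 0] / alpha[0, 0].sum()
        assert np.abs(p_hat - p_true).max() < 0.05

    def test_strong_smoothing_flattens_alpha(self, two_cluster_dataset):
        ds, _ = two_cluster_dataset
        model, resp = initialize(ds, 2, ShiftFlipConfig(),
                                 Hyperparameters(eta_h=None, nu_h=None), seed=1)
        loose = m_step_alpha(ds, resp, model, Hyperparameters(eta_h=None, nu_h=None))
        # mean 1, variance 1e-4 => shape = rate = 1e4: h is pinned near 1
        tight = m_step_alpha(ds, resp, model, Hyperparameters(eta_h=1e4, nu_h=1e4))
        for k in range(2):
            for m in range(2):
                assert np.ptp(tight[k, m]) < np.ptp(loose[k, m])


class TestInitialize:
    def test_k_exceeding_n_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            initialize(tiny_dataset, 5, ShiftFlipConfig(), Hyperparameters(), seed=0)

    def test_single_cluster_memberships(self, tiny_dataset):
        _, resp = initialize(tiny_dataset, 1, ShiftFlipConfig(),
                             Hyperparameters(), seed=0)
        np.testing.assert_allclose(resp.cluster_marginals, 1.0)

    def test_separated_clusters_recovered_by_soft_kmeans(self, two_cluster_dataset):
        ds, truth = two_cluster_dataset
        _, resp = initialize(ds, 2, ShiftFlipConfig(), Hyperparameters(), seed=0)
        hard = resp.cluster_marginals.argmax(axis=1) + 1
        agree = max(np.mean(hard == truth.labels), np.mean(hard != truth.labels))
        assert agree >= 0.9

    def test_same_seed_identical(self, two_cluster_dataset):
        ds, _ = two_cluster_dataset
        m1, r1 = initialize(ds, 2, ShiftFlipConfig(), Hyperparameters(), seed=4)
        m2, r2 = initialize(ds, 2, ShiftFlipConfig(), Hyperparameters(), seed=4)
        np.testing.assert_array_equal(m1.alpha, m2.alpha)
        np.testing.assert_array_equal(r1.values, r2.values)


class TestFit:
    def test_single_component_degenerate(self, tiny_dataset):
        res = fit(tiny_dataset, 1, seed=0, max_iter=50)
        assert res.converged
        np.testing.assert_allclose(res.model.pi, [1.0])
        assert res.n_iterations <= 10

    def test_monotone_lower_bound_and_normalised_responsibilities(self):
        alpha = default_alpha_fixtures(12, 1)
        ds, _ = simulate_dmm(alpha, [0.6, 0.4], [30], 60, seed=2)
        res = fit(ds, 2, seed=5, max_iter=80)
        tr = np.asarray(res.lower_bound_trace)
        assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[1:]))
        sums = res.responsibilities.values.sum(axis=(1, 2, 3))
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_determinism_same_seed_same_trace(self):
        alpha = default_alpha_fixtures(10, 1)
        ds, _ = simulate_dmm(alpha, [0.5, 0.5], [40], 50, seed=3)
        r1 = fit(ds, 2, seed=17, max_iter=40)
        r2 = fit(ds, 2, seed=17, max_iter=40)
        assert r1.lower_bound_trace == r2.lower_bound_trace
        np.testing.assert_array_equal(r1.model.alpha, r2.model.alpha)

    def test_recovers_separated_clusters(self, two_cluster_dataset):
        from chromclust import clustering_auc
        ds, truth = two_cluster_dataset
        res = fit(ds, 2, seed=1, max_iter=100)
        assert clustering_auc(truth.labels, res.responsibilities) >= 0.95

    def test_loglik_field_matches_reevaluation(self, two_cluster_dataset):
        ds, _ = two_cluster_dataset
        res = fit(ds, 2, seed=1, max_iter=60)
        assert res.log_likelihood == pytest.approx(
            observed_log_likelihood(ds, res.model), abs=1e-8)

    def test_invalid_controls(self, tiny_dataset):
        with pytest.raises(ValueError):
            fit(tiny_dataset, 1, max_iter=0)
        with pytest.raises(ValueError):
            fit(tiny_dataset, 1, tol=-1.0)


class TestLoglikTensorAgainstScalarPath:
    def test_tensor_matches_locus_loop(self, tiny_dataset):
        model = _toy_model(tiny_dataset, K=2, shift=True, flip=True, seed=11)
        ll = _loglik_tensor(tiny_dataset, model)
        cfg = model.config
        for i in (0, 2):
            for k in range(2):
                for s in (1, cfg.n_shift_states):
                    for f in (1, 2):
                        expected = sum(
                            log_dirichlet_multinomial(
                                tiny_dataset.counts[m][i],
                                extract_window(model.alpha[k, m], s, f,
                                               tiny_dataset.n_bins))
                            for m in range(2))
                        assert ll[i, k, s - 1, f - 1] == pytest.approx(expected, rel=1e-10)
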