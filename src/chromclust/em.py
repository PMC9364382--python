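"""MAP-EM fitting of the shift/flip-aware product Dirichlet-multinomial mixture.

The latent state of a locus is the triple (cluster k, shift state s, flip
state f); the E-step fills an N x K x S x 2 responsibility tensor by Bayes'
rule from the product-DM likelihood of each (k, s, f) window times the priors
pi, xi, zeta, with all products done via log-sum-exp.  The M-step updates the
mixture weights in closed form and maximises the expected complete-data log
posterior over lambda = log(alpha) with BFGS, one (component, feature) block
at a time — the objective is separable across blocks given responsibilities.

Because bin counts are small integers, the per-block objective is condensed
once per M-step into weighted histograms over count values at each extended
parameter position; each BFGS objective/gradient evaluation then costs
O(L_ext * max_count) log-gamma/digamma calls instead of a pass over all loci
and shift states.  The generalized-EM contract is enforced explicitly: a
block update is kept only if it does not decrease its objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp, softmax
from sklearn.cluster import KMeans

from .core_model import (
    LAMBDA_CLIP,
    ChromatinDataset,
    Hyperparameters,
    MixtureModel,
    ShiftFlipConfig,
    _log_prior_alpha_array,
    _prior_grad_alpha_block,
    gamma_logpdf,
    smoothness_term,
)
from .shift_flip import (
    hard_assign_all,
    pyramid_shift_prior,
    uniform_shift_prior,
    window_positions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResponsibilityTensor",
    "FitResult",
    "initialize",
    "e_step",
    "m_step_weights",
    "m_step_alpha",
    "fit",
    "observed_log_likelihood",
]

_H_FLOOR = 1e-12  # roughness floor inside the optimizer; keeps log Gamma(h) finite


@dataclass
class ResponsibilityTensor:
    """Posterior membership probabilities E[z_iksf], N x K x S x 2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != 2:
            raise ValueError("responsibilities must have shape (N, K, S, 2)")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        sums = self.values.sum(axis=(1, 2, 3))
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("responsibilities must sum to 1 per locus")

    @property
    def cluster_marginals(self) -> np.ndarray:
        """N x K marginal membership E[z_ik], shift and flip summed out."""
        return self.values.sum(axis=(2, 3))


@dataclass
class FitResult:
    """A converged (or iteration-capped) EM fit."""

    model: MixtureModel
    responsibilities: ResponsibilityTensor
    lower_bound_trace: list
    n_iterations: int
    converged: bool
    log_posterior: float
    log_likelihood: float
    assignments: list
    seed: int


class _FeatureCache:
    """Per-feature count statistics reused across EM iterations."""

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=np.int64)
        N, L = self.X.shape
        self.n = self.X.sum(axis=1)
        self.logcoef = gammaln(self.n + 1) - gammaln(self.X + 1).sum(axis=1)
        self.cmax = int(self.X.max(initial=0))
        self.carr = np.arange(self.cmax + 1)
        self.uniq_n, self.inv_n = np.unique(self.n, return_inverse=True)
        self._indicator = None

    @property
    def indicator(self) -> sparse.csr_matrix:
        """Sparse N x (L * (cmax+1)) one-hot of (bin, count value) pairs."""
        if self._indicator is None:
            N, L = self.X.shape
            C1 = self.cmax + 1
            cols = (np.arange(L)[None, :] * C1 + self.X).ravel()
            rows = np.repeat(np.arange(N), L)
            data = np.ones(N * L)
            self._indicator = sparse.csr_matrix(
                (data, (rows, cols)), shape=(N, L * C1)
            )
        return self._indicator


def _caches(dataset: ChromatinDataset) -> list:
    return [_FeatureCache(X) for X in dataset.counts]


def _window_sums(a: np.ndarray, L: int, S: int) -> np.ndarray:
    """Sliding sums A_s = sum(a[s-1 : s-1+L]) for s = 1..S (flip-invariant)."""
    cs = np.concatenate(([0.0], np.cumsum(a)))
    return cs[L: L + S] - cs[:S]


def _loglik_tensor(dataset: ChromatinDataset, model: MixtureModel,
                   caches: Optional[list] = None) -> np.ndarray:
    """Sum over features of log DM(x_i^(m) | window(alpha_k^(m), s, f)).

    Shape (N, K, S, 2).  When flipping is disabled the f=2 slice duplicates
    f=1 (its prior mass is zero, so it never contributes downstream).
    """
    if caches is None:
        caches = _caches(dataset)
    cfg = model.config
    N, L = dataset.n_loci, dataset.n_bins
    K, S = model.n_components, cfg.n_shift_states
    flips = (1, 2) if cfg.flip_enabled else (1,)
    jidx = np.arange(L)[None, :]
    out = np.zeros((N, K, S, 2))
    for k in range(K):
        for m, cache in enumerate(caches):
            a = model.alpha[k, m]
            A = _window_sums(a, L, S)
            T = gammaln(a[:, None] + cache.carr[None, :]) - gammaln(a)[:, None]
            for s0 in range(S):
                base = cache.logcoef + gammaln(A[s0]) - gammaln(cache.n + A[s0])
                for f in flips:
                    pos = window_positions(L, s0 + 1, f)
                    contrib = T[pos][jidx, cache.X].sum(axis=1)
                    out[:, k, s0, f - 1] += base + contrib
    if not cfg.flip_enabled:
        out[:, :, :, 1] = out[:, :, :, 0]
    return out


def _posterior_logw(dataset: ChromatinDataset, model: MixtureModel,
                    caches: Optional[list] = None) -> np.ndarray:
    ll = _loglik_tensor(dataset, model, caches)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
        logxi = np.log(model.xi)
        logzeta = np.log(model.zeta)
    return (
        ll
        + logpi[None, :, None, None]
        + logxi[:, None, :, None]
        + logzeta[:, None, None, :]
    )


def _normalize_logw(logw: np.ndarray) -> tuple:
    lse = logsumexp(logw, axis=(1, 2, 3))
    bad = ~np.isfinite(lse)
    R = np.exp(logw - lse[:, None, None, None])
    if np.any(bad):
        logger.warning("degenerate likelihood for %d loci; using uniform "
                       "responsibilities over states with prior support", bad.sum())
        mask = np.isfinite(logw[bad])
        R[bad] = mask / mask.sum(axis=(1, 2, 3), keepdims=True)
        lse = np.where(bad, 0.0, lse)
    return R, lse


def e_step(dataset: ChromatinDataset, model: MixtureModel,
           caches: Optional[list] = None) -> ResponsibilityTensor:
    """Posterior over (k, s, f) per locus by Bayes' rule, via log-sum-exp."""
    R, _ = _normalize_logw(_posterior_logw(dataset, model, caches))
    return ResponsibilityTensor(R)


def m_step_weights(responsibilities: ResponsibilityTensor) -> np.ndarray:
    """pi_k = mean over loci of the marginal membership E[z_ik]."""
    pi = responsibilities.cluster_marginals.mean(axis=0)
    return pi / pi.sum()


@dataclass
class _BlockStats:
    """Sufficient statistics of one (component, feature) M-step block."""

    H: np.ndarray        # (L_ext, cmax+1) weighted count-value histograms
    Hrow: np.ndarray     # (L_ext,) row sums of H
    Ws: np.ndarray       # (S,) total weight per shift state
    Wsn: np.ndarray      # (U, S) weight per (unique total count, shift state)
    uniq_n: np.ndarray
    carr: np.ndarray
    L: int
    S: int


def _block_stats(cache: _FeatureCache, Rk: np.ndarray, L: int, S: int,
                 L_ext: int, flip_enabled: bool) -> _BlockStats:
    N = Rk.shape[0]
    C1 = cache.cmax + 1
    W2 = Rk.reshape(N, S * 2)
    # (S*2, L, C1) weighted histogram of count values per (state, data bin)
    hist = cache.indicator.T.dot(W2).T.reshape(S * 2, L, C1)
    H = np.zeros((L_ext, C1))
    flips = (1, 2) if flip_enabled else (1,)
    for s0 in range(S):
        for f in flips:
            pos = window_positions(L, s0 + 1, f)
            H[pos] += hist[s0 * 2 + (f - 1)]
    Ws = Rk.sum(axis=(0, 2))
    rn = Rk.sum(axis=2)
    Wsn = np.zeros((cache.uniq_n.size, S))
    np.add.at(Wsn, cache.inv_n, rn)
    return _BlockStats(H=H, Hrow=H.sum(axis=1), Ws=Ws, Wsn=Wsn,
                       uniq_n=cache.uniq_n, carr=cache.carr, L=L, S=S)


def _block_neg_objective(lam: np.ndarray, stats: _BlockStats,
                         hyper: Hyperparameters) -> tuple:
    """Negative expected complete-data log posterior of one block, + gradient.

    Works in lambda = log(alpha); includes the elementwise Gamma prior, the
    (floored) smoothness prior and the change-of-variables Jacobian.
    """
    lam = np.clip(lam, -LAMBDA_CLIP, LAMBDA_CLIP)
    a = np.exp(lam)
    L, S = stats.L, stats.S
    A = _window_sums(a, L, S)

    Ga = gammaln(a[:, None] + stats.carr[None, :])
    nA = stats.uniq_n[:, None] + A[None, :]
    ll = float(
        (stats.H * Ga).sum() - (stats.Hrow * Ga[:, 0]).sum()
        + (stats.Ws * gammaln(A)).sum() - (stats.Wsn * gammaln(nA)).sum()
    )

    prior = float(np.sum((hyper.eta - 1) * lam - hyper.nu * a))
    if hyper.smoothing_enabled:
        h = max(float(np.sum(np.diff(a) ** 2)), _H_FLOOR)
        prior += gamma_logpdf(h, hyper.eta_h, hyper.nu_h)
    obj = ll + prior + float(lam.sum())

    Psi = digamma(a[:, None] + stats.carr[None, :])
    g_counts = (stats.H * Psi).sum(axis=1) - stats.Hrow * Psi[:, 0]
    g_s = stats.Ws * digamma(A) - (stats.Wsn * digamma(nA)).sum(axis=0)
    cg = np.concatenate(([0.0], np.cumsum(g_s)))
    p = np.arange(a.size)
    lo = np.clip(p - L + 1, 0, None)
    hi = np.minimum(p, S - 1)
    g_A = cg[hi + 1] - cg[lo]
    g_alpha = g_counts + g_A + _prior_grad_alpha_block(a, hyper, _H_FLOOR)
    g_lam = a * g_alpha + 1.0
    return -obj, -g_lam


def m_step_alpha(dataset: ChromatinDataset, responsibilities: ResponsibilityTensor,
                 model: MixtureModel, hyper: Hyperparameters,
                 caches: Optional[list] = None, gtol: float = 1e-5,
                 maxiter: int = 200) -> np.ndarray:
    """BFGS update of alpha = exp(lambda), block by (component, feature).

    Each block update is accepted only if it does not decrease the block
    objective (generalized-EM contract); on optimizer failure the previous
    alpha is kept and a warning logged.
    """
    if caches is None:
        caches = _caches(dataset)
    cfg = model.config
    L, S = dataset.n_bins, cfg.n_shift_states
    L_ext = cfg.extended_length(L)
    new_alpha = model.alpha.copy()
    R = responsibilities.values
    for k in range(model.n_components):
        Rk = R[:, k, :, :]
        for m, cache in enumerate(caches):
            stats = _block_stats(cache, Rk, L, S, L_ext, cfg.flip_enabled)
            lam0 = np.log(model.alpha[k, m])
            f0, _ = _block_neg_objective(lam0, stats, hyper)
            try:
                res = minimize(
                    _block_neg_objective, lam0, args=(stats, hyper),
                    jac=True, method="BFGS",
                    options={"gtol": gtol, "maxiter": maxiter},
                )
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("BFGS failed for block (k=%d, m=%d): %s; "
                               "keeping previous alpha", k, m, exc)
                continue
            if np.isfinite(res.fun) and res.fun <= f0:
                new_alpha[k, m] = np.exp(np.clip(res.x, -LAMBDA_CLIP, LAMBDA_CLIP))
            else:
                logger.warning("BFGS did not improve block (k=%d, m=%d); "
                               "keeping previous alpha", k, m)
    return new_alpha


def _default_priors(N: int, config: ShiftFlipConfig) -> tuple:
    S = config.n_shift_states
    if config.shift_enabled and config.shift_prior_kind == "pyramid":
        xi_row = pyramid_shift_prior(S)
    else:
        xi_row = uniform_shift_prior(S)
    zeta_row = np.array([0.5, 0.5]) if config.flip_enabled else np.array([1.0, 0.0])
    return np.tile(xi_row, (N, 1)), np.tile(zeta_row, (N, 1))


def _concat_proportions(dataset: ChromatinDataset) -> np.ndarray:
    blocks = []
    for X in dataset.counts:
        tot = X.sum(axis=1, keepdims=True).astype(float)
        tot[tot == 0] = 1.0
        blocks.append(X / tot)
    return np.hstack(blocks)


def initialize(dataset: ChromatinDataset, K: int, config: ShiftFlipConfig,
               hyper: Hyperparameters, seed: int,
               caches: Optional[list] = None) -> tuple:
    """Soft k-means initialisation of memberships, BFGS initialisation of alpha.

    Cluster memberships come from k-means on the row-wise concatenation of
    per-feature bin proportions, softened by a softmax of negative squared
    distances at a temperature equal to the mean nearest-centroid squared
    distance (keeps memberships non-degenerate).  Shift/flip responsibilities
    are spread by the priors xi and zeta; alpha then maximises the lower
    bound given these responsibilities, started from membership-weighted
    mean profiles.
    """
    N = dataset.n_loci
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} exceeds the number of loci N={N}")
    if caches is None:
        caches = _caches(dataset)
    prop = _concat_proportions(dataset)
    if K == 1:
        memb = np.ones((N, 1))
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31 - 1))
        km.fit(prop)
        d2 = km.transform(prop) ** 2
        temp = float(np.mean(d2.min(axis=1))) + 1e-12
        memb = softmax(-d2 / temp, axis=1)
    xi, zeta = _default_priors(N, config)
    R = (memb[:, :, None, None] * xi[0][None, None, :, None]
         * zeta[0][None, None, None, :])
    resp = ResponsibilityTensor(R)
    pi = m_step_weights(resp)

    L = dataset.n_bins
    pad = config.max_shift_bins
    M = dataset.n_features
    alpha0 = np.empty((K, M, config.extended_length(L)))
    for m in range(M):
        prop_m = prop[:, m * L:(m + 1) * L]
        for k in range(K):
            w = memb[:, k]
            pbar = w @ prop_m / max(w.sum(), 1e-12)
            pbar = np.clip(pbar, 1e-4, None)
            alpha0[k, m] = np.pad(L * pbar, pad, mode="edge")
    model = MixtureModel(alpha=alpha0, pi=pi, xi=xi, zeta=zeta, config=config)
    model.alpha = m_step_alpha(dataset, resp, model, hyper, caches)
    return model, resp


def _prior_value(alpha: np.ndarray, hyper: Hyperparameters) -> float:
    """Log prior of lambda = log(alpha), with the optimizer's roughness floor.

    Includes the change-of-variables Jacobian sum(log alpha): the M-step
    maximises the posterior in the lambda parameterisation, so this is the
    prior whose sum with the marginal log-likelihood is guaranteed
    non-decreasing under generalized EM.  Always finite.
    """
    total = 0.0
    for k in range(alpha.shape[0]):
        for m in range(alpha.shape[1]):
            a = alpha[k, m]
            lam = np.log(a)
            total += float(np.sum((hyper.eta - 1) * lam - hyper.nu * a) + lam.sum())
            if hyper.smoothing_enabled:
                total += gamma_logpdf(max(smoothness_term(a), _H_FLOOR),
                                      hyper.eta_h, hyper.nu_h)
    return total


def observed_log_likelihood(dataset: ChromatinDataset, model: MixtureModel,
                            caches: Optional[list] = None) -> float:
    """Marginal log-likelihood: shift, flip and cluster states summed out."""
    logw = _posterior_logw(dataset, model, caches)
    return float(logsumexp(logw, axis=(1, 2, 3)).sum())


def _em_single(dataset: ChromatinDataset, K: int, config: ShiftFlipConfig,
               hyper: Hyperparameters, max_iter: int, tol: float,
               seed: int) -> FitResult:
    caches = _caches(dataset)
    model, resp = initialize(dataset, K, config, hyper, seed, caches)
    trace = []
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        logw = _posterior_logw(dataset, model, caches)
        R, lse = _normalize_logw(logw)
        resp = ResponsibilityTensor(R)
        loglik = float(lse.sum())
        lp = loglik + _prior_value(model.alpha, hyper)
        trace.append(lp)
        logger.debug("EM iteration %d: log posterior %.6f", len(trace), lp)
        if len(trace) > 1 and abs(lp - trace[-2]) <= tol * abs(lp):
            converged = True
            break
        model.alpha = m_step_alpha(dataset, resp, model, hyper, caches)
        model.pi = m_step_weights(resp)
    return FitResult(
        model=model,
        responsibilities=resp,
        lower_bound_trace=trace,
        n_iterations=len(trace),
        converged=converged,
        log_posterior=trace[-1],
        log_likelihood=loglik,
        assignments=hard_assign_all(resp, config),
        seed=seed,
    )


def fit(dataset: ChromatinDataset, K: int,
        config: Optional[ShiftFlipConfig] = None,
        hyper: Optional[Hyperparameters] = None,
        n_restarts: int = 1, max_iter: int = 200, tol: float = 1e-6,
        seed: int = 0) -> FitResult:
    """Run ``n_restarts`` independent EM fits; return the best by lower bound.

    Restart r uses the derived seed ``seed + r``; results are independent of
    execution order.  Convergence is declared when the relative change of the
    observed-data log posterior drops below ``tol``.
    """
    if max_iter < 1 or tol <= 0:
        raise ValueError("max_iter and tol must be positive")
    if config is None:
        config = ShiftFlipConfig(bin_size=dataset.bin_size or 1)
    if hyper is None:
        hyper = Hyperparameters()
    best = None
    failures = []
    for r in range(n_restarts):
        try:
            result = _em_single(dataset, K, config, hyper, max_iter, tol, seed + r)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            logger.warning("restart %d failed: %s", r, exc)
            failures.append((r, exc))
            continue
        if best is None or result.log_posterior > best.log_posterior:
            best = result
    if best is None:
        raise RuntimeError(f"all {n_restarts} EM restarts failed: {failures}")
    return best
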