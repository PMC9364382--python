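"""Domain types and the probabilistic core of the model.

The data are per-locus, per-feature vectors of binned sequencing-read counts.
Each mixture component models a locus's counts for feature ``m`` with a
Dirichlet-multinomial (Pólya) compound distribution; features are independent
given the component, so the component likelihood is a product of M
Dirichlet-multinomials.  Component concentration parameters ``alpha`` carry a
regularised Gamma prior: an independent Gamma(eta, nu) on every element, plus
a Gamma(eta_h, nu_h) on the roughness statistic
``h = sum_j (alpha_j - alpha_{j-1})**2``, which favours profiles that vary
smoothly across consecutive genomic bins.  Optimisation works on
``lambda = log(alpha)``; the prior is transported to lambda space with the
change-of-variables Jacobian ``sum(lambda)``.

All Gamma densities use the shape-rate parameterisation.  The prior is known
only up to a constant; every log-prior here is unnormalised but consistent, so
MAP optimisation and model comparison at fixed hyperparameters are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ChromatinDataset",
    "Hyperparameters",
    "ShiftFlipConfig",
    "MixtureModel",
    "log_dirichlet_multinomial",
    "log_likelihood_locus",
    "smoothness_term",
    "log_prior_alpha",
    "log_prior_lambda",
    "gamma_logpdf",
]

# lambda values outside this range correspond to alpha outside [~2e-14, 5e+12];
# clipping keeps exp() finite without affecting any realistic optimum
LAMBDA_CLIP = 29.0


def _as_count_matrix(m: np.ndarray, name: str = "counts") -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"{name}: expected 2-D matrix, got ndim={m.ndim}")
    if not np.issubdtype(m.dtype, np.integer):
        if not np.all(np.equal(np.mod(m, 1), 0)):
            raise ValueError(f"{name}: entries must be integral")
        m = m.astype(np.int64)
    if np.any(m < 0):
        raise ValueError(f"{name}: entries must be non-negative")
    return m.astype(np.int64, copy=False)


@dataclass
class ChromatinDataset:
    """N genomic loci x M chromatin features x L bins of read counts.

    ``counts`` holds one N x L non-negative integer matrix per feature.  Bin
    size B (bp) and window size W (bp) are bookkeeping; when both are given,
    L = W / B must be exact.
    """

    counts: list
    feature_names: Optional[Sequence[str]] = None
    bin_size: Optional[int] = None
    window_size: Optional[int] = None
    locus_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("dataset needs at least one feature matrix")
        self.counts = [_as_count_matrix(c, f"feature {m}") for m, c in enumerate(self.counts)]
        shape = self.counts[0].shape
        for m, c in enumerate(self.counts):
            if c.shape != shape:
                raise ValueError(
                    f"feature {m} has shape {c.shape}, expected {shape}: "
                    "all features must share N x L"
                )
        if self.feature_names is None:
            self.feature_names = [f"feature{m + 1}" for m in range(len(self.counts))]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != len(self.counts):
            raise ValueError("feature_names length must match number of features")
        if self.bin_size is not None and self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.window_size is not None and self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.bin_size is not None and self.window_size is not None:
            if self.window_size % self.bin_size != 0:
                raise ValueError("window_size must be an exact multiple of bin_size")
            if self.window_size // self.bin_size != self.n_bins:
                raise ValueError(
                    f"window_size/bin_size = {self.window_size // self.bin_size} "
                    f"does not match L = {self.n_bins}"
                )
        if self.locus_ids is not None:
            self.locus_ids = list(self.locus_ids)
            if len(self.locus_ids) != self.n_loci:
                raise ValueError("locus_ids length must match N")

    @property
    def n_loci(self) -> int:
        return self.counts[0].shape[0]

    @property
    def n_features(self) -> int:
        return len(self.counts)

    @property
    def n_bins(self) -> int:
        return self.counts[0].shape[1]

    def totals(self, m: int) -> np.ndarray:
        """Per-locus total read count for feature ``m``."""
        return self.counts[m].sum(axis=1)


@dataclass(frozen=True)
class Hyperparameters:
    """Gamma hyperprior settings (shape-rate parameterisation).

    eta, nu: shape and rate of the independent per-element prior on alpha.
    eta_h, nu_h: shape and rate of the prior on the roughness statistic h;
    both ``None`` disables the smoothness regularisation entirely.
    Defaults follow the robust values found in hyperparameter sweeps:
    eta=1.1, nu=0.1 (prior mean 11 per element), and a mean-1/variance-0.1
    Gamma on h, i.e. eta_h = nu_h = 10.
    """

    eta: float = 1.1
    nu: float = 0.1
    eta_h: Optional[float] = 10.0
    nu_h: Optional[float] = 10.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.nu <= 0:
            raise ValueError("eta and nu must be strictly positive")
        if (self.eta_h is None) != (self.nu_h is None):
            raise ValueError("eta_h and nu_h must be both set or both None")
        if self.eta_h is not None and (self.eta_h <= 0 or self.nu_h <= 0):
            raise ValueError("eta_h and nu_h must be strictly positive when set")

    @property
    def smoothing_enabled(self) -> bool:
        return self.eta_h is not None


@dataclass(frozen=True)
class ShiftFlipConfig:
    """Discrete alignment configuration.

    With bin size B and maximum shift +-max_shift_bp there are
    S = 2 * (max_shift_bp / B) + 1 shift states; state (S+1)/2 (1-based) is
    "no shift".  Component parameter vectors are extended to
    L_ext = L + S - 1 so every shift state indexes an L-length window.
    """

    shift_enabled: bool = False
    flip_enabled: bool = False
    max_shift_bp: int = 0
    bin_size: int = 1
    shift_prior_kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.max_shift_bp < 0:
            raise ValueError("max_shift_bp must be non-negative")
        if self.max_shift_bp % self.bin_size != 0:
            raise ValueError("max_shift_bp must be an exact multiple of bin_size")
        if self.shift_enabled and self.max_shift_bp == 0:
            raise ValueError("shift_enabled requires max_shift_bp > 0")
        if self.shift_prior_kind not in ("uniform", "pyramid"):
            raise ValueError("shift_prior_kind must be 'uniform' or 'pyramid'")

    @property
    def max_shift_bins(self) -> int:
        return self.max_shift_bp // self.bin_size if self.shift_enabled else 0

    @property
    def n_shift_states(self) -> int:
        return 2 * self.max_shift_bins + 1

    @property
    def no_shift_state(self) -> int:
        """1-based index of the zero-shift state."""
        return (self.n_shift_states + 1) // 2

    def extended_length(self, n_bins: int) -> int:
        return n_bins + self.n_shift_states - 1


@dataclass
class MixtureModel:
    """Fitted or initialised mixture parameters.

    alpha: (K, M, L_ext) positive concentration parameters.
    pi: (K,) mixture weights.
    xi: (N, S) per-locus shift-state prior (row-stochastic).
    zeta: (N, 2) per-locus flip-state prior (row-stochastic); column 2 is
    zero when flipping is disabled.
    """

    alpha: np.ndarray
    pi: np.ndarray
    xi: np.ndarray
    zeta: np.ndarray
    config: ShiftFlipConfig = field(default_factory=ShiftFlipConfig)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        self.zeta = np.atleast_2d(np.asarray(self.zeta, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.alpha.ndim != 3:
            raise ValueError("alpha must have shape (K, M, L_ext)")
        if np.any(self.alpha <= 0) or not np.all(np.isfinite(self.alpha)):
            raise ValueError("all alpha elements must be positive and finite")
        if self.pi.ndim != 1 or self.pi.shape[0] != self.alpha.shape[0]:
            raise ValueError("pi must be a length-K vector")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")
        S = self.config.n_shift_states
        if self.xi.shape[1] != S:
            raise ValueError(f"xi must have S={S} columns")
        if not np.allclose(self.xi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of xi must sum to 1")
        if self.zeta.shape[1] != 2:
            raise ValueError("zeta must have 2 columns")
        if not np.allclose(self.zeta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of zeta must sum to 1")

    @property
    def n_components(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_features(self) -> int:
        return self.alpha.shape[1]

    @property
    def extended_length(self) -> int:
        return self.alpha.shape[2]

    @property
    def n_bins(self) -> int:
        return self.extended_length - self.config.n_shift_states + 1


def log_dirichlet_multinomial(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial (Pólya) distribution.

    Includes the multinomial coefficient, so this is a proper probability
    mass over count vectors with fixed total.  Everything is computed in
    log-gamma space and is finite for any valid input (including n = 0,
    whose mass is 1).
    """
    x = np.asarray(x)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape or x.ndim != 1:
        raise ValueError("x and alpha must be 1-D vectors of equal length")
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be strictly positive and finite")
    if np.any(x < 0) or not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("x must contain non-negative integers")
    x = x.astype(np.int64)
    n = int(x.sum())
    A = alpha.sum()
    return float(
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(x + alpha) - gammaln(alpha)).sum()
    )


def log_likelihood_locus(x_star: Sequence[np.ndarray], alpha_k: Sequence[np.ndarray]) -> float:
    """Product-DM log-likelihood of one locus: sum over the M features."""
    if len(x_star) != len(alpha_k):
        raise ValueError("number of features differs between data and parameters")
    return float(sum(log_dirichlet_multinomial(x, a) for x, a in zip(x_star, alpha_k)))


def smoothness_term(alpha_km: np.ndarray) -> float:
    """Roughness statistic h = sum of squared first differences; 0 if constant."""
    a = np.asarray(alpha_km, dtype=float)
    if a.ndim != 1 or a.size < 1:
        raise ValueError("alpha_km must be a non-empty 1-D vector")
    if a.size == 1:
        return 0.0
    return float(np.sum(np.diff(a) ** 2))


def gamma_logpdf(x: float, shape: float, rate: float) -> float:
    """Log density of Gamma(shape, rate); -inf at x=0 when shape>1."""
    if x < 0:
        return -np.inf
    if x == 0.0:
        if shape > 1:
            return -np.inf
        if shape == 1:
            return float(np.log(rate))
        return np.inf
    return float(shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x)


def _log_prior_alpha_array(alpha: np.ndarray, hyper: Hyperparameters) -> float:
    """Unnormalised log prior over a (K, M, L_ext) alpha array."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[None, None, :]
    total = 0.0
    for k in range(alpha.shape[0]):
        for m in range(alpha.shape[1]):
            a = alpha[k, m]
            total += float(
                np.sum((hyper.eta - 1) * np.log(a) - hyper.nu * a)
                + a.size * (hyper.eta * np.log(hyper.nu) - gammaln(hyper.eta))
            )
            if hyper.smoothing_enabled:
                total += gamma_logpdf(smoothness_term(a), hyper.eta_h, hyper.nu_h)
    return total


def log_prior_alpha(model: MixtureModel, hyper: Hyperparameters) -> float:
    """Unnormalised log prior of the model's component parameters.

    Sums, over components and features, the elementwise Gamma(eta, nu) log
    densities and (when enabled) the Gamma(eta_h, nu_h) log density of the
    roughness statistic.  Returns -inf (never raises) when h = 0 meets
    eta_h > 1.
    """
    return _log_prior_alpha_array(model.alpha, hyper)


def log_prior_lambda(lambda_star: np.ndarray, hyper: Hyperparameters) -> float:
    """Log prior in the lambda = log(alpha) parameterisation.

    Equals ``log_prior_alpha`` at alpha = exp(lambda) plus the log-Jacobian
    sum(lambda) of the elementwise exponential map.
    """
    lam = np.asarray(lambda_star, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("lambda values must be finite")
    lam = np.clip(lam, -LAMBDA_CLIP, LAMBDA_CLIP)
    return _log_prior_alpha_array(np.exp(lam), hyper) + float(lam.sum())


def _prior_grad_alpha_block(a: np.ndarray, hyper: Hyperparameters,
                            h_floor: float = 1e-12) -> np.ndarray:
    """d/d alpha of the block log prior for one (L_ext,) vector.

    The roughness h is floored at ``h_floor`` in the gradient to keep it
    finite when alpha is (numerically) constant.
    """
    g = (hyper.eta - 1) / a - hyper.nu
    if hyper.smoothing_enabled and a.size > 1:
        d = np.diff(a)
        h = max(float(np.sum(d**2)), h_floor)
        dlog_dh = (hyper.eta_h - 1) / h - hyper.nu_h
        dh = np.zeros_like(a)
        dh[1:] += 2 * d
        dh[:-1] -= 2 * d
        g = g + dlog_dh * dh
    return g
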