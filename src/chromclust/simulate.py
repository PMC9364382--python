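"""Synthetic chromatin-profile generators.

Three generators cover the study designs the model is exercised on:

* ``simulate_dmm`` — sampling from the model itself: per locus a cluster from
  pi, per feature a bin-probability vector from Dirichlet(alpha) and counts
  from a multinomial at a fixed feature-specific coverage.
* ``simulate_gaussian_lowcov`` — a low-coverage protocol with Gaussian-shaped
  cluster aggregate profiles and per-bin Poisson counts scaled by a coverage
  factor f; all-zero profiles are rejected and redrawn, because at these
  coverages most raw draws contain no reads at all.
* ``sample_from_prior`` — ancestral (prior predictive) sampling: alpha from
  the elementwise Gamma(eta, nu) prior, then ``simulate_dmm``.  The smoothness
  factor of the joint prior is ignored here (the joint is known only up to a
  constant); this is an approximation used solely for prior predictive checks.

``corrupt_shift_flip`` post-hoc displaces profiles by mean-zero Skellam draws
(in bins, i.e. multiples of the bin size) truncated to the maximum shift, and
reverses them with probability 1/2, recording the true states in the shared
shift/flip convention of :mod:`chromclust.shift_flip`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import ChromatinDataset, Hyperparameters
from .shift_flip import translate_profile

__all__ = [
    "SimulationTruth",
    "simulate_dmm",
    "simulate_gaussian_lowcov",
    "corrupt_shift_flip",
    "sample_from_prior",
    "make_smooth_alpha",
    "default_alpha_fixtures",
]


@dataclass
class SimulationTruth:
    """Ground-truth latent states and parameters of a simulated dataset."""

    labels: np.ndarray          # N, 1-based cluster labels
    shift_states: np.ndarray    # N, 1-based shift states
    flip_states: np.ndarray     # N, values in {1, 2}
    alpha_true: np.ndarray      # (K, M, L) generating parameters (or profiles)
    coverages: np.ndarray       # M
    n_shift_states: int = 1

    @property
    def shift_bp(self) -> int:
        raise AttributeError("use shift_bp_of(bin_size)")

    def shift_bp_of(self, bin_size: int) -> np.ndarray:
        """True data displacement in bp under the shared sign convention."""
        s0 = (self.n_shift_states + 1) // 2
        return (s0 - self.shift_states) * bin_size


def simulate_dmm(alpha_true: np.ndarray, pi: np.ndarray,
                 coverages: Sequence[int], N: int, seed: int,
                 bin_size: Optional[int] = None,
                 feature_names: Optional[Sequence[str]] = None) -> tuple:
    """Draw N loci from the product Dirichlet-multinomial mixture.

    ``alpha_true`` has shape (K, M, L); each locus/feature row sums exactly
    to its feature coverage, so all-zero rows cannot occur.
    """
    alpha_true = np.asarray(alpha_true, dtype=float)
    if alpha_true.ndim != 3:
        raise ValueError("alpha_true must have shape (K, M, L)")
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must be a probability vector")
    coverages = np.asarray(coverages, dtype=int)
    if np.any(coverages < 1):
        raise ValueError("coverages must be >= 1")
    K, M, L = alpha_true.shape
    if coverages.size != M:
        raise ValueError("need one coverage per feature")
    rng = np.random.default_rng(seed)
    labels = rng.choice(K, size=N, p=pi) + 1
    counts = [np.zeros((N, L), dtype=np.int64) for _ in range(M)]
    for i in range(N):
        k = labels[i] - 1
        for m in range(M):
            p = rng.dirichlet(alpha_true[k, m])
            counts[m][i] = rng.multinomial(coverages[m], p)
    dataset = ChromatinDataset(counts=counts, feature_names=feature_names,
                               bin_size=bin_size)
    truth = SimulationTruth(
        labels=labels,
        shift_states=np.ones(N, dtype=int),
        flip_states=np.ones(N, dtype=int),
        alpha_true=alpha_true,
        coverages=coverages,
    )
    return dataset, truth


def simulate_gaussian_lowcov(N_per_cluster: int, f: float, L: int = 50,
                             cluster_specs: Optional[Sequence[dict]] = None,
                             seed: int = 0, total_rate: float = 1.0,
                             max_batches: int = 1000) -> tuple:
    """Low-coverage two-cluster protocol with Gaussian aggregate profiles.

    Per cluster, the expected profile is a Gaussian bump (location/scale from
    ``cluster_specs``, in bins) normalised to ``total_rate`` expected reads
    and scaled by the coverage factor ``f``; counts are per-bin Poisson.
    All-zero draws are rejected until ``N_per_cluster`` non-zero profiles per
    cluster are collected (bounded by ``max_batches`` redraw rounds).
    """
    if f <= 0:
        raise ValueError("coverage factor f must be positive")
    if cluster_specs is None:
        cluster_specs = [
            {"mean": 0.40 * L, "sd": 0.08 * L},
            {"mean": 0.60 * L, "sd": 0.15 * L},
        ]
    rng = np.random.default_rng(seed)
    j = np.arange(L)
    profiles, labels = [], []
    expected = []
    for k, spec in enumerate(cluster_specs):
        g = np.exp(-0.5 * ((j - spec["mean"]) / spec["sd"]) ** 2)
        rate = f * total_rate * g / g.sum()
        expected.append(rate)
        if rate.sum() <= 0:
            raise ValueError(f"cluster {k}: expected profile is zero")
        kept = []
        for _ in range(max_batches):
            draw = rng.poisson(rate, size=(N_per_cluster, L))
            nz = draw[draw.sum(axis=1) > 0]
            kept.extend(nz)
            if len(kept) >= N_per_cluster:
                break
        if len(kept) < N_per_cluster:
            raise RuntimeError(
                f"cluster {k}: could not collect {N_per_cluster} non-zero "
                f"profiles in {max_batches} rounds (expected total "
                f"{rate.sum():.3g} reads)")
        profiles.append(np.array(kept[:N_per_cluster]))
        labels.extend([k + 1] * N_per_cluster)
    counts = np.vstack(profiles)
    N = counts.shape[0]
    dataset = ChromatinDataset(counts=[counts])
    truth = SimulationTruth(
        labels=np.array(labels),
        shift_states=np.ones(N, dtype=int),
        flip_states=np.ones(N, dtype=int),
        alpha_true=np.stack(expected)[:, None, :],
        coverages=np.array([max(1, int(round(f * total_rate)))]),
    )
    return dataset, truth


def _skellam_mu(max_shift_bins: int) -> float:
    # equal Poisson rates mu = sigma^2 / 2 with sigma such that ~99% of the
    # mass falls inside the support before truncation (normal approximation)
    sigma = max_shift_bins / 2.576
    return sigma**2 / 2.0


def corrupt_shift_flip(dataset: ChromatinDataset, truth: SimulationTruth,
                       max_shift_bp: int, bin_size: int, seed: int,
                       mu: Optional[float] = None) -> tuple:
    """Displace and reverse profiles with random true shift/flip states.

    Shifts (in bins) are mean-zero Skellam draws with equal Poisson rates
    ``mu`` (default chosen so that ~99% of draws fall inside the support),
    redrawn while outside +-max_shift_bp; flips are fair coin flips.  The
    profile is translated right by ``u`` bins (zero-fill) and then reversed
    when flipped; the recorded true shift state is ``s0 - u``.
    """
    if max_shift_bp % bin_size != 0:
        raise ValueError("max_shift_bp must be a multiple of bin_size")
    max_bins = max_shift_bp // bin_size
    S = 2 * max_bins + 1
    s0 = (S + 1) // 2
    rng = np.random.default_rng(seed)
    N = dataset.n_loci
    if max_bins == 0:
        shifts = np.zeros(N, dtype=int)
    else:
        if mu is None:
            mu = _skellam_mu(max_bins)
        shifts = np.empty(N, dtype=int)
        remaining = np.arange(N)
        while remaining.size:
            draw = stats.skellam.rvs(mu, mu, size=remaining.size, random_state=rng)
            ok = np.abs(draw) <= max_bins
            shifts[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
    flips = rng.integers(1, 3, size=N)
    new_counts = []
    for X in dataset.counts:
        Y = X.copy()
        for i in range(N):
            row = translate_profile(X[i], shifts[i])
            if flips[i] == 2:
                row = row[::-1]
            Y[i] = row
        new_counts.append(Y)
    corrupted = ChromatinDataset(counts=new_counts,
                                 feature_names=list(dataset.feature_names),
                                 bin_size=dataset.bin_size,
                                 window_size=dataset.window_size)
    new_truth = replace(truth, shift_states=s0 - shifts, flip_states=flips,
                        n_shift_states=S)
    return corrupted, new_truth


def sample_from_prior(hyper: Hyperparameters, K: int, M: int, L_ext: int,
                      coverages: Sequence[int], N: int, seed: int) -> tuple:
    """Prior predictive (ancestral) sampling of a dataset.

    alpha is drawn elementwise from Gamma(eta, nu) — expectation eta/nu per
    element — and the data follow by ``simulate_dmm`` with uniform mixture
    weights.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.gamma(shape=hyper.eta, scale=1.0 / hyper.nu, size=(K, M, L_ext))
    alpha = np.clip(alpha, 1e-12, None)
    pi = np.full(K, 1.0 / K)
    return simulate_dmm(alpha, pi, coverages, N, seed=int(rng.integers(2**31 - 1)))


def make_smooth_alpha(L_ext: int, peaks: Sequence[tuple] = (),
                      baseline: float = 0.5) -> np.ndarray:
    """Deterministic smooth concentration vector: Gaussian bumps + baseline.

    ``peaks`` is a list of (center, width, height) in bin units (0-based
    centers); the result is strictly positive.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    j = np.arange(L_ext, dtype=float)
    a = np.full(L_ext, float(baseline))
    for center, width, height in peaks:
        a += height * np.exp(-0.5 * ((j - center) / width) ** 2)
    return a


def default_alpha_fixtures(L: int, M: int = 2) -> np.ndarray:
    """Two-cluster smooth concentration fixtures, shape (2, M, L).

    Cluster 1 mimics a central valley flanked by two peaks of unequal height
    (a nucleosome-free region with asymmetric flanking enrichment); cluster 2
    an off-centre single peak.  Both shapes are strand-asymmetric, as real
    chromatin profiles are, so flip states are identifiable.  Feature index
    slightly varies the geometry so features are informative but not
    identical.
    """
    out = np.empty((2, M, L))
    for m in range(M):
        w = 0.055 * L * (1 + 0.25 * m)
        out[0, m] = make_smooth_alpha(
            L, peaks=[(0.30 * L, w, 5.0), (0.70 * L, w, 2.0)], baseline=0.3)
        out[1, m] = make_smooth_alpha(
            L, peaks=[(0.40 * L + 0.06 * L * m, 0.10 * L, 5.0)], baseline=0.3)
    return out
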