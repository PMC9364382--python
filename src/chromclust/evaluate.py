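"""Clustering, shift and flip accuracy metrics with identifiability corrections.

Mixture likelihoods are invariant under permuting cluster labels and, absent
an informative strand prior, under globally inverting the flip labels of a
cluster; a flipped frame also mirrors shift states.  All metrics here correct
for these invariances: labels are aligned by the agreement-maximising
permutation (exhaustive for K <= 6), flip error takes the better of the two
global inversions per inferred cluster, and shift error mirrors the true
shifts for clusters whose flip frame was inverted.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import roc_auc_score

from .core_model import ChromatinDataset
from .shift_flip import realign_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "align_labels",
    "clustering_auc",
    "flip_error",
    "shift_error",
    "aggregate_profiles",
    "profile_recovery_error",
    "evaluate_fit",
]


def align_labels(true_labels: np.ndarray, inferred: np.ndarray, K: int) -> np.ndarray:
    """Permutation p (length K) maximising agreement: p[inferred-1] ~ true.

    Exhaustive over K! permutations; intended for K <= 6.
    """
    if K > 6:
        raise ValueError("exhaustive label alignment supports K <= 6")
    true_labels = np.asarray(true_labels)
    inferred = np.asarray(inferred)
    best, best_score = None, -1
    for perm in itertools.permutations(range(1, K + 1)):
        mapped = np.asarray(perm)[inferred - 1]
        score = int((mapped == true_labels).sum())
        if score > best_score:
            best, best_score = np.asarray(perm), score
    return best


def clustering_auc(truth_labels: np.ndarray, responsibilities) -> float:
    """AUC of the marginal posterior of one cluster against binary truth.

    Defined for two true clusters; label switching is corrected by
    max(AUC, 1 - AUC), and the result is invariant to any strictly monotone
    transform of the posterior scores.
    """
    truth_labels = np.asarray(truth_labels)
    classes = np.unique(truth_labels)
    if classes.size != 2:
        raise ValueError("clustering_auc requires exactly two true clusters")
    values = getattr(responsibilities, "values", responsibilities)
    values = np.asarray(values, dtype=float)
    score = values[:, 0].sum(axis=(1, 2)) if values.ndim == 4 else values[:, 0]
    auc = roc_auc_score(truth_labels == classes[0], score)
    return float(max(auc, 1.0 - auc))


def _per_cluster_flip(truth, assignments) -> tuple:
    """(per-cluster error, per-cluster inversion flag, cluster of each locus)."""
    inf_cluster = np.array([a.cluster for a in assignments])
    inf_flip = np.array([a.flip_state for a in assignments])
    true_flip = np.asarray(truth.flip_states)
    errors, inverted = {}, {}
    for c in np.unique(inf_cluster):
        sel = inf_cluster == c
        mismatch = float(np.mean(inf_flip[sel] != true_flip[sel]))
        inverted[int(c)] = (1.0 - mismatch) < mismatch
        errors[int(c)] = min(mismatch, 1.0 - mismatch)
    return errors, inverted, inf_cluster


def flip_error(truth, assignments) -> float:
    """Proportion of incorrectly inferred flip states, inversion-corrected.

    Within each inferred cluster the flip labels can be globally inverted
    without changing the likelihood, so the smaller of the two mismatch
    proportions is taken per cluster; the overall error is the locus-weighted
    mean and is therefore always <= 0.5.
    """
    errors, _, inf_cluster = _per_cluster_flip(truth, assignments)
    total = 0.0
    for c, e in errors.items():
        total += e * np.sum(inf_cluster == c)
    return float(total / len(assignments))


def shift_error(truth, assignments, bin_size: int) -> float:
    """Mean absolute difference between true and inferred shift, in bp.

    For loci in clusters whose flip frame was inverted (as chosen by the
    flip-error correction), the true shifts are mirrored (s <-> S+1-s, i.e.
    the displacement changes sign) before differencing, because a flipped
    frame mirrors the shift axis.
    """
    _, inverted, inf_cluster = _per_cluster_flip(truth, assignments)
    true_bp = truth.shift_bp_of(bin_size).astype(float)
    inf_bp = np.array([a.shift_bp for a in assignments], dtype=float)
    signs = np.array([-1.0 if inverted[int(c)] else 1.0 for c in inf_cluster])
    return float(np.mean(np.abs(signs * true_bp - inf_bp)))


def aggregate_profiles(dataset: ChromatinDataset, assignments,
                       n_clusters: Optional[int] = None) -> np.ndarray:
    """Per-cluster, per-feature mean profiles after re-alignment.

    Shape (K, M, L); an empty cluster yields a zero profile and a warning.
    """
    K = n_clusters or max(a.cluster for a in assignments)
    realigned = realign_profiles(dataset, assignments)
    clusters = np.array([a.cluster for a in assignments])
    out = np.zeros((K, dataset.n_features, dataset.n_bins))
    for k in range(1, K + 1):
        sel = clusters == k
        if not np.any(sel):
            logger.warning("cluster %d is empty; aggregate profile set to zeros", k)
            continue
        for m in range(dataset.n_features):
            out[k - 1, m] = realigned.counts[m][sel].mean(axis=0)
    return out


def _central_window(a: np.ndarray, L: int) -> np.ndarray:
    pad = (a.shape[-1] - L) // 2
    return a[..., pad: pad + L] if pad else a


def profile_recovery_error(model, truth, label_mapping: np.ndarray) -> float:
    """Mean per-bin |fitted mean profile - true mean profile|.

    Profiles are the normalised concentrations alpha / sum(alpha); the fitted
    (possibly shift-extended) vectors are cut to their central L-length
    window, and clusters are matched through ``label_mapping``.
    """
    alpha_true = np.asarray(truth.alpha_true, dtype=float)
    K, M, L = alpha_true.shape
    errs = []
    for k_inf in range(model.n_components):
        k_true = int(label_mapping[k_inf]) - 1
        for m in range(M):
            fitted = _central_window(model.alpha[k_inf, m], L)
            p_fit = fitted / fitted.sum()
            p_true = alpha_true[k_true, m] / alpha_true[k_true, m].sum()
            errs.append(np.abs(p_fit - p_true).mean())
    return float(np.mean(errs))


@dataclass
class EvaluationReport:
    """Bundle of accuracy metrics for a fit against simulation truth."""

    clustering_auc: Optional[float]
    shift_error_bp: float
    flip_error: float
    aggregate_correlations: np.ndarray  # (K, M) Pearson r, NaN for empty
    label_mapping: np.ndarray
    flip_inversion: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "clustering_auc": self.clustering_auc,
            "shift_error_bp": self.shift_error_bp,
            "flip_error": self.flip_error,
            "aggregate_correlations": np.asarray(self.aggregate_correlations).tolist(),
            "label_mapping": np.asarray(self.label_mapping).tolist(),
            "flip_inversion": {str(k): bool(v) for k, v in self.flip_inversion.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            if self.clustering_auc is not None:
                fh.write(f"clustering_auc\t{self.clustering_auc:.6f}\n")
            fh.write(f"shift_error_bp\t{self.shift_error_bp:.6f}\n")
            fh.write(f"flip_error\t{self.flip_error:.6f}\n")


def evaluate_fit(dataset: ChromatinDataset, truth, fit_result,
                 true_aggregates: Optional[np.ndarray] = None) -> EvaluationReport:
    """Full accuracy report of one fit against its simulation truth."""
    model = fit_result.model
    assignments = fit_result.assignments
    K = model.n_components
    inferred = np.array([a.cluster for a in assignments])
    mapping = align_labels(np.asarray(truth.labels), inferred, K)

    auc = None
    if np.unique(np.asarray(truth.labels)).size == 2 and K >= 2:
        auc = clustering_auc(truth.labels, fit_result.responsibilities)

    bin_size = model.config.bin_size
    s_err = shift_error(truth, assignments, bin_size)
    f_err = flip_error(truth, assignments)
    _, inversion, _ = _per_cluster_flip(truth, assignments)

    agg = aggregate_profiles(dataset, assignments, n_clusters=K)
    if true_aggregates is None:
        ref = np.asarray(truth.alpha_true, dtype=float)
        ref = ref / ref.sum(axis=2, keepdims=True)
    else:
        ref = np.asarray(true_aggregates, dtype=float)
    corr = np.full((K, dataset.n_features), np.nan)
    for k_inf in range(K):
        k_true = int(mapping[k_inf]) - 1
        if k_true >= ref.shape[0]:
            continue
        for m in range(dataset.n_features):
            a = agg[k_inf, m]
            b = ref[k_true, m][: a.size]
            if np.std(a) > 0 and np.std(b) > 0:
                corr[k_inf, m] = sp_stats.pearsonr(a, b)[0]
    return EvaluationReport(
        clustering_auc=auc,
        shift_error_bp=s_err,
        flip_error=f_err,
        aggregate_correlations=corr,
        label_mapping=mapping,
        flip_inversion=inversion,
    )
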