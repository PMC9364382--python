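"""Windowing and orientation machinery for shift/flip-aware components.

A shift state s (1-based, 1..S) selects the L-length window
``alpha_ext[s-1 : s-1+L]`` of the extended component parameters; flip state
f = 2 reverses that window.  Under this slicing, data generated from window s
appears translated right by ``(s0 - s)`` bins relative to the centred window
``s0 = (S+1)/2``, so the hard assignment's ``shift_bp = (s0 - s) * B`` is the
data's rightward displacement in base pairs, and re-aligning a profile means
undoing the flip and then translating by ``-shift_bp / B`` bins.  The same
convention is used by the simulator, the model and the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ChromatinDataset, ShiftFlipConfig

__all__ = [
    "HardAssignment",
    "extract_window",
    "window_positions",
    "pyramid_shift_prior",
    "uniform_shift_prior",
    "hard_assign",
    "hard_assign_all",
    "translate_profile",
    "realign_profiles",
]


@dataclass(frozen=True)
class HardAssignment:
    """MAP cluster/shift/flip labels for one locus (all 1-based)."""

    cluster: int
    shift_state: int
    flip_state: int
    shift_bp: int

    def __post_init__(self) -> None:
        if self.flip_state not in (1, 2):
            raise ValueError("flip_state must be 1 or 2")


def extract_window(alpha_ext: np.ndarray, s: int, f: int, L: int) -> np.ndarray:
    """L-length view of the extended parameters for shift s, flip f.

    Returns a fresh array (never mutates ``alpha_ext``); f = 2 reverses the
    window order.
    """
    alpha_ext = np.asarray(alpha_ext)
    S = alpha_ext.shape[-1] - L + 1
    if not 1 <= s <= S:
        raise IndexError(f"shift state s={s} out of range 1..{S}")
    if f not in (1, 2):
        raise ValueError("flip state must be 1 or 2")
    w = alpha_ext[..., s - 1: s - 1 + L].copy()
    return w[..., ::-1] if f == 2 else w


def window_positions(L: int, s: int, f: int) -> np.ndarray:
    """0-based extended-parameter index matched to each data bin j=0..L-1."""
    base = np.arange(s - 1, s - 1 + L)
    return base[::-1].copy() if f == 2 else base


def uniform_shift_prior(S: int) -> np.ndarray:
    _check_states(S)
    return np.full(S, 1.0 / S)


def pyramid_shift_prior(S: int) -> np.ndarray:
    """Triangular prior peaking at the no-shift state, decreasing linearly.

    Weights ((S+1)/2 - |s - (S+1)/2|) normalised; strictly positive and
    symmetric.  Mirrors anchoring loci at ChIP-seq peak summits, where small
    displacements are a priori more likely than large ones.
    """
    _check_states(S)
    c = (S + 1) // 2
    s = np.arange(1, S + 1)
    w = (c - np.abs(s - c)).astype(float)
    return w / w.sum()


def _check_states(S: int) -> None:
    if S < 1 or S % 2 == 0:
        raise ValueError(f"S must be a positive odd integer, got {S}")


def hard_assign(responsibilities, i: int, config: ShiftFlipConfig) -> HardAssignment:
    """MAP labels for locus i by staged marginalisation.

    Cluster first (marginalising shift and flip), then flip given the
    cluster (marginalising shift), then shift given the cluster
    (marginalising flip).  Ties break to the lowest index.
    """
    values = getattr(responsibilities, "values", responsibilities)
    row = np.asarray(values[i], dtype=float)  # (K, S, 2)
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValueError(f"responsibilities for locus {i} do not sum to 1")
    k = int(np.argmax(row.sum(axis=(1, 2))))
    f = int(np.argmax(row[k].sum(axis=0)))
    s = int(np.argmax(row[k].sum(axis=1)))
    s0 = config.no_shift_state
    return HardAssignment(
        cluster=k + 1,
        shift_state=s + 1,
        flip_state=f + 1,
        shift_bp=(s0 - (s + 1)) * config.bin_size,
    )


def hard_assign_all(responsibilities, config: ShiftFlipConfig) -> list:
    values = getattr(responsibilities, "values", responsibilities)
    return [hard_assign(values, i, config) for i in range(values.shape[0])]


def translate_profile(x: np.ndarray, shift_bins: int) -> np.ndarray:
    """Translate a profile right by ``shift_bins`` (zero-fill, drop overflow)."""
    x = np.asarray(x)
    out = np.zeros_like(x)
    L = x.shape[-1]
    t = int(shift_bins)
    if abs(t) >= L:
        return out
    if t >= 0:
        out[..., t:] = x[..., : L - t]
    else:
        out[..., : L + t] = x[..., -t:]
    return out


def realign_profiles(dataset: ChromatinDataset, assignments: list) -> ChromatinDataset:
    """Undo each locus's inferred shift and flip, e.g. for visualisation.

    Flipped loci are reversed first, then translated by ``-shift_bp/B`` bins;
    bins shifted outside the window are dropped and vacated bins zero-filled,
    so the output has the input's shape.
    """
    if len(assignments) != dataset.n_loci:
        raise ValueError("need exactly one assignment per locus")
    B = dataset.bin_size if dataset.bin_size is not None else 1
    new_counts = []
    for m in range(dataset.n_features):
        X = dataset.counts[m].copy()
        for i, a in enumerate(assignments):
            row = X[i]
            if a.flip_state == 2:
                row = row[::-1]
            if a.shift_bp % B != 0:
                raise ValueError("shift_bp must be a multiple of the bin size")
            X[i] = translate_profile(row, -a.shift_bp // B)
        new_counts.append(X)
    return ChromatinDataset(
        counts=new_counts,
        feature_names=list(dataset.feature_names),
        bin_size=dataset.bin_size,
        window_size=dataset.window_size,
        locus_ids=None if dataset.locus_ids is None else list(dataset.locus_ids),
    )
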