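"""File formats: tab-delimited count matrices, BED loci, JSON model dumps.

Inputs are precomputed per-feature count matrices (loci x bins) as
tab-delimited text; an optional BED file supplies locus labels only — signal
extraction from alignment files is out of scope.  BED coordinates are 0-based
half-open; bin indices in all outputs are 1-based (j = 1..L).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import ChromatinDataset, MixtureModel, ShiftFlipConfig

logger = logging.getLogger(__name__)

__all__ = [
    "BedRecord",
    "read_count_matrix",
    "write_count_matrix",
    "read_bed",
    "model_to_json",
    "model_from_json",
    "assignments_frame",
    "write_results",
    "load_dataset",
]


def read_count_matrix(path) -> np.ndarray:
    """Read an N x L non-negative integer matrix from tab-delimited text.

    The first column may be a row label (any non-numeric string); remaining
    cells must be non-negative integers.  Ragged, non-integer or negative
    rows raise a parse error naming the file and line.
    """
    path = Path(path)
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            start = 0
            try:
                float(fields[0])
            except ValueError:
                start = 1
            try:
                vals = [int(v) for v in fields[start:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer cell ({exc})") from None
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}:{lineno}: negative count")
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(vals)} cells, expected {width})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    return np.asarray(rows, dtype=np.int64)


def write_count_matrix(matrix: np.ndarray, path,
                       locus_ids: Optional[Sequence[str]] = None) -> None:
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        for i, row in enumerate(matrix):
            cells = [str(int(v)) for v in row]
            if locus_ids is not None:
                cells.insert(0, str(locus_ids[i]))
            fh.write("\t".join(cells) + "\n")


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."


def read_bed(path) -> list:
    """Parse a BED file (0-based half-open) into locus records.

    Used for labelling and output annotation only.  Strand defaults to '.'
    (unknown) when the column is absent.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            records.append(BedRecord(fields[0], start, end, name, strand))
    return records


def load_dataset(feature_paths: dict, bed_path=None, bin_size=None,
                 window_size=None) -> ChromatinDataset:
    """Assemble a dataset from {feature name: matrix path} plus optional BED."""
    names, counts = [], []
    for name, path in feature_paths.items():
        names.append(name)
        counts.append(read_count_matrix(path))
    locus_ids = None
    if bed_path is not None:
        records = read_bed(bed_path)
        locus_ids = [f"{r.chrom}:{r.start}-{r.end}" if r.name == "." else r.name
                     for r in records]
    ds = ChromatinDataset(counts=counts, feature_names=names, bin_size=bin_size,
                          window_size=window_size, locus_ids=locus_ids)
    n_zero = sum(int(np.sum(X.sum(axis=1) == 0)) for X in ds.counts)
    if n_zero:
        logger.warning("%d all-zero locus/feature rows in the input; their "
                       "Dirichlet-multinomial mass is 1 (n=0) but they carry "
                       "no clustering signal", n_zero)
    return ds


def model_to_json(model: MixtureModel, path, metadata: Optional[dict] = None) -> None:
    payload = {
        "alpha": model.alpha.tolist(),
        "pi": model.pi.tolist(),
        "xi": model.xi.tolist(),
        "zeta": model.zeta.tolist(),
        "config": {
            "shift_enabled": model.config.shift_enabled,
            "flip_enabled": model.config.flip_enabled,
            "max_shift_bp": model.config.max_shift_bp,
            "bin_size": model.config.bin_size,
            "shift_prior_kind": model.config.shift_prior_kind,
        },
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path) -> MixtureModel:
    with open(path) as fh:
        payload = json.load(fh)
    config = ShiftFlipConfig(**payload["config"])
    return MixtureModel(
        alpha=np.asarray(payload["alpha"]),
        pi=np.asarray(payload["pi"]),
        xi=np.asarray(payload["xi"]),
        zeta=np.asarray(payload["zeta"]),
        config=config,
    )


def assignments_frame(fit_result, locus_ids=None) -> pd.DataFrame:
    """Tidy per-locus table: cluster, posterior, shift (bp), flip."""
    marg = fit_result.responsibilities.cluster_marginals
    rows = []
    for i, a in enumerate(fit_result.assignments):
        rows.append({
            "locus": locus_ids[i] if locus_ids is not None else f"locus{i + 1}",
            "cluster": a.cluster,
            "posterior": float(marg[i, a.cluster - 1]),
            "shift_bp": a.shift_bp,
            "flip": a.flip_state,
        })
    return pd.DataFrame(rows)


def check_outdir(outdir) -> Path:
    """Pre-flight check: the output directory exists (or is creatable) and is
    writable, before any compute starts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    return outdir


def write_results(fit_result, outdir, dataset: Optional[ChromatinDataset] = None,
                  selection_table=None, metadata: Optional[dict] = None) -> dict:
    """Emit the standard result files; returns {kind: path}.

    assignments.tsv, model.json (with run metadata, including the parameter-
    count convention used by BIC/AIC), selection.tsv (when a K sweep was
    run), realigned count matrices and aggregate profiles per feature.
    """
    from .evaluate import aggregate_profiles
    from .shift_flip import realign_profiles

    outdir = check_outdir(outdir)
    written = {}
    locus_ids = dataset.locus_ids if dataset is not None else None

    path = outdir / "assignments.tsv"
    assignments_frame(fit_result, locus_ids).to_csv(path, sep="\t", index=False)
    written["assignments"] = path

    meta = {
        "seed": fit_result.seed,
        "converged": fit_result.converged,
        "n_iterations": fit_result.n_iterations,
        "log_posterior": fit_result.log_posterior,
        "log_likelihood": fit_result.log_likelihood,
        "n_parameters_convention": "K*M*L_ext + (K-1); shift-extended length "
                                   "counted, fixed priors and hyperparameters not",
        "bin_index_convention": "1-based, j = 1..L",
    }
    meta.update(metadata or {})
    path = outdir / "model.json"
    model_to_json(fit_result.model, path, metadata=meta)
    written["model"] = path

    if selection_table is not None:
        path = outdir / "selection.tsv"
        selection_table.to_tsv(path)
        written["selection"] = path

    if dataset is not None:
        realigned = realign_profiles(dataset, fit_result.assignments)
        for m, name in enumerate(realigned.feature_names):
            path = outdir / f"realigned_{name}.tsv"
            write_count_matrix(realigned.counts[m], path, locus_ids)
            written[f"realigned_{name}"] = path
        agg = aggregate_profiles(dataset, fit_result.assignments,
                                 n_clusters=fit_result.model.n_components)
        path = outdir / "aggregate_profiles.tsv"
        with open(path, "w") as fh:
            fh.write("cluster\tfeature\t" +
                     "\t".join(f"bin{j + 1}" for j in range(agg.shape[2])) + "\n")
            for k in range(agg.shape[0]):
                for m in range(agg.shape[1]):
                    vals = "\t".join(f"{v:.6g}" for v in agg[k, m])
                    fh.write(f"{k + 1}\t{dataset.feature_names[m]}\t{vals}\n")
        written["aggregate_profiles"] = path
    return written
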