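"""AIC/BIC computation and selection of the number of clusters.

Criteria are computed from the maximized observed-data log-likelihood (shift
and flip states marginalised, prior excluded), so the regularisation strength
does not distort model comparison.  The parameter count covers the optimized
quantities only: the extended concentration vectors (K * M * L_ext) and the
free mixture weights (K - 1); fixed shift/flip priors and hyperparameters are
not counted.  Ties in the selection go to the smaller K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import ChromatinDataset, Hyperparameters, ShiftFlipConfig
from .em import FitResult, fit

logger = logging.getLogger(__name__)

__all__ = ["SelectionTable", "n_parameters", "information_criteria", "select_k"]


def n_parameters(K: int, M: int, L_ext: int) -> int:
    return K * M * L_ext + (K - 1)


def information_criteria(fit_result: FitResult, N: int) -> tuple:
    """(AIC, BIC) of a fit on N loci.

    AIC = 2 p - 2 logL and BIC = p ln(N) - 2 logL with p the number of free
    parameters and logL the maximized marginal log-likelihood.
    """
    model = fit_result.model
    p = n_parameters(model.n_components, model.n_features, model.extended_length)
    logL = fit_result.log_likelihood
    aic = 2.0 * p - 2.0 * logL
    bic = p * np.log(N) - 2.0 * logL
    return float(aic), float(bic)


@dataclass
class SelectionTable:
    """One row per fitted K, with AIC/BIC and the chosen flags."""

    frame: pd.DataFrame

    @property
    def best_aic(self) -> int:
        return int(self.frame.loc[self.frame["AIC"].idxmin(), "K"])

    @property
    def best_bic(self) -> int:
        return int(self.frame.loc[self.frame["BIC"].idxmin(), "K"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def select_k(dataset: ChromatinDataset, K_range: Sequence[int],
             config: Optional[ShiftFlipConfig] = None,
             hyper: Optional[Hyperparameters] = None,
             n_restarts: int = 1, max_iter: int = 200, tol: float = 1e-6,
             seed: int = 0) -> tuple:
    """Fit every K in ``K_range``; report the AIC- and BIC-optimal fits.

    Returns (SelectionTable, {"AIC": best fit, "BIC": best fit}).  A fit
    failure for one K is logged and the remaining K values continue; with
    ties, the smaller K wins (idxmin on a K-sorted frame).
    """
    K_range = sorted(set(int(K) for K in K_range))
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rows = []
    fits = {}
    for K in K_range:
        try:
            res = fit(dataset, K, config=config, hyper=hyper,
                      n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                      seed=seed)
        except RuntimeError as exc:
            logger.warning("fit failed for K=%d: %s", K, exc)
            continue
        aic, bic = information_criteria(res, dataset.n_loci)
        p = n_parameters(res.model.n_components, res.model.n_features,
                         res.model.extended_length)
        rows.append({"K": K, "log_likelihood": res.log_likelihood,
                     "n_parameters": p, "AIC": aic, "BIC": bic,
                     "n_restarts": n_restarts})
        fits[K] = res
    if not rows:
        raise RuntimeError("no K in the range could be fitted")
    frame = pd.DataFrame(rows).sort_values("K", kind="stable").reset_index(drop=True)
    frame["chosen_aic"] = frame["K"] == int(frame.loc[frame["AIC"].idxmin(), "K"])
    frame["chosen_bic"] = frame["K"] == int(frame.loc[frame["BIC"].idxmin(), "K"])
    table = SelectionTable(frame)
    best = {"AIC": fits[table.best_aic], "BIC": fits[table.best_bic]}
    return table, best
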