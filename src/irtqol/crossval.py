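"""K-fold cross-validation of model fit and parameter/score stability.

The protocol: split persons into k (default 5) equal parts; for each part,
fit the model on the remaining k-1 parts (training set), evaluate fit on
the held-out part with the training parameters frozen, refit on the
held-out part with no additional constraints, and record per-parameter
differences (standardized loadings, intercepts in logits) and per-person
score differences relative to score standard errors.

Conventions: factors are matched by structure position (confirmatory
patterns leave no rotational ambiguity); a validation factor whose summed
loading product with the training fit is negative is sign-flipped before
deltas are computed.  Frozen-parameter evaluation uses df equal to the
number of margin statistics (no parameters estimated on the validation
part); this is logged by the M2 routine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FittedModel, QuadratureSpec, fit_em, marginal_loglik
from .fit_stats import FitReport, fit_report
from .io import ResponseMatrix
from .scoring import irt_scores, standardized_loadings
from .structures import LatentStructure

logger = logging.getLogger("irtqol")

__all__ = ["kfold_split", "cross_validate", "CVResult", "FoldResult"]


def kfold_split(n_persons: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random fold assignment: sizes differ by at most 1; deterministic."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_persons:
        raise ValueError(f"k={k} exceeds n_persons={n_persons}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_persons)
    folds = np.empty(n_persons, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


@dataclass
class FoldResult:
    fold: int
    n_train: int
    n_validation: int
    report: FitReport
    val_loglik_frozen: float
    loading_delta: np.ndarray
    intercept_delta: np.ndarray
    score_delta: np.ndarray
    score_se: np.ndarray
    train_converged: bool
    val_converged: bool

    @property
    def frac_score_within_se(self) -> float:
        return float(np.mean(np.abs(self.score_delta) < self.score_se))


@dataclass
class CVResult:
    """Per-fold validation reports and stability deltas."""

    folds: list
    k: int
    seed: int
    notes: list = field(default_factory=list)

    def summary(self) -> dict:
        loading = np.concatenate([np.abs(f.loading_delta).ravel()
                                  for f in self.folds])
        intercept = np.concatenate([np.abs(f.intercept_delta).ravel()
                                    for f in self.folds])
        within = [f.frac_score_within_se for f in self.folds]
        return {
            "median_abs_loading_delta": float(np.median(loading)),
            "max_abs_loading_delta": float(np.max(loading)),
            "median_abs_intercept_delta": float(np.median(intercept)),
            "max_abs_intercept_delta": float(np.max(intercept)),
            "frac_scores_within_se": float(np.mean(within)),
            "n_folds_converged": int(sum(f.train_converged and f.val_converged
                                         for f in self.folds)),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"fold": f.fold, "n_train": f.n_train,
                   "n_validation": f.n_validation,
                   "val_loglik_frozen": f.val_loglik_frozen,
                   "frac_scores_within_se": f.frac_score_within_se,
                   "median_abs_loading_delta":
                       float(np.median(np.abs(f.loading_delta))),
                   "median_abs_intercept_delta":
                       float(np.median(np.abs(f.intercept_delta)))}
            row.update({k: v for k, v in f.report.to_row().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _sign_align(train: FittedModel, val: FittedModel) -> FittedModel:
    """Flip validation factors whose loading product with training is < 0."""
    A_train = np.vstack([p.slopes for p in train.items])
    A_val = np.vstack([p.slopes for p in val.items])
    flips = np.sign(np.sum(A_train * A_val, axis=0))
    flips[flips == 0] = 1.0
    if np.all(flips > 0):
        return val
    from .items import ItemParameters

    items = [ItemParameters(p.slopes * flips, p.intercepts) for p in val.items]
    out = FittedModel(**{**val.__dict__, "items": items})
    return out


def cross_validate(
    data: ResponseMatrix,
    s: LatentStructure,
    k: int = 5,
    seed: int = 0,
    quad: QuadratureSpec | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_categories=None,
    compute_fit_indices: bool = True,
) -> CVResult:
    """Run the k-fold protocol; non-converging folds are flagged, not fatal."""
    folds = kfold_split(data.n_persons, k, seed)
    results = []
    notes = []
    for f in range(k):
        val_idx = np.nonzero(folds == f)[0]
        train_idx = np.nonzero(folds != f)[0]
        train_data = data.subset(train_idx)
        val_data = data.subset(val_idx)
        train_model = fit_em(train_data, s, quad=quad, max_iter=max_iter,
                             tol=tol, seed=seed, n_categories=n_categories)
        val_model = fit_em(val_data, s, quad=quad, max_iter=max_iter,
                           tol=tol, seed=seed, n_categories=n_categories)
        if not train_model.converged or not val_model.converged:
            notes.append(f"fold {f}: non-convergence "
                         f"(train={train_model.converged}, "
                         f"val={val_model.converged})")
            logger.warning(notes[-1])
        val_model = _sign_align(train_model, val_model)
        lam_delta = standardized_loadings(train_model) - standardized_loadings(val_model)
        ic_delta = np.concatenate([
            t.intercepts - v.intercepts
            for t, v in zip(train_model.items, val_model.items)])
        # validation persons scored under both parameterizations
        scores_frozen = irt_scores(val_data, train_model)
        scores_refit = irt_scores(val_data, val_model)
        gi = s.general_indices
        delta = scores_frozen.estimates[:, gi] - scores_refit.estimates[:, gi]
        se = scores_frozen.ses[:, gi]
        if compute_fit_indices:
            report = fit_report(val_data, train_model, frozen=True)
        else:
            report = FitReport(np.nan, np.nan, np.nan, 0, np.nan, np.nan,
                               (np.nan, np.nan), np.nan, np.nan, np.nan)
        results.append(FoldResult(
            fold=f, n_train=train_idx.size, n_validation=val_idx.size,
            report=report,
            val_loglik_frozen=marginal_loglik(val_data, train_model),
            loading_delta=lam_delta, intercept_delta=ic_delta,
            score_delta=delta, score_se=se,
            train_converged=train_model.converged,
            val_converged=val_model.converged,
        ))
    return CVResult(results, k, seed, notes)
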