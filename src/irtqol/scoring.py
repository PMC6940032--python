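"""Latent-trait scores, precision, reliability, loadings, and ECV.

Trait estimates follow the protocol's switch: expected a posteriori (EAP)
scores for models with at most two integral dimensions, maximum a
posteriori (MAP) scores otherwise (the posterior mean becomes expensive to
tabulate in higher dimensions, while the mode is cheap); either can be
requested explicitly.  Standard errors are the posterior SD (EAP) or the
inverse-curvature SD at the mode (MAP), in logits.

Standardized loadings convert logistic slopes through the normal-ogive
constant 1.702: ``lambda_f = (a_f/1.702) / sqrt(1 + sum_f (a_f/1.702)^2)``
per item.  Explained common variance (ECV) of a general factor is its
share of the summed squared standardized loadings.  Empirical reliability
is ``var(estimates) / (var(estimates) + mean(SE^2))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimation import FittedModel, _engine_for
from .io import ResponseMatrix
from .items import MISSING
from .structures import integral_dimension

logger = logging.getLogger("irtqol")

__all__ = [
    "PersonScores",
    "eap_scores",
    "map_scores",
    "irt_scores",
    "empirical_reliability",
    "standardized_loadings",
    "ecv",
    "score_correlations",
]

#: Normal-ogive scaling constant used only for standardized-loading conversion.
OGIVE = 1.702


@dataclass
class PersonScores:
    """Per-person, per-factor trait estimates and standard errors (logits)."""

    estimates: np.ndarray
    ses: np.ndarray
    method: str
    person_ids: tuple
    factor_names: tuple

    @property
    def n_persons(self) -> int:
        return self.estimates.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: person, factor, estimate, SE, method."""
        rows = []
        for i, pid in enumerate(self.person_ids):
            for f, name in enumerate(self.factor_names):
                rows.append((pid, name, self.estimates[i, f], self.ses[i, f],
                             self.method))
        return pd.DataFrame(rows, columns=["person", "factor", "estimate", "se",
                                           "method"])

    def frame(self) -> pd.DataFrame:
        """Wide estimates: persons x factors."""
        return pd.DataFrame(self.estimates, index=list(self.person_ids),
                            columns=list(self.factor_names))


def _retained(data: ResponseMatrix):
    keep = ~(data.values == MISSING).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("scoring: excluding %d all-missing person(s)", n_dropped)
    values = data.values[keep]
    ids = tuple(np.asarray(data.person_ids, dtype=object)[keep])
    return values, ids


def eap_scores(data: ResponseMatrix, model: FittedModel) -> PersonScores:
    """Posterior means and SDs per factor via the model's quadrature."""
    values, ids = _retained(data)
    X, inverse = np.unique(values, axis=0, return_inverse=True)
    engine = _engine_for(model)
    logLi, logLtot, logLc = engine.pattern_loglik(X)
    post_g = np.exp(engine.gen_logw + logLtot - logLi[:, None])  # (npat, G)
    F = model.structure.n_factors
    npat = X.shape[0]
    means = np.zeros((npat, F))
    second = np.zeros((npat, F))
    for col, f in enumerate(model.structure.general_indices):
        means[:, f] = post_g @ engine.gen_nodes[:, col]
        second[:, f] = post_g @ engine.gen_nodes[:, col] ** 2
    if engine.has_specifics:
        ones = np.ones(npat)
        for ci, (f, idx) in enumerate(engine.clusters):
            cp = engine.cluster_posterior(X, ones, logLi, logLtot, logLc, ci)
            ps = cp.sum(axis=1)  # (npat, S)
            means[:, f] = ps @ engine.spec_nodes
            second[:, f] = ps @ engine.spec_nodes**2
    var = np.clip(second - means**2, 0.0, None)
    return PersonScores(means[inverse], np.sqrt(var)[inverse], "EAP", ids,
                        model.structure.factor_names)


def _posterior_logp_grad_hess(theta, values, model: FittedModel, prior_prec):
    """Log posterior, gradient, and Hessian per person (vectorized)."""
    n, F = theta.shape
    logp = -0.5 * np.einsum("ni,ij,nj->n", theta, prior_prec, theta)
    grad = -theta @ prior_prec
    hess = np.broadcast_to(-prior_prec, (n, F, F)).copy()
    idx = np.arange(n)
    for j, params in enumerate(model.items):
        x = values[:, j]
        obs = x != MISSING
        if not obs.any():
            continue
        z = theta @ params.slopes  # (n,)
        cum = expit(z[None, :] + params.intercepts[:, None])  # (K-1, n)
        P = -np.diff(np.vstack([np.ones(n), cum, np.zeros(n)]), axis=0)
        P = np.clip(P, 1e-300, None)
        U = np.vstack([np.zeros(n), cum * (1 - cum), np.zeros(n)])  # (K+1, n)
        dU = np.vstack([np.zeros(n),
                        cum * (1 - cum) * (1 - 2 * cum),
                        np.zeros(n)])
        xo = x.copy()
        xo[~obs] = 0  # placeholder; masked out below
        pk = P[xo, idx]
        num = U[xo, idx] - U[xo + 1, idx]
        dnum = dU[xo, idx] - dU[xo + 1, idx]
        g1 = np.where(obs, num / pk, 0.0)
        g2 = np.where(obs, dnum / pk - (num / pk) ** 2, 0.0)
        logp += np.where(obs, np.log(pk), 0.0)
        grad += g1[:, None] * params.slopes[None, :]
        hess += g2[:, None, None] * np.outer(params.slopes, params.slopes)[None]
    return logp, grad, hess


def map_scores(data: ResponseMatrix, model: FittedModel,
               max_iter: int = 50, tol: float = 1e-8) -> PersonScores:
    """Posterior modes via damped Newton ascent; SE from inverse curvature.

    Initialization is the EAP estimate (a grid-based start, which makes the
    ascent robust when the posterior is flat or mildly multimodal); steps
    are halved until the posterior improves.
    """
    values, ids = _retained(data)
    eap = eap_scores(data, model)
    theta = eap.estimates.copy()
    F = model.structure.n_factors
    prior_prec = np.eye(F)
    gi = model.structure.general_indices
    if gi.size:
        prior_prec[np.ix_(gi, gi)] = np.linalg.inv(model.general_corr)
    logp, grad, hess = _posterior_logp_grad_hess(theta, values, model, prior_prec)
    for _ in range(max_iter):
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        new_theta = theta - step
        new_logp, new_grad, new_hess = _posterior_logp_grad_hess(
            new_theta, values, model, prior_prec)
        worse = new_logp < logp - 1e-12
        halvings = 0
        while worse.any() and halvings < 12:
            step[worse] *= 0.5
            new_theta = theta - step
            new_logp, new_grad, new_hess = _posterior_logp_grad_hess(
                new_theta, values, model, prior_prec)
            worse = new_logp < logp - 1e-12
            halvings += 1
        if worse.any():
            logger.info("MAP: %d person(s) kept at grid-initialized point",
                        int(worse.sum()))
            new_theta[worse] = theta[worse]
            new_logp, new_grad, new_hess = _posterior_logp_grad_hess(
                new_theta, values, model, prior_prec)
        moved = np.abs(new_theta - theta).max()
        theta, logp, grad, hess = new_theta, new_logp, new_grad, new_hess
        if moved < tol:
            break
    cov = np.linalg.inv(-hess)
    ses = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    return PersonScores(theta, ses, "MAP", ids, model.structure.factor_names)


def irt_scores(data: ResponseMatrix, model: FittedModel,
               method: str | None = None) -> PersonScores:
    """Protocol switch: EAP for <= 2 integral dimensions, MAP otherwise."""
    if method is None:
        method = "EAP" if integral_dimension(model.structure) <= 2 else "MAP"
    method = method.upper()
    if method == "EAP":
        return eap_scores(data, model)
    if method == "MAP":
        return map_scores(data, model)
    raise ValueError(f"unknown scoring method {method!r}")


def empirical_reliability(scores: PersonScores, factor: int = 0) -> float:
    """Empirical internal consistency of one trait.

    ``var(estimates) / (var(estimates) + mean(SE^2))``; >= 0.70 is the
    conventional acceptability threshold.
    """
    if scores.n_persons < 2:
        raise ValueError("need at least 2 scored persons")
    est = scores.estimates[:, factor]
    se2 = scores.ses[:, factor] ** 2
    v = float(np.var(est, ddof=1))
    if v == 0.0:
        logger.warning("zero score variance on factor %d; reliability 0", factor)
        return 0.0
    return v / (v + float(np.mean(se2)))


def standardized_loadings(model: FittedModel) -> np.ndarray:
    """Items x factors standardized loading matrix.

    ``lambda = (a/1.702) / sqrt(1 + sum_f (a_f/1.702)^2)`` per item; the
    communality ``sum_f lambda_f^2`` is below 1 for every item.
    """
    A = np.vstack([p.slopes for p in model.items]) / OGIVE
    denom = np.sqrt(1.0 + np.sum(A**2, axis=1, keepdims=True))
    return A / denom


def ecv(model: FittedModel) -> np.ndarray:
    """Explained common variance per general factor.

    ``sum_items lambda_g^2 / sum_items sum_f lambda_f^2``; values summed
    over all general factors >= 0.85 suggest a unidimensional model would
    be sufficiently complex.
    """
    gi = model.structure.general_indices
    if gi.size == 0:
        raise ValueError("model has no general factor")
    lam2 = standardized_loadings(model) ** 2
    total = lam2.sum()
    return lam2[:, gi].sum(axis=0) / total


def _as_frame(scores) -> pd.DataFrame:
    if isinstance(scores, PersonScores):
        return scores.frame()
    return pd.DataFrame(scores)


def score_correlations(scores_a, scores_b=None, min_n: int = 3,
                       pairwise: bool = False):
    """Product-moment correlations between score sets (convergent validity).

    Accepts :class:`PersonScores` or data frames (e.g., conventional
    scores).  Persons are matched on index; the default policy keeps
    complete cases only (``pairwise=True`` switches to pairwise-complete).
    Returns ``(correlation DataFrame, n_used)``.
    """
    A = _as_frame(scores_a)
    if scores_b is None:
        combined = A
    else:
        B = _as_frame(scores_b)
        combined = A.join(B, how="inner", lsuffix="", rsuffix="_b")
    if not pairwise:
        combined = combined.dropna()
    n = len(combined)
    if n < min_n:
        raise ValueError(f"only {n} overlapping person(s); need >= {min_n}")
    return combined.corr(), n
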