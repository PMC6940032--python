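"""Model-selection and goodness-of-fit machinery.

Scale level: AIC/BIC, the limited-information M2 statistic on univariate
and bivariate response margins with its chi-square reference, RMSEA (with
a 90% interval via noncentrality inversion), SRMSR, and TLI/CFI against an
independence null.  Item level: residual correlations, the rest-score
S-X2 statistic (unidimensional models), and observed-vs-expected category
proportions by trait level.  Person level: the standardized
log-likelihood statistic Zh.

Conventions (the source methodology leaves these open; they are declared,
not asserted as equivalent to any particular software):

* M2 margins are all univariate and bivariate category probabilities with
  category 0 dropped (full cross-classification).  The statistic is
  computed on complete cases, since the multinomial asymptotics of the
  margin proportions assume a common sample size.
* Item-score correlations (SRMSR, residual correlations) use raw category
  scores 0..K-1, not polychorics.
* The TLI/CFI null model fixes every slope at zero with free intercepts.
* S-X2 pools adjacent rest-score groups until every expected cell count
  is at least 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .estimation import FittedModel, _engine_for, fit_null
from .io import ResponseMatrix
from .items import MISSING
from .structures import integral_dimension

logger = logging.getLogger("irtqol")

__all__ = [
    "FitReport",
    "PersonFit",
    "information_criteria",
    "m2_statistic",
    "rmsea_from_m2",
    "srmsr",
    "tli_cfi",
    "residual_correlations",
    "item_fit_sx2",
    "observed_expected_by_score",
    "zh_person_fit",
    "fit_report",
]


@dataclass
class FitReport:
    """Scale-level fit summary for one candidate model."""

    aic: float
    bic: float
    m2: float
    df_m2: int
    p_m2: float
    rmsea: float
    rmsea_ci: tuple
    srmsr: float
    tli: float
    cfi: float
    loglik: float = np.nan
    n_params: int = 0

    def to_row(self) -> dict:
        return {
            "aic": self.aic, "bic": self.bic, "m2": self.m2, "df": self.df_m2,
            "p": self.p_m2, "rmsea": self.rmsea, "rmsea_lo": self.rmsea_ci[0],
            "rmsea_hi": self.rmsea_ci[1], "srmsr": self.srmsr, "tli": self.tli,
            "cfi": self.cfi, "loglik": self.loglik, "n_params": self.n_params,
        }


@dataclass
class PersonFit:
    """Zh per person; NaN where fewer than 2 non-missing responses."""

    zh: np.ndarray
    person_ids: tuple
    summary: dict = field(default_factory=dict)


def information_criteria(model: FittedModel) -> tuple:
    """``AIC = -2 loglik + 2 q``; ``BIC = -2 loglik + q log N``."""
    if not model.converged:
        raise ValueError("information criteria require a converged model")
    aic = -2.0 * model.loglik + 2.0 * model.n_params
    bic = -2.0 * model.loglik + model.n_params * np.log(model.n_persons)
    return aic, bic


# ---------------------------------------------------------------------------
# Model-implied margins, their derivatives, and the M2 machinery.


class _MarginEngine:
    """Model-implied joint category margins under two-tier reduction."""

    def __init__(self, model: FittedModel):
        self.model = model
        self.engine = _engine_for(model)
        self.gen_w = np.exp(self.engine.gen_logw)
        self.spec_w = np.exp(self.engine.spec_logw)
        self.cluster_of = model.structure.cluster_of()
        self.has_specifics = self.engine.has_specifics
        # probability tables per item on the engine grid
        self.P = [self.engine.category_prob_table(j) for j in range(model.n_items)]
        # reduced (specific-integrated) tables, shape (K, G)
        if self.has_specifics:
            self.Pg = [T @ self.spec_w for T in self.P]
        else:
            self.Pg = self.P
        self._joint_cache: dict = {}

    # -- joint category tables -----------------------------------------

    def joint_table(self, items: tuple) -> np.ndarray:
        """Joint category probabilities of an item subset; shape (K_i, ...)."""
        items = tuple(items)
        if items in self._joint_cache:
            return self._joint_cache[items]
        letters = "abcdefh"
        if len(items) > len(letters):
            raise ValueError("joint_table supports at most 7 items")
        # group by cluster so each specific factor is integrated once
        order: list = []
        tensors: list = []
        if self.has_specifics:
            by_cluster: dict = {}
            for pos, j in enumerate(items):
                by_cluster.setdefault(self.cluster_of[j], []).append(pos)
            for members in by_cluster.values():
                subs, ops = [], []
                for m, pos in enumerate(members):
                    ops.append(self.P[items[pos]])
                    subs.append(letters[len(order) + m] + "gs")
                ops.append(self.spec_w)
                subs.append("s")
                out = "".join(letters[len(order):len(order) + len(members)]) + "g"
                tensors.append(np.einsum(",".join(subs) + "->" + out, *ops))
                order.extend(members)
        else:
            for pos, j in enumerate(items):
                tensors.append(self.Pg[j])
                order.append(pos)
        # multiply group tensors over the shared general grid, then integrate
        R = tensors[0]
        used = R.ndim - 1
        for T in tensors[1:]:
            subR = letters[:used] + "g"
            extra = T.ndim - 1
            subT = letters[used:used + extra] + "g"
            R = np.einsum(f"{subR},{subT}->{letters[:used + extra]}g", R, T)
            used += extra
        table = np.einsum(f"{letters[:used]}g,g->{letters[:used]}", R, self.gen_w)
        # order[] maps output axes to positions in `items`; invert it
        perm = np.argsort(order)
        table = np.transpose(table, perm)
        self._joint_cache[items] = table
        return table

    # -- derivative tables ----------------------------------------------

    def _item_deriv(self, j: int):
        """dP/d(free params) on the engine grid; shape (K, n_par, grid...)."""
        params = self.model.items[j]
        eng = self.engine
        a_gen = params.slopes[eng.gen_idx]
        z = eng.gen_nodes @ a_gen
        theta_cols = []
        if self.model.slopes_fixed:
            free = np.array([], dtype=int)
        else:
            free = np.nonzero(self.model.structure.pattern[j])[0]
        cl = self.cluster_of[j]
        if cl >= 0:
            z = z[:, None] + params.slopes[cl] * eng.spec_nodes[None, :]
            for f in free:
                if f == cl:
                    theta_cols.append(np.broadcast_to(
                        eng.spec_nodes[None, :], z.shape))
                else:
                    col = np.where(eng.gen_idx == f)[0][0]
                    theta_cols.append(np.broadcast_to(
                        eng.gen_nodes[:, col][:, None], z.shape))
        else:
            for f in free:
                col = np.where(eng.gen_idx == f)[0][0]
                theta_cols.append(eng.gen_nodes[:, col])
        cum = expit(z[None, ...] + params.intercepts.reshape(
            (-1,) + (1,) * z.ndim))
        u = cum * (1 - cum)  # (K-1, grid)
        K = params.n_categories
        n_par = len(free) + (K - 1)
        dP = np.zeros((K, n_par) + z.shape)
        # slope derivatives: theta_f * (u_k - u_{k+1})
        pad = np.concatenate([np.zeros((1,) + z.shape), u,
                              np.zeros((1,) + z.shape)])
        num = -np.diff(pad, axis=0)  # (K, grid): u_k - u_{k+1}
        for p, tcol in enumerate(theta_cols):
            dP[:, p] = tcol * num
        # intercept derivatives: +u_m at k=m+1, -u_m at k=m
        for m in range(K - 1):
            dP[m + 1, len(free) + m] += u[m]
            dP[m, len(free) + m] -= u[m]
        return dP, len(free)

    def margin_stats(self):
        """List of (items, cats) margin statistics, category 0 dropped."""
        J = self.model.n_items
        Ks = self.model.n_categories()
        stats_list = []
        for j in range(J):
            for k in range(1, Ks[j]):
                stats_list.append(((j,), (k,)))
        for i, j in itertools.combinations(range(J), 2):
            for k in range(1, Ks[i]):
                for l in range(1, Ks[j]):
                    stats_list.append(((i, j), (k, l)))
        return stats_list

    def model_margins(self, stats_list) -> np.ndarray:
        pi = np.empty(len(stats_list))
        for r, (items, cats) in enumerate(stats_list):
            pi[r] = self.joint_table(items)[cats]
        return pi

    def xi_matrix(self, stats_list, pi) -> np.ndarray:
        """Asymptotic covariance of the margin proportions (times N)."""
        s = len(stats_list)
        xi = np.empty((s, s))
        for r in range(s):
            items_r, cats_r = stats_list[r]
            map_r = dict(zip(items_r, cats_r))
            for c in range(r, s):
                items_c, cats_c = stats_list[c]
                merged = dict(map_r)
                ok = True
                for it, ct in zip(items_c, cats_c):
                    if merged.setdefault(it, ct) != ct:
                        ok = False
                        break
                if not ok:
                    e = 0.0
                else:
                    union = tuple(sorted(merged))
                    e = float(self.joint_table(union)[
                        tuple(merged[it] for it in union)])
                xi[r, c] = xi[c, r] = e - pi[r] * pi[c]
        return xi

    def jacobian(self, stats_list) -> np.ndarray:
        """d(model margins)/d(free parameters), items then correlations."""
        model = self.model
        J = model.n_items
        # per-item reduced derivative tables: (K, n_par, G)
        dPg = []
        n_par_items = []
        for j in range(J):
            dP, n_free = self._item_deriv(j)
            if dP.ndim == 4:  # clustered: integrate the specific dimension
                dPg.append(dP @ self.spec_w)
            else:
                dPg.append(dP)
            n_par_items.append(dP.shape[1])
        offsets = np.concatenate([[0], np.cumsum(n_par_items)])
        s_struct = model.structure
        n_corr = 0
        if s_struct.oblique_general and s_struct.n_general > 1:
            g = s_struct.n_general
            n_corr = g * (g - 1) // 2
        q = offsets[-1] + n_corr
        delta = np.zeros((len(stats_list), q))
        for r, (items, cats) in enumerate(stats_list):
            if len(items) == 1:
                (j,), (k,) = items, cats
                delta[r, offsets[j]:offsets[j + 1]] = dPg[j][k] @ self.gen_w
            else:
                (i, j), (k, l) = items, cats
                same = (self.has_specifics
                        and self.cluster_of[i] == self.cluster_of[j])
                if same:
                    # joint integration over the shared specific factor
                    d_i = np.einsum("pgs,gs,s->pg", self._deriv_full(i)[k],
                                    self.P[j][l], self.spec_w)
                    d_j = np.einsum("gs,pgs,s->pg", self.P[i][k],
                                    self._deriv_full(j)[l], self.spec_w)
                else:
                    d_i = dPg[i][k][:, :] * self.Pg[j][l][None, :]
                    d_j = self.Pg[i][k][None, :] * dPg[j][l][:, :]
                delta[r, offsets[i]:offsets[i + 1]] = d_i @ self.gen_w
                delta[r, offsets[j]:offsets[j + 1]] += d_j @ self.gen_w
        if n_corr:
            delta[:, offsets[-1]:] = self._corr_jacobian(stats_list)
        return delta

    def _deriv_full(self, j: int) -> np.ndarray:
        if not hasattr(self, "_deriv_cache"):
            self._deriv_cache: dict = {}
        if j not in self._deriv_cache:
            self._deriv_cache[j] = self._item_deriv(j)[0]
        return self._deriv_cache[j]

    def _corr_jacobian(self, stats_list) -> np.ndarray:
        """Central finite differences in the Cholesky-angle parameterization."""
        from .estimation import _angles_to_corr, _corr_to_angles, _mvn_logw

        angles0 = _corr_to_angles(self.model.general_corr)
        F = self.model.structure.n_general
        h = 1e-5
        cols = []
        saved_w = self.gen_w
        for p in range(angles0.size):
            vals = []
            for sign in (+1, -1):
                ang = angles0.copy()
                ang[p] += sign * h
                R = _angles_to_corr(ang, F)
                self.gen_w = np.exp(_mvn_logw(self.engine.gen_nodes, R))
                self._joint_cache = {}
                vals.append(self.model_margins(stats_list))
            cols.append((vals[0] - vals[1]) / (2 * h))
        self.gen_w = saved_w
        self._joint_cache = {}
        cols_arr = np.column_stack(cols) if cols else np.zeros((len(stats_list), 0))
        return cols_arr


def _observed_margins(values: np.ndarray, stats_list) -> np.ndarray:
    N = values.shape[0]
    p = np.empty(len(stats_list))
    for r, (items, cats) in enumerate(stats_list):
        mask = np.ones(N, dtype=bool)
        for it, ct in zip(items, cats):
            mask &= values[:, it] == ct
        p[r] = mask.mean()
    return p


def m2_statistic(data: ResponseMatrix, model: FittedModel,
                 frozen: bool = False) -> tuple:
    """Limited-information M2 on univariate + bivariate category margins.

    Returns ``(m2, df, p)``.  ``frozen=True`` treats the parameters as
    known a priori (no Jacobian projection; df equals the number of margin
    statistics), the convention used for cross-validation evaluation with
    training-set estimates.
    """
    complete = data.complete_cases()
    N = complete.n_persons
    if N < 10:
        raise ValueError("too few complete cases for M2")
    logger.info("M2 variant: full univariate+bivariate category margins "
                "(complete cases, N=%d)", N)
    me = _MarginEngine(model)
    stats_list = me.margin_stats()
    pi = me.model_margins(stats_list)
    p = _observed_margins(complete.values, stats_list)
    xi = me.xi_matrix(stats_list, pi)
    q = 0 if frozen else model.n_params
    df = len(stats_list) - q
    if df <= 0:
        raise ValueError(
            f"non-positive degrees of freedom (s={len(stats_list)}, q={q}); "
            "collapse response categories or reduce the parameter count")
    e = p - pi
    try:
        if frozen:
            m2 = N * float(e @ np.linalg.solve(xi, e))
        else:
            delta = me.jacobian(stats_list)
            A = np.linalg.solve(xi, delta)
            xe = np.linalg.solve(xi, e)
            M = delta.T @ A
            proj = A.T @ e
            m2 = N * float(e @ xe - proj @ np.linalg.solve(M, proj))
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular margin covariance matrix; consider collapsing sparse "
            "response categories") from err
    m2 = max(m2, 0.0)
    return m2, int(df), float(stats.chi2.sf(m2, df))


def rmsea_from_m2(m2: float, df: int, n_persons: int,
                  level: float = 0.90) -> tuple:
    """RMSEA point estimate and confidence interval from an M2 statistic.

    ``sqrt(max(m2 - df, 0) / (df (N - 1)))``; the interval inverts the
    noncentral chi-square at the (1-level)/2 and (1+level)/2 tails.
    """
    if df <= 0:
        raise ValueError("RMSEA requires positive degrees of freedom")
    point = np.sqrt(max(m2 - df, 0.0) / (df * (n_persons - 1)))
    lo_q = (1 + level) / 2  # lower bound solves cdf = upper tail
    hi_q = (1 - level) / 2

    def bound(prob):
        if stats.ncx2.cdf(m2, df, 1e-10) < prob:
            return 0.0
        upper = max(m2 * 2, df * 10, 10.0)
        while stats.ncx2.cdf(m2, df, upper) > prob:
            upper *= 2
        lam = brentq(lambda nc: stats.ncx2.cdf(m2, df, nc) - prob, 1e-10, upper)
        return np.sqrt(lam / (df * (n_persons - 1)))

    return float(point), (float(bound(lo_q)), float(bound(hi_q)))


def _implied_score_correlations(model: FittedModel) -> np.ndarray:
    """Model-implied product-moment correlations of raw item scores."""
    me = _MarginEngine(model)
    J = model.n_items
    Ks = model.n_categories()
    means = np.empty(J)
    sds = np.empty(J)
    for j in range(J):
        pj = me.joint_table((j,))
        k = np.arange(Ks[j])
        means[j] = k @ pj
        sds[j] = np.sqrt(max(k**2 @ pj - means[j] ** 2, 1e-300))
    R = np.eye(J)
    for i, j in itertools.combinations(range(J), 2):
        pij = me.joint_table((i, j))
        ki = np.arange(Ks[i])
        kj = np.arange(Ks[j])
        exy = ki @ pij @ kj
        R[i, j] = R[j, i] = (exy - means[i] * means[j]) / (sds[i] * sds[j])
    return R


def _observed_score_correlations(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"item at column {j} is constant in the observed data")
    return np.corrcoef(values.T)


def srmsr(data: ResponseMatrix, model: FittedModel) -> float:
    """Standardized root mean square residual over item-score correlations."""
    if data.n_items < 2:
        raise ValueError("SRMSR requires at least 2 items")
    complete = data.complete_cases()
    r_obs = _observed_score_correlations(complete.values)
    r_mod = _implied_score_correlations(model)
    iu = np.triu_indices(data.n_items, k=1)
    return float(np.sqrt(np.mean((r_obs[iu] - r_mod[iu]) ** 2)))


def residual_correlations(data: ResponseMatrix, model: FittedModel,
                          threshold: float = 0.05):
    """Observed minus model-implied item-score correlations.

    Returns ``(matrix, summary)`` where summary reports the mean absolute
    off-diagonal residual, the count of pairs beyond ``threshold`` and the
    maximum absolute residual — residuals at or below 0.05 are
    conventionally considered negligible.
    """
    complete = data.complete_cases()
    r_obs = _observed_score_correlations(complete.values)
    r_mod = _implied_score_correlations(model)
    resid = r_obs - r_mod
    resid = (resid + resid.T) / 2.0  # exact symmetry despite fp rounding
    np.fill_diagonal(resid, 0.0)
    iu = np.triu_indices(data.n_items, k=1)
    vals = resid[iu]
    summary = {
        "mean_abs": float(np.mean(np.abs(vals))),
        "n_above_threshold": int(np.sum(np.abs(vals) > threshold)),
        "max_abs": float(np.max(np.abs(vals))) if vals.size else 0.0,
        "threshold": threshold,
    }
    return resid, summary


def tli_cfi(m2: float, df: int, m2_null: float, df_null: int) -> tuple:
    """Incremental fit indices relative to the independence null.

    ``TLI = (m2_null/df_null - m2/df) / (m2_null/df_null - 1)``;
    ``CFI = 1 - max(m2-df, 0) / max(m2_null-df_null, m2-df, 0)`` clamped to
    [0, 1].  Values >= 0.90 are conventionally acceptable.
    """
    if df <= 0 or df_null <= 0:
        raise ValueError("degrees of freedom must be positive")
    ratio_null = m2_null / df_null
    if ratio_null <= 1:
        logger.warning("degenerate null model (m2_null/df_null <= 1); "
                       "incremental indices are uninformative")
    tli = (ratio_null - m2 / df) / (ratio_null - 1) if ratio_null != 1 else np.nan
    denom = max(m2_null - df_null, m2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(m2 - df, 0.0) / denom
    return float(tli), float(np.clip(cfi, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Item-level fit.


def _lw_rest_distribution(model: FittedModel, exclude: int,
                          theta: np.ndarray) -> np.ndarray:
    """Polytomous Lord-Wingersky recursion: P(rest score = r | theta).

    Returns an array of shape (max_rest + 1, Q) over the theta grid.
    """
    from .items import category_probabilities_grid

    dist = np.ones((1, theta.shape[0]))
    for j, params in enumerate(model.items):
        if j == exclude:
            continue
        P = category_probabilities_grid(params, theta)  # (K, Q)
        K = P.shape[0]
        new = np.zeros((dist.shape[0] + K - 1, theta.shape[0]))
        for k in range(K):
            new[k:k + dist.shape[0]] += dist * P[k]
        dist = new
    return dist


def item_fit_sx2(data: ResponseMatrix, model: FittedModel, item: int):
    """Rest-score S-X2 item fit for unidimensional models.

    Groups complete-case persons by their rest score (total minus the
    studied item), compares observed to model-expected category counts,
    pooling adjacent rest-score groups until every expected cell is >= 1.
    Returns ``(statistic, df, p, table)``.
    """
    if integral_dimension(model.structure) != 1:
        raise ValueError(
            "S-X2 is defined here for unidimensional models; use "
            "observed_expected_by_score for multidimensional structures")
    from .items import category_probabilities_grid

    complete = data.complete_cases()
    values = complete.values
    N = values.shape[0]
    if N == 0:
        raise ValueError("no complete cases")
    theta = model.quadrature.nodes[:, None]
    w = np.exp(-0.5 * theta[:, 0] ** 2)
    w /= w.sum()
    params = model.items[item]
    K = params.n_categories
    Pj = category_probabilities_grid(params, theta)  # (K, Q)
    S = _lw_rest_distribution(model, item, theta)  # (R+1, Q)
    R_max = S.shape[0] - 1
    rest = values.sum(axis=1) - values[:, item]
    obs = np.zeros((R_max + 1, K))
    for r in range(R_max + 1):
        sel = rest == r
        for k in range(K):
            obs[r, k] = np.sum(values[sel, item] == k)
    # expected probabilities per rest-score group
    denom = S @ w  # (R+1,)
    with np.errstate(invalid="ignore", divide="ignore"):
        E_prob = (S * w) @ Pj.T / denom[:, None]  # (R+1, K)
    n_r = obs.sum(axis=1)
    # pool adjacent groups until all expected cells >= 1
    groups = []
    acc_obs = np.zeros(K)
    acc_exp = np.zeros(K)
    for r in range(R_max + 1):
        if n_r[r] == 0 and not np.isfinite(E_prob[r]).all():
            continue
        acc_obs += obs[r]
        acc_exp += n_r[r] * np.nan_to_num(E_prob[r])
        if acc_exp.min() >= 1.0:
            groups.append((acc_obs.copy(), acc_exp.copy()))
            acc_obs[:] = 0.0
            acc_exp[:] = 0.0
    if acc_obs.sum() > 0 or acc_exp.sum() > 0:
        if groups:
            o, e = groups[-1]
            groups[-1] = (o + acc_obs, e + acc_exp)
        else:
            groups.append((acc_obs.copy(), acc_exp.copy()))
    o_mat = np.array([g[0] for g in groups])
    e_mat = np.array([g[1] for g in groups])
    e_mat = np.clip(e_mat, 1e-10, None)
    statistic = float(np.sum((o_mat - e_mat) ** 2 / e_mat))
    n_item_params = int(np.sum(model.structure.pattern[item])) + (K - 1)
    df = o_mat.size - len(groups) - n_item_params
    if df <= 0:
        df = 1
        logger.warning("S-X2 df non-positive after pooling; reported with df=1")
    table = pd.DataFrame(
        {"group": np.repeat(np.arange(len(groups)), K),
         "category": np.tile(np.arange(K), len(groups)),
         "observed": o_mat.ravel(), "expected": e_mat.ravel()})
    return statistic, int(df), float(stats.chi2.sf(statistic, df)), table


def observed_expected_by_score(data: ResponseMatrix, model: FittedModel,
                               item: int, n_groups: int = 10) -> pd.DataFrame:
    """Observed vs model-expected category proportions by trait level.

    Persons are binned into ``n_groups`` quantile groups of the primary
    (first general factor) EAP score; expected proportions average the
    model's category probabilities over each person's posterior.  Both the
    binning score and the posterior EXCLUDE the studied item (leave-one-out
    conditioning, as in rest-score item fit): conditioning on the item's own
    response would make even a correctly specified model appear to misfit,
    since bin membership and expectation would both depend on the response
    being predicted.  Empty or duplicate-edge bins are merged (logged).
    """
    from .estimation import posterior_weights
    from .scoring import eap_scores

    rest_values = data.values.copy()
    rest_values[:, item] = MISSING
    rest = type(data)(rest_values, data.item_labels, data.person_ids)
    scores = eap_scores(rest, model)
    pw = posterior_weights(rest, model)
    primary = model.structure.general_indices[0]
    est = scores.estimates[:, primary]
    keep = ~(rest_values == MISSING).all(axis=1)
    values = data.values[keep]
    # expected probability per person for this item
    cl = model.structure.cluster_of()[item]
    me_engine = _engine_for(model)
    Pj = me_engine.category_prob_table(item)  # (K, G[, S])
    if cl >= 0:
        post = pw.cluster[cl]  # (n, G, S)
        exp_pp = np.einsum("ngs,kgs->nk", post, Pj)
    else:
        exp_pp = pw.general @ Pj.T  # (n, K)
    cats = pd.qcut(est, q=n_groups, duplicates="drop")
    if cats.categories.size < n_groups:
        logger.info("observed_expected_by_score: %d bins merged due to ties",
                    n_groups - cats.categories.size)
    rows = []
    obs_mask = values[:, item] != MISSING
    for g, interval in enumerate(cats.categories):
        sel = (cats.codes == g) & obs_mask
        n = int(sel.sum())
        if n == 0:
            continue
        x = values[sel, item]
        K = model.items[item].n_categories
        for k in range(K):
            rows.append({
                "group": g, "theta_hi": interval.right, "n": n, "category": k,
                "observed": float(np.mean(x == k)),
                "expected": float(exp_pp[sel, k].mean()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Person fit.


def zh_person_fit(data: ResponseMatrix, model: FittedModel, scores) -> PersonFit:
    """Standardized person log-likelihood Zh at each person's trait estimate.

    ``Zh = (l0 - E[l0]) / sd(l0)`` with the expectation and variance taken
    over the model's category distributions at the estimated theta,
    non-missing items only.  |Zh| < 2 is conventionally acceptable;
    negative values flag unpredictable (misfitting) patterns, positive
    values overly deterministic (overfitting) ones.
    """
    from .items import category_probabilities

    keep = ~(data.values == MISSING).all(axis=1)
    values = data.values[keep]
    if values.shape[0] != scores.n_persons:
        raise ValueError("scores do not match the retained persons of the data")
    n = values.shape[0]
    zh = np.full(n, np.nan)
    theta = scores.estimates
    l0 = np.zeros(n)
    mean_l = np.zeros(n)
    var_l = np.zeros(n)
    n_obs = np.zeros(n, dtype=int)
    idx = np.arange(n)
    for j, params in enumerate(model.items):
        x = values[:, j]
        obs = x != MISSING
        if not obs.any():
            continue
        z = theta @ params.slopes
        cum = expit(z[None, :] + params.intercepts[:, None])
        P = -np.diff(np.vstack([np.ones(n), cum, np.zeros(n)]), axis=0)
        P = np.clip(P, 1e-300, None)
        logP = np.log(P)
        xo = np.where(obs, x, 0)
        l0 += np.where(obs, logP[xo, idx], 0.0)
        m = np.sum(P * logP, axis=0)
        v = np.sum(P * logP**2, axis=0) - m**2
        mean_l += np.where(obs, m, 0.0)
        var_l += np.where(obs, v, 0.0)
        n_obs += obs
    ok = (n_obs >= 2) & (var_l > 0)
    zh[ok] = (l0[ok] - mean_l[ok]) / np.sqrt(var_l[ok])
    defined = zh[np.isfinite(zh)]
    summary = {
        "pct_misfit": float(100 * np.mean(defined < -2)) if defined.size else np.nan,
        "pct_overfit": float(100 * np.mean(defined > 2)) if defined.size else np.nan,
        "n_defined": int(defined.size),
    }
    return PersonFit(zh, scores.person_ids, summary)


# ---------------------------------------------------------------------------
# Convenience report.


def fit_report(data: ResponseMatrix, model: FittedModel,
               null_model: FittedModel | None = None,
               frozen: bool = False) -> FitReport:
    """Assemble the full scale-level fit report for one model."""
    if frozen:
        aic = bic = np.nan
    else:
        aic, bic = information_criteria(model)
    if null_model is None:
        null_model = fit_null(data, model.structure,
                              quad=model.quadrature,
                              n_categories=model.n_categories())
    m2, df, p = m2_statistic(data, model, frozen=frozen)
    m2_n, df_n, _ = m2_statistic(data, null_model)
    N = data.complete_cases().n_persons
    rmsea, ci = rmsea_from_m2(m2, df, N)
    tli, cfi = tli_cfi(m2, df, m2_n, df_n)
    return FitReport(
        aic=aic, bic=bic, m2=m2, df_m2=df, p_m2=p, rmsea=rmsea, rmsea_ci=ci,
        srmsr=srmsr(data, model), tli=tli, cfi=cfi,
        loglik=model.loglik, n_params=model.n_params,
    )
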