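"""Full-information marginal maximum-likelihood estimation.

Models with normally distributed latent traits are fitted by Bock-Aitkin
expectation-maximization on a fixed rectangular quadrature grid with
standard-normal prior weights (renormalized to sum to one).  Structures
with cluster-partitioned orthogonal specific factors use two-tier
dimension reduction: conditional on the general factors, item clusters are
independent and each cluster integrates over its own specific factor, so
the integral dimension is ``n_general + 1`` instead of ``n_factors``.
This caps the quadrature dimension at 3 for every structure shipped here;
structures whose integral dimension exceeds the cap are rejected rather
than silently approximated (a stochastic-approximation estimator for such
models is a non-goal).

The marginal log-likelihood is non-decreasing across EM iterations up to
numerical tolerance; each fit records its iteration history so this can be
asserted.  The M-step runs a bounded quasi-Newton update per item on the
expected complete-data log-likelihood, with intercept gaps log-transformed
to keep the intercepts strictly decreasing, and slopes bounded at zero
under a positive-loadings constraint (a slope at the bound is reported as
0 with a boundary note).  Oblique general-tier correlations are updated by
an exact generalized M-step on the normalized grid prior, parameterized
through hyperspherical Cholesky angles so the correlation matrix stays
positive definite; the update is only accepted when it improves its
objective, preserving EM monotonicity.

Missing responses are treated as ignorable (MAR) and skipped in the
likelihood; persons with all responses missing are dropped with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, logit

from .io import ResponseMatrix
from .items import MISSING, ItemParameters
from .structures import LatentStructure, integral_dimension

logger = logging.getLogger("irtqol")

__all__ = [
    "QuadratureSpec",
    "default_quadrature",
    "FittedModel",
    "fit_em",
    "fit_null",
    "fit_2pl",
    "marginal_loglik",
    "posterior_weights",
    "PosteriorWeights",
]

#: Largest integral dimension handled by fixed-point quadrature.
MAX_INTEGRAL_DIM = 3


@dataclass(frozen=True)
class QuadratureSpec:
    """Equally spaced rectangular grid spanning ``[-bound, bound]`` per dim.

    ``nodes_per_dim`` must be odd (the grid includes 0) and at least 5.
    """

    nodes_per_dim: int
    bound: float = 6.0

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 5 or self.nodes_per_dim % 2 == 0:
            raise ValueError("nodes_per_dim must be odd and >= 5")
        if self.bound <= 0:
            raise ValueError("bound must be positive")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(-self.bound, self.bound, self.nodes_per_dim)


def default_quadrature(integral_dim: int) -> QuadratureSpec:
    """Default grid density by integral dimension: 61 / 21 / 11 nodes."""
    if integral_dim <= 1:
        return QuadratureSpec(61)
    if integral_dim == 2:
        return QuadratureSpec(21)
    return QuadratureSpec(11)


@dataclass
class FittedModel:
    """A fitted (or frozen) multidimensional graded-response model."""

    structure: LatentStructure
    items: list
    general_corr: np.ndarray
    loglik: float
    n_params: int
    n_persons: int
    converged: bool
    iterations: int
    quadrature: QuadratureSpec
    item_labels: tuple = ()
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))
    notes: list = field(default_factory=list)
    #: True for the independence baseline (slopes are constants, not parameters)
    slopes_fixed: bool = False

    @property
    def n_items(self) -> int:
        return len(self.items)

    def n_categories(self) -> list:
        return [p.n_categories for p in self.items]


# ---------------------------------------------------------------------------
# Correlation parameterization: hyperspherical Cholesky angles.


def _angles_to_corr(angles: np.ndarray, F: int) -> np.ndarray:
    L = np.zeros((F, F))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, F):
        row_angles = angles[pos:pos + i]
        pos += i
        sin_prod = 1.0
        for j in range(i):
            L[i, j] = np.cos(row_angles[j]) * sin_prod
            sin_prod *= np.sin(row_angles[j])
        L[i, i] = sin_prod
    return L @ L.T


def _corr_to_angles(R: np.ndarray) -> np.ndarray:
    F = R.shape[0]
    L = np.linalg.cholesky(R)
    angles = []
    for i in range(1, F):
        sin_prod = 1.0
        for j in range(i):
            c = np.clip(L[i, j] / max(sin_prod, 1e-12), -1.0, 1.0)
            phi = np.arccos(c)
            angles.append(phi)
            sin_prod *= np.sin(phi)
    return np.asarray(angles)


# ---------------------------------------------------------------------------
# Quadrature engine.


def _normal_logw(nodes: np.ndarray) -> np.ndarray:
    lw = -0.5 * nodes**2
    return lw - logsumexp(lw)


def _mvn_logw(nodes: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Normalized log-weights of a zero-mean MVN with correlation R on a grid."""
    Rinv = np.linalg.inv(R)
    lw = -0.5 * np.einsum("qi,ij,qj->q", nodes, Rinv, nodes)
    return lw - logsumexp(lw)


class _Engine:
    """Grids, per-item probability tables, and E-step machinery.

    Shared by fitting, marginal likelihood, posterior weights, EAP scoring,
    and limited-information fit statistics.
    """

    def __init__(self, structure: LatentStructure, quad: QuadratureSpec,
                 general_corr: np.ndarray | None = None):
        dim = integral_dimension(structure)
        if dim > MAX_INTEGRAL_DIM:
            raise ValueError(
                f"integral dimension {dim} exceeds the quadrature cap "
                f"({MAX_INTEGRAL_DIM}); this structure is out of scope for EM"
            )
        self.s = structure
        self.quad = quad
        self.gen_idx = structure.general_indices
        self.spec_idx = structure.specific_indices
        self.has_specifics = self.spec_idx.size > 0
        n_gen = self.gen_idx.size

        nodes1d = quad.nodes
        grids = np.meshgrid(*([nodes1d] * n_gen), indexing="ij")
        self.gen_nodes = np.column_stack([g.ravel() for g in grids])  # (G, n_gen)
        self.R = np.eye(n_gen) if general_corr is None else np.asarray(general_corr, float)
        self.gen_logw = _mvn_logw(self.gen_nodes, self.R)
        self.spec_nodes = nodes1d
        self.spec_logw = _normal_logw(nodes1d)
        cluster_of = structure.cluster_of()
        self.clusters = [
            (int(f), np.nonzero(cluster_of == f)[0]) for f in self.spec_idx
        ]
        self._tables: list | None = None
        self.items: list | None = None

    # -- parameter-dependent tables ------------------------------------

    def set_params(self, items: list) -> None:
        self.items = items
        self._Aprod = None
        cluster_of = self.s.cluster_of()
        self._tables = []
        for j, params in enumerate(items):
            a_gen = params.slopes[self.gen_idx]
            z = self.gen_nodes @ a_gen  # (G,)
            if cluster_of[j] >= 0:
                a_s = params.slopes[cluster_of[j]]
                z = z[:, None] + a_s * self.spec_nodes[None, :]  # (G, S)
            cum = expit(z[None, ...] + params.intercepts.reshape(
                (-1,) + (1,) * z.ndim))
            P = np.concatenate([
                np.ones((1,) + z.shape), cum, np.zeros((1,) + z.shape)])
            P = -np.diff(P, axis=0)
            logP = np.log(np.clip(P, 1e-300, None))
            # one extra row of zeros so response code -1 (missing) maps to log 1
            table = np.concatenate([logP, np.zeros((1,) + z.shape)])
            self._tables.append(table)
        # linear-space tables (missing row = 1.0) for fast cluster products
        self._lin_tables = [np.exp(t) for t in self._tables]

    def category_prob_table(self, j: int) -> np.ndarray:
        """exp of the log-probability table of item j (without missing row)."""
        return np.exp(self._tables[j][:-1])

    # -- E-step --------------------------------------------------------

    def pattern_loglik(self, X: np.ndarray):
        """Log-likelihood pieces per response pattern.

        Returns ``(logLi, logLtot, logLc)``: per-pattern marginal
        log-likelihood, per-pattern conditional (on the general grid)
        log-likelihood, and per-cluster conditionals (None without
        specifics).
        """
        npat = X.shape[0]
        G = self.gen_nodes.shape[0]
        self._Aprod = None
        if self.has_specifics:
            # linear-space cluster products: within-cluster products of at
            # most ~10 category probabilities cannot underflow float64
            spec_w = np.exp(self.spec_logw)
            logLc = np.empty((npat, len(self.clusters), G))
            Aprods = []
            for ci, (f, idx) in enumerate(self.clusters):
                A = None
                for j in idx:
                    t = self._lin_tables[j][X[:, j]]  # (npat, G, S)
                    A = t.copy() if A is None else A * t
                Aprods.append(A)
                logLc[:, ci, :] = np.log(np.clip(A @ spec_w, 1e-300, None))
            self._Aprod = Aprods
            logLtot = logLc.sum(axis=1)
        else:
            logLc = None
            logLtot = None
            for j in range(X.shape[1]):
                t = self._tables[j][X[:, j]]  # (npat, G)
                logLtot = t if logLtot is None else logLtot + t
        z = logLtot + self.gen_logw
        m = z.max(axis=-1)
        logLi = m + np.log(np.exp(z - m[:, None]).sum(axis=-1))
        return logLi, logLtot, logLc

    def cluster_posterior(self, X, counts, logLi, logLtot, logLc, ci):
        """Posterior weight over (general, specific) nodes for one cluster,
        scaled by pattern counts; shape ``(npat, G, S)``."""
        f, idx = self.clusters[ci]
        if self._Aprod is not None:
            A = self._Aprod[ci]
        else:
            A = None
            for j in idx:
                t = self._lin_tables[j][X[:, j]]
                A = t.copy() if A is None else A * t
        outer = counts[:, None] * np.exp(
            self.gen_logw + logLtot - logLc[:, ci, :] - logLi[:, None])
        return outer[:, :, None] * (A * np.exp(self.spec_logw)[None, None, :])

    def general_posterior(self, counts, logLi, logLtot) -> np.ndarray:
        """Count-scaled posterior over the general grid; shape ``(npat, G)``."""
        return counts[:, None] * np.exp(self.gen_logw + logLtot - logLi[:, None])

    # -- M-step node geometry ------------------------------------------

    def item_theta_eff(self, j: int) -> np.ndarray:
        """Node coordinates for item ``j``'s free slopes, flattened.

        Columns follow the item's free-factor order: generals ascending,
        then (when present) the item's specific factor.
        """
        free = np.nonzero(self.s.pattern[j])[0]
        cluster = self.s.cluster_of()[j]
        gen_cols = self.gen_nodes[:, [np.where(self.gen_idx == f)[0][0]
                                      for f in free if f in self.gen_idx]]
        if cluster >= 0:
            S = self.spec_nodes.size
            G = self.gen_nodes.shape[0]
            return np.column_stack([
                np.repeat(gen_cols, S, axis=0),
                np.tile(self.spec_nodes, G),
            ])
        return gen_cols


# ---------------------------------------------------------------------------
# Per-item M-step.


def _pack_item(params: ItemParameters, free: np.ndarray) -> np.ndarray:
    a = params.slopes[free]
    d = params.intercepts
    tau = np.empty(d.size)
    tau[0] = d[0]
    if d.size > 1:
        tau[1:] = np.log(-np.diff(d))
    return np.concatenate([a, tau])


def _unpack_item(x: np.ndarray, n_free: int, n_factors: int,
                 free: np.ndarray) -> ItemParameters:
    a_free = x[:n_free]
    tau = x[n_free:]
    d = np.empty(tau.size)
    d[0] = tau[0]
    if tau.size > 1:
        d[1:] = tau[0] - np.cumsum(np.exp(tau[1:]))
    slopes = np.zeros(n_factors)
    slopes[free] = a_free
    return ItemParameters(slopes, d)


def _item_objective(x, n_weights, theta_eff, n_free):
    """Negative expected complete-data log-likelihood and its gradient."""
    a = x[:n_free]
    tau = x[n_free:]
    d = np.empty(tau.size)
    d[0] = tau[0]
    gaps = np.exp(tau[1:]) if tau.size > 1 else np.empty(0)
    if gaps.size:
        d[1:] = tau[0] - np.cumsum(gaps)
    z = theta_eff @ a  # (Q,)
    cum = expit(z[None, :] + d[:, None])  # (K-1, Q)
    Q = z.size
    P = -np.diff(np.vstack([np.ones(Q), cum, np.zeros(Q)]), axis=0)
    P = np.clip(P, 1e-300, None)
    f = -float(np.sum(n_weights * np.log(P)))
    r = n_weights / P  # (K, Q)
    u = cum * (1.0 - cum)
    w = u * (r[1:] - r[:-1])  # (K-1, Q)
    grad_d = -w.sum(axis=1)
    gq = -w.sum(axis=0)
    grad_a = theta_eff.T @ gq
    grad_tau = np.empty_like(tau)
    grad_tau[0] = grad_d.sum()
    if gaps.size:
        rev = np.cumsum(grad_d[::-1])[::-1]
        grad_tau[1:] = -gaps * rev[1:]
    return f, np.concatenate([grad_a, grad_tau])


def _mstep_item(engine: _Engine, j: int, n_weights: np.ndarray,
                params: ItemParameters, inner_maxiter: int = 12) -> ItemParameters:
    free = np.nonzero(engine.s.pattern[j])[0]
    theta_eff = engine.item_theta_eff(j)
    K = params.n_categories
    n_weights = n_weights.reshape(K, -1)
    x0 = _pack_item(params, free)
    if engine.s.positive_loadings:
        slope_bounds = [(0.0, 25.0)] * free.size
    else:
        slope_bounds = [(-25.0, 25.0)] * free.size
    bounds = slope_bounds + [(-30.0, 30.0)] + [(-12.0, 6.0)] * (K - 2)
    f0, _ = _item_objective(x0, n_weights, theta_eff, free.size)
    res = minimize(_item_objective, x0, args=(n_weights, theta_eff, free.size),
                   jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": inner_maxiter, "ftol": 1e-10})
    if res.fun <= f0:  # generalized M-step: never decrease the Q-function
        return _unpack_item(res.x, free.size, engine.s.n_factors, free)
    return params


def _mstep_corr(engine: _Engine, Ng: np.ndarray) -> np.ndarray:
    """Exact constrained M-step for the general-tier correlation matrix."""
    F = engine.gen_idx.size

    def neg_obj(angles):
        R = _angles_to_corr(angles, F)
        if np.linalg.eigvalsh(R).min() < 1e-8:
            return np.inf
        return -float(Ng @ _mvn_logw(engine.gen_nodes, R))

    x0 = _corr_to_angles(engine.R)
    f0 = neg_obj(x0)
    res = minimize(neg_obj, x0, method="Nelder-Mead",
                   options={"maxiter": 200, "xatol": 1e-5, "fatol": 1e-9})
    if res.fun < f0 - 1e-12:
        return _angles_to_corr(res.x, F)
    return engine.R


# ---------------------------------------------------------------------------
# Data preparation.


def _prepare(data: ResponseMatrix, n_categories=None, require_two_categories=True):
    """Drop all-missing persons, compress patterns, infer category counts.

    ``require_two_categories`` is the estimation precondition; likelihood
    evaluation under fixed parameters does not need it.
    """
    values = data.values
    all_missing = (values == MISSING).all(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        logger.info("excluding %d person(s) with complete missing data", n_dropped)
        values = values[~all_missing]
    if values.shape[0] == 0:
        raise ValueError("no persons with at least one observed response")
    if n_categories is None:
        Ks = []
        for j in range(values.shape[1]):
            col = values[:, j]
            obs = np.unique(col[col != MISSING])
            if obs.size < 2 and require_two_categories:
                raise ValueError(
                    f"item {data.item_labels[j]!r} has a single observed category"
                )
            Ks.append(int(obs.max()) + 1 if obs.size else 1)
    else:
        Ks = [int(k) for k in n_categories]
        for j, K in enumerate(Ks):
            col = values[:, j]
            obs = np.unique(col[col != MISSING])
            if obs.size < 2 and require_two_categories:
                raise ValueError(
                    f"item {data.item_labels[j]!r} has a single observed category"
                )
            if obs.max() >= K:
                raise ValueError(
                    f"item {data.item_labels[j]!r}: observed category {obs.max()} "
                    f">= K={K}"
                )
    X, counts = np.unique(values, axis=0, return_counts=True)
    return X, counts.astype(float), Ks, values.shape[0], n_dropped


def _start_values(X, counts, Ks, structure: LatentStructure, seed: int = 0) -> list:
    """Deterministic (given seed) starting values.

    Intercepts come from the observed cumulative category proportions;
    slopes start at 1.0 on permitted general loadings and 0.5 on
    specifics, with a small seeded jitter.  The jitter breaks the
    exchange symmetry between general factors in two-tier structures
    (with exactly symmetric starts the EM map preserves the symmetry and
    converges to a degenerate mode where the generals coincide).
    """
    rng = np.random.default_rng([seed % (2**31), 23])
    items = []
    for j, K in enumerate(Ks):
        col = X[:, j]
        obs = col != MISSING
        w = counts[obs]
        x = col[obs]
        tot = w.sum()
        p_ge = np.array([(w[x >= k]).sum() / tot for k in range(1, K)])
        d = logit(np.clip(p_ge, 1e-3, 1 - 1e-3))
        d = np.clip(d, -4.0, 4.0)
        for k in range(1, d.size):  # enforce strict decrease
            d[k] = min(d[k], d[k - 1] - 0.01)
        slopes = np.zeros(structure.n_factors)
        slopes[structure.general_indices] = np.where(
            structure.pattern[j, structure.general_indices], 1.0, 0.0)
        cl = structure.cluster_of()[j]
        if cl >= 0:
            slopes[cl] = 0.5
        slopes *= structure.pattern[j]
        jitter = rng.uniform(0.7, 1.3, slopes.size)
        items.append(ItemParameters(slopes * jitter, d))
    return items


def count_free_parameters(structure: LatentStructure, Ks) -> int:
    n_slopes = int(structure.pattern.sum())
    n_intercepts = int(sum(K - 1 for K in Ks))
    n_corr = 0
    if structure.oblique_general and structure.n_general > 1:
        g = structure.n_general
        n_corr = g * (g - 1) // 2
    return n_slopes + n_intercepts + n_corr


# ---------------------------------------------------------------------------
# Public fitting interface.


def _pack_all(items: list, s: LatentStructure) -> list:
    return [_pack_item(p, np.nonzero(s.pattern[j])[0])
            for j, p in enumerate(items)]


def _unpack_all(segs: list, s: LatentStructure, Ks: list) -> list:
    out = []
    for j, seg in enumerate(segs):
        free = np.nonzero(s.pattern[j])[0]
        out.append(_unpack_item(seg, free.size, s.n_factors, free))
    return out


def _clip_seg(seg: np.ndarray, n_free: int, positive: bool) -> np.ndarray:
    seg = seg.copy()
    lo = 0.0 if positive else -25.0
    seg[:n_free] = np.clip(seg[:n_free], lo, 25.0)
    seg[n_free] = np.clip(seg[n_free], -30.0, 30.0)
    if seg.size > n_free + 1:
        seg[n_free + 1:] = np.clip(seg[n_free + 1:], -12.0, 6.0)
    return seg


def fit_em(
    data: ResponseMatrix,
    s: LatentStructure,
    quad: QuadratureSpec | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int = 0,
    start: FittedModel | None = None,
    n_categories=None,
    accelerate: bool = True,
) -> FittedModel:
    """Fit a graded-response model by Bock-Aitkin EM.

    ``tol`` is the absolute change in marginal log-likelihood below which
    the fit is declared converged.  ``start`` warm-starts from an earlier
    fit's estimates.  ``seed`` is recorded for manifest reproducibility;
    the algorithm itself is deterministic (fixed starting values, fixed
    grid).  Non-convergence is returned as ``converged=False``, never
    silently.
    """
    if data.n_items != s.n_items:
        raise ValueError(
            f"data has {data.n_items} items but structure expects {s.n_items}")
    X, counts, Ks, n_persons, n_dropped = _prepare(data, n_categories)
    if quad is None:
        quad = default_quadrature(integral_dimension(s))

    if start is not None:
        items = [ItemParameters(p.slopes.copy(), p.intercepts.copy())
                 for p in start.items]
        R = start.general_corr.copy()
    else:
        items = _start_values(X, counts, Ks, s, seed=seed)
        R = np.eye(s.n_general)

    engine = _Engine(s, quad, R)
    history = []
    converged = False
    it = 0
    pending_plain = None  # un-accelerated fallback parameters
    alpha = 2.0  # over-relaxation factor, grown while steps keep succeeding
    for it in range(1, max_iter + 1):
        engine.set_params(items)
        logLi, logLtot, logLc = engine.pattern_loglik(X)
        ll = float(counts @ logLi)
        if pending_plain is not None and history and ll < history[-1] - 1e-10:
            # over-relaxed step overshot; fall back to the plain EM update,
            # which cannot decrease the likelihood
            items = pending_plain
            engine.set_params(items)
            logLi, logLtot, logLc = engine.pattern_loglik(X)
            ll = float(counts @ logLi)
            alpha = 2.0
        elif pending_plain is not None:
            alpha = min(alpha * 1.4, 10.0)
        pending_plain = None
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
        # M-step
        new_items = list(items)
        if engine.has_specifics:
            for ci, (f, idx) in enumerate(engine.clusters):
                post = engine.cluster_posterior(X, counts, logLi, logLtot, logLc, ci)
                for j in idx:
                    K = Ks[j]
                    nw = np.zeros((K,) + post.shape[1:])
                    col = X[:, j]
                    for k in range(K):
                        sel = col == k
                        if sel.any():
                            nw[k] = post[sel].sum(axis=0)
                    new_items[j] = _mstep_item(engine, j, nw, items[j])
        else:
            post = engine.general_posterior(counts, logLi, logLtot)  # (npat, G)
            for j in range(len(items)):
                K = Ks[j]
                nw = np.zeros((K, post.shape[1]))
                col = X[:, j]
                for k in range(K):
                    sel = col == k
                    if sel.any():
                        nw[k] = post[sel].sum(axis=0)
                new_items[j] = _mstep_item(engine, j, nw, items[j])
        if accelerate and it >= 3:
            # safeguarded over-relaxation: double the EM step in the
            # (slope, ordered-intercept) parameterization; the next E-step
            # falls back to the plain update if the likelihood drops
            segs0 = _pack_all(items, s)
            segs1 = _pack_all(new_items, s)
            cand = [
                _clip_seg(a + alpha * (b - a), int(s.pattern[j].sum()),
                          s.positive_loadings)
                for j, (a, b) in enumerate(zip(segs0, segs1))
            ]
            pending_plain = new_items
            items = _unpack_all(cand, s, Ks)
        else:
            items = new_items
        if s.oblique_general and s.n_general > 1:
            Ng = engine.general_posterior(counts, logLi, logLtot).sum(axis=0)
            R_new = _mstep_corr(engine, Ng)
            engine.R = R_new
            engine.gen_logw = _mvn_logw(engine.gen_nodes, R_new)
            R = R_new

    if not converged:  # evaluate the log-likelihood of the final parameters
        engine.set_params(items)
        logLi, _, _ = engine.pattern_loglik(X)
        history.append(float(counts @ logLi))
        logger.warning("EM did not converge in %d iterations (last delta %.3g)",
                       max_iter, history[-1] - history[-2])

    history_arr = np.asarray(history)
    notes = []
    if n_dropped:
        notes.append(f"excluded {n_dropped} all-missing person(s)")
    decreases = np.diff(history_arr)
    if decreases.size and decreases.min() < -1e-8:
        notes.append(f"log-likelihood decreased by {-decreases.min():.3g}")
    if s.positive_loadings:
        n_bound = sum(int(np.sum((p.slopes == 0.0) & s.pattern[j]))
                      for j, p in enumerate(items))
        if n_bound:
            notes.append(f"{n_bound} slope(s) at the positive-loadings bound, reported as 0")

    return FittedModel(
        structure=s,
        items=items,
        general_corr=R,
        loglik=history_arr[-1],
        n_params=count_free_parameters(s, Ks),
        n_persons=n_persons,
        converged=converged,
        iterations=it,
        quadrature=quad,
        item_labels=data.item_labels,
        loglik_history=history_arr,
        notes=notes,
    )


def fit_null(data: ResponseMatrix, s: LatentStructure,
             quad: QuadratureSpec | None = None,
             n_categories=None) -> FittedModel:
    """Independence baseline: same structure, all slopes fixed at zero.

    With zero slopes the marginal likelihood factorizes over items, so the
    intercept MLEs are the logits of the observed cumulative category
    proportions (closed form; no EM needed).
    """
    X, counts, Ks, n_persons, _ = _prepare(data, n_categories)
    items = []
    ll = 0.0
    for j, K in enumerate(Ks):
        col = X[:, j]
        obs = col != MISSING
        w = counts[obs]
        x = col[obs]
        tot = w.sum()
        p_cat = np.array([(w[x == k]).sum() / tot for k in range(K)])
        p_cat = np.clip(p_cat, 1e-10, None)
        p_cat /= p_cat.sum()
        p_ge = np.cumsum(p_cat[::-1])[::-1][1:]  # P(x >= k), k = 1..K-1
        d = logit(np.clip(p_ge, 1e-10, 1 - 1e-10))
        for k in range(1, d.size):
            d[k] = min(d[k], d[k - 1] - 1e-9)
        items.append(ItemParameters(np.zeros(s.n_factors), d))
        nk = np.array([(w[x == k]).sum() for k in range(K)])
        ll += float(nk @ np.log(p_cat))
    if quad is None:
        quad = default_quadrature(integral_dimension(s))
    return FittedModel(
        structure=s, items=items, general_corr=np.eye(s.n_general),
        loglik=ll, n_params=int(sum(K - 1 for K in Ks)), n_persons=n_persons,
        converged=True, iterations=0, quadrature=quad,
        item_labels=data.item_labels, loglik_history=np.array([ll]),
        notes=["independence null model (slopes fixed at 0)"],
        slopes_fixed=True,
    )


def fit_2pl(data: ResponseMatrix, quad: QuadratureSpec | None = None,
            max_iter: int = 500, tol: float = 1e-4):
    """Dedicated two-parameter logistic path for dichotomous data.

    An intentionally separate Bernoulli formulation, ``P(x=1) =
    expit(a*theta + d)``, used to verify that the graded model with K=2
    reproduces the 2PL exactly.  Returns ``(items, loglik, history)``.
    """
    X, counts, Ks, n_persons, _ = _prepare(data)
    if any(K != 2 for K in Ks):
        raise ValueError("fit_2pl requires dichotomous (K=2) items")
    if quad is None:
        quad = default_quadrature(1)
    nodes = quad.nodes
    logw = _normal_logw(nodes)
    J = X.shape[1]
    a = np.ones(J)
    d = np.zeros(J)
    for j in range(J):
        col = X[:, j]
        obs = col != MISSING
        p1 = counts[obs][col[obs] == 1].sum() / counts[obs].sum()
        d[j] = float(logit(np.clip(p1, 1e-3, 1 - 1e-3)))

    history = []
    converged = False
    for _ in range(max_iter):
        # E-step: Bernoulli log-likelihood per pattern per node
        logp1 = np.log(expit(a[:, None] * nodes[None, :] + d[:, None]))
        logp0 = np.log(expit(-(a[:, None] * nodes[None, :] + d[:, None])))
        logL = np.zeros((X.shape[0], nodes.size))
        for j in range(J):
            col = X[:, j]
            logL[col == 1] += logp1[j]
            logL[col == 0] += logp0[j]
        logLi = logsumexp(logL + logw, axis=1)
        ll = float(counts @ logLi)
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
        post = counts[:, None] * np.exp(logw + logL - logLi[:, None])  # (npat, Q)
        for j in range(J):
            col = X[:, j]
            r1 = post[col == 1].sum(axis=0)
            r0 = post[col == 0].sum(axis=0)

            def obj(x, r1=r1, r0=r0):
                aj, dj = x
                z = aj * nodes + dj
                p1 = expit(z)
                f = -float(r1 @ np.log(np.clip(p1, 1e-300, None))
                           + r0 @ np.log(np.clip(1 - p1, 1e-300, None)))
                gz = -(r1 * (1 - p1) - r0 * p1)
                return f, np.array([gz @ nodes, gz.sum()])

            res = minimize(obj, np.array([a[j], d[j]]), jac=True,
                           method="L-BFGS-B", options={"maxiter": 30})
            a[j], d[j] = res.x
    items = [ItemParameters(np.array([a[j]]), np.array([d[j]])) for j in range(J)]
    return items, history[-1], np.asarray(history), converged


# ---------------------------------------------------------------------------
# Marginal likelihood and posterior weights for fixed parameters.


def _engine_for(model: FittedModel) -> _Engine:
    engine = _Engine(model.structure, model.quadrature, model.general_corr)
    engine.set_params(model.items)
    return engine


def marginal_loglik(data: ResponseMatrix, model: FittedModel,
                    per_person: bool = False):
    """Marginal log-likelihood of ``data`` under a fitted model's parameters.

    Uses the model's quadrature, with two-tier dimension reduction when the
    structure has specific factors.  Decomposes as a sum over persons.
    """
    if data.n_items != model.n_items:
        raise ValueError(
            f"data has {data.n_items} items but model expects {model.n_items}")
    X, counts, Ks, _, _ = _prepare(data, n_categories=None,
                                   require_two_categories=False)
    for j, (K_data, params) in enumerate(zip(Ks, model.items)):
        if K_data > params.n_categories:
            raise ValueError(
                f"item {data.item_labels[j]!r}: observed category beyond model K")
    engine = _engine_for(model)
    logLi, _, _ = engine.pattern_loglik(X)
    if per_person:
        # map back onto the retained-person order
        values = data.values[~(data.values == MISSING).all(axis=1)]
        _, inverse = np.unique(values, axis=0, return_inverse=True)
        return logLi[inverse]
    return float(counts @ logLi)


def model_to_config(model: FittedModel) -> dict:
    """Serialize a fitted model to a plain dict (YAML/JSON friendly)."""
    from .structures import structure_to_config

    return {
        "structure": structure_to_config(model.structure),
        "items": [
            {"label": model.item_labels[j] if model.item_labels else f"item{j + 1}",
             "slopes": [float(a) for a in p.slopes],
             "intercepts": [float(d) for d in p.intercepts]}
            for j, p in enumerate(model.items)
        ],
        "general_corr": [[float(v) for v in row] for row in model.general_corr],
        "loglik": float(model.loglik),
        "n_params": int(model.n_params),
        "n_persons": int(model.n_persons),
        "converged": bool(model.converged),
        "iterations": int(model.iterations),
        "quadrature": {"nodes_per_dim": model.quadrature.nodes_per_dim,
                       "bound": model.quadrature.bound},
        "notes": list(model.notes),
        "slopes_fixed": bool(model.slopes_fixed),
    }


def model_from_config(cfg: dict) -> FittedModel:
    from .structures import structure_from_config

    structure = structure_from_config(cfg["structure"])
    items = [ItemParameters(np.asarray(it["slopes"]), np.asarray(it["intercepts"]))
             for it in cfg["items"]]
    return FittedModel(
        structure=structure, items=items,
        general_corr=np.asarray(cfg["general_corr"], dtype=float),
        loglik=float(cfg["loglik"]), n_params=int(cfg["n_params"]),
        n_persons=int(cfg["n_persons"]), converged=bool(cfg["converged"]),
        iterations=int(cfg["iterations"]),
        quadrature=QuadratureSpec(**cfg["quadrature"]),
        item_labels=tuple(it["label"] for it in cfg["items"]),
        notes=list(cfg.get("notes", [])),
        slopes_fixed=bool(cfg.get("slopes_fixed", False)),
    )


@dataclass
class PosteriorWeights:
    """Per-person posterior weights over the quadrature grid.

    ``general`` has one row per retained person over the general-factor
    grid (all factors, for structures without specifics); rows are
    non-negative and sum to one.  ``cluster[f]`` holds the joint posterior
    over (general grid x specific grid) for the specific factor ``f``.
    """

    general: np.ndarray
    gen_nodes: np.ndarray
    cluster: dict
    spec_nodes: np.ndarray
    person_ids: tuple


def posterior_weights(data: ResponseMatrix, model: FittedModel) -> PosteriorWeights:
    if data.n_items != model.n_items:
        raise ValueError("item count mismatch between data and model")
    values = data.values
    keep = ~(values == MISSING).all(axis=1)
    values = values[keep]
    X, inverse = np.unique(values, axis=0, return_inverse=True)
    engine = _engine_for(model)
    logLi, logLtot, logLc = engine.pattern_loglik(X)
    post_g = np.exp(engine.gen_logw + logLtot - logLi[:, None])
    cluster = {}
    if engine.has_specifics:
        ones = np.ones(X.shape[0])
        for ci, (f, idx) in enumerate(engine.clusters):
            cp = engine.cluster_posterior(X, ones, logLi, logLtot, logLc, ci)
            cluster[f] = cp[inverse]
    ids = tuple(np.asarray(data.person_ids, dtype=object)[keep])
    return PosteriorWeights(post_g[inverse], engine.gen_nodes, cluster,
                            engine.spec_nodes, ids)
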