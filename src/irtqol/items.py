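"""Graded response model (GRM) primitives.

The logistic graded response model describes the probability of an ordinal
item response ``x`` in categories ``0..K-1`` given a latent trait vector
``theta`` through cumulative ("step") probabilities

    P*(x >= k | theta) = 1 / (1 + exp(-(a . theta + d_k))),   k = 1..K-1,

with a slope (discrimination) vector ``a`` over all model factors and
strictly decreasing intercepts ``d_1 > d_2 > ... > d_{K-1}``.  Category
probabilities are differences of adjacent cumulative probabilities, with
``P*(x >= 0) = 1`` and ``P*(x >= K) = 0``.  With ``K = 2`` the model is the
two-parameter logistic (2PL) model for dichotomous items.

Conventions
-----------
* Slope-intercept parameterization.  For unidimensional reporting the
  difficulty form is ``b_k = -d_k / a``.
* No logistic scaling constant is applied (D = 1.7 appears only in the
  standardized-loading conversion in :mod:`irtqol.scoring`); the likelihood
  is purely logistic.
* Category codes are 0-based integers ``0..K-1``; missing responses are the
  sentinel :data:`MISSING` (-1), distinct from any category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: Sentinel for a missing response (never a valid category code).
MISSING: int = -1

__all__ = [
    "MISSING",
    "ItemSpec",
    "ItemParameters",
    "cumulative_probabilities",
    "category_probabilities",
    "person_loglik",
    "expected_item_score",
    "item_information",
]


@dataclass(frozen=True)
class ItemSpec:
    """Schema for one ordinal item.

    Parameters
    ----------
    label : str
        Item label (column name in response CSVs).
    n_categories : int
        Number of ordered response categories ``K >= 2``.
    subscale : str
        Subscale / cluster tag (e.g. ``"PF"`` for SF-36 physical functioning).
    loading_pattern : frozenset[int]
        Indices of the model factors the item may load on; non-empty.
    """

    label: str
    n_categories: int
    subscale: str = ""
    loading_pattern: frozenset = field(default_factory=lambda: frozenset({0}))

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.label!r}: n_categories must be >= 2")
        if not self.loading_pattern:
            raise ValueError(f"item {self.label!r}: loading_pattern must be non-empty")


@dataclass(frozen=True)
class ItemParameters:
    """Slope vector and ordered intercepts of one graded-response item.

    ``slopes`` has one entry per model factor (zero where the loading
    pattern forbids a loading); ``intercepts`` has length ``K - 1`` and is
    strictly decreasing, which guarantees non-negative category
    probabilities.
    """

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes", np.atleast_1d(np.asarray(self.slopes, dtype=float)))
        object.__setattr__(
            self, "intercepts", np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        )
        if self.intercepts.size < 1:
            raise ValueError("at least one intercept required (K >= 2)")
        if np.any(np.diff(self.intercepts) >= 0):
            raise ValueError(f"intercepts must be strictly decreasing, got {self.intercepts}")

    @property
    def n_categories(self) -> int:
        return self.intercepts.size + 1

    @property
    def n_factors(self) -> int:
        return self.slopes.size

    def difficulties(self) -> np.ndarray:
        """Difficulty parameters ``b_k = -d_k / a`` (unidimensional reporting).

        Only meaningful when a single slope is non-zero.
        """
        a = self.slopes[np.nonzero(self.slopes)[0]]
        if a.size != 1:
            raise ValueError("difficulty conversion requires exactly one non-zero slope")
        return -self.intercepts / a[0]


def _linear_predictor(params: ItemParameters, theta: np.ndarray) -> float | np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != params.slopes.size:
        raise ValueError(
            f"theta has {theta.shape[-1]} coordinates but item has "
            f"{params.slopes.size} slopes"
        )
    return theta @ params.slopes


def cumulative_probabilities(params: ItemParameters, theta) -> np.ndarray:
    """``P*(x >= k | theta)`` for ``k = 1..K-1``.

    Values are strictly within (0, 1) and non-increasing in ``k``.
    """
    z = _linear_predictor(params, theta)
    return expit(z + params.intercepts)


def category_probabilities(params: ItemParameters, theta) -> np.ndarray:
    """Probabilities of each of the K categories at ``theta``; sums to 1."""
    cum = cumulative_probabilities(params, theta)
    full = np.concatenate(([1.0], cum, [0.0]))
    return -np.diff(full)


def person_loglik(items, responses, theta) -> float:
    """Conditional log-likelihood of one response vector given ``theta``.

    Missing responses (:data:`MISSING`) are skipped.  Raises if every
    response is missing or a code is outside ``0..K-1``.
    """
    responses = np.asarray(responses)
    if len(items) != responses.size:
        raise ValueError("responses length must equal number of items")
    total = 0.0
    n_obs = 0
    for params, x in zip(items, responses):
        if x == MISSING:
            continue
        k = int(x)
        if k < 0 or k >= params.n_categories:
            raise ValueError(f"response code {k} outside 0..{params.n_categories - 1}")
        total += float(np.log(category_probabilities(params, theta)[k]))
        n_obs += 1
    if n_obs == 0:
        raise ValueError("all responses missing; person carries no information")
    return total


def expected_item_score(params: ItemParameters, theta) -> float:
    """Expected category index ``sum_k k P(x = k | theta)``, in ``[0, K-1]``."""
    p = category_probabilities(params, theta)
    return float(np.arange(params.n_categories) @ p)


# ---------------------------------------------------------------------------
# Vectorized grid evaluations (used by estimation, fit statistics, scoring).


def cumulative_probabilities_grid(params: ItemParameters, theta_grid: np.ndarray) -> np.ndarray:
    """Cumulative probabilities at many theta points; shape ``(K-1, Q)``."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    z = theta_grid @ params.slopes  # (Q,)
    return expit(z[None, :] + params.intercepts[:, None])


def category_probabilities_grid(params: ItemParameters, theta_grid: np.ndarray) -> np.ndarray:
    """Category probabilities at many theta points; shape ``(K, Q)``."""
    cum = cumulative_probabilities_grid(params, theta_grid)
    Q = cum.shape[1]
    full = np.vstack([np.ones(Q), cum, np.zeros(Q)])
    return -np.diff(full, axis=0)


def item_information(params: ItemParameters, theta_grid: np.ndarray) -> np.ndarray:
    """Fisher information of a unidimensional graded item along a theta grid.

    ``I_j(theta) = a^2 * sum_k (u_k - u_{k+1})^2 / P_k`` with
    ``u_k = P*_k (1 - P*_k)`` (``u_0 = u_K = 0``).  Requires exactly one
    non-zero slope.
    """
    nz = np.nonzero(params.slopes)[0]
    if nz.size != 1:
        raise ValueError("item_information requires exactly one non-zero slope")
    a = params.slopes[nz[0]]
    cum = cumulative_probabilities_grid(params, theta_grid)
    Q = cum.shape[1]
    u = np.vstack([np.zeros(Q), cum * (1.0 - cum), np.zeros(Q)])
    p = category_probabilities_grid(params, theta_grid)
    num = -np.diff(u, axis=0)  # u_k - u_{k+1} per category k
    return a**2 * np.sum(num**2 / np.clip(p, 1e-300, None), axis=0)
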