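"""Synthetic response-matrix generation emulating SF-36, EQ-5D, and HADS.

The generator draws latent traits from the structure's multivariate normal
prior, draws ordinal responses from graded-response category probabilities
at each person's trait vector, and blanks cells completely at random
(MCAR) at the instrument's missingness rate.  The shipped presets emulate
the response structure of a large chronic-pain rehabilitation registry:

* ``sf36`` — 36 items with 2/3/5/6 ordered categories under a two-tier
  structure (2 orthogonal general factors for physical and mental health,
  8 specific subscale factors), 15.9% partial missingness.
* ``eq5d`` — 5 items with 3 categories under a unidimensional structure,
  2.1% missingness (higher trait = worse health-related quality of life).
* ``hads`` — 14 items with 4 categories under a bifactor structure (1
  general emotional-distress factor + anxiety and depression specifics),
  5.4% missingness.
* ``sf36_reduced`` — a 12-item, 4-cluster scale-model of the SF-36 design
  for quick studies.

Preset item parameters are reconstructions with the qualitative features
the emulated instruments show (general factors clearly stronger than
specifics, spread category thresholds, instrument-matched category
counts); they are drawn once from fixed ranges with a fixed internal seed
and are identical on every call.  Default ``n_persons`` matches the
registry scale (35,908); studies at smaller N simply override it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import ResponseMatrix
from .items import MISSING, ItemParameters
from .structures import (SF36_PHYSICAL, SF36_SUBSCALES, LatentStructure,
                         build_structure, candidate_models)

__all__ = [
    "SimulationSpec",
    "simulate_thetas",
    "simulate_responses",
    "inject_missing",
    "simulate",
    "preset",
    "describe_responses",
    "spec_to_config",
    "spec_from_config",
]

#: Registry-scale default sample size emulated by the presets.
REGISTRY_N = 35908

_PRESET_MISSING = {"sf36": 0.159, "eq5d": 0.021, "hads": 0.054,
                   "sf36_reduced": 0.159}


@dataclass
class SimulationSpec:
    """Everything needed to simulate one instrument's response matrix."""

    structure: LatentStructure
    items: list
    n_persons: int
    missing_rate: float = 0.0
    general_corr: np.ndarray | None = None
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.general_corr is None:
            self.general_corr = np.eye(self.structure.n_general)
        for j, p in enumerate(self.items):
            if p.n_factors != self.structure.n_factors:
                raise ValueError(f"item {j}: slope length != n_factors")
            off = ~self.structure.pattern[j] & (p.slopes != 0)
            if off.any():
                raise ValueError(f"item {j}: non-zero slope outside loading pattern")

    @property
    def item_labels(self) -> tuple:
        return self.structure.item_labels


def simulate_thetas(spec: SimulationSpec) -> np.ndarray:
    """Draw persons x factors latent traits from the structure's prior.

    Generals follow MVN(0, R); specifics are independent standard normal
    (and independent of the generals).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    F = spec.structure.n_factors
    theta = np.empty((spec.n_persons, F))
    gi = spec.structure.general_indices
    si = spec.structure.specific_indices
    if gi.size:
        R = np.asarray(spec.general_corr, dtype=float)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as err:
            raise ValueError("general correlation matrix not positive definite") from err
        theta[:, gi] = rng.standard_normal((spec.n_persons, gi.size)) @ L.T
    if si.size:
        theta[:, si] = rng.standard_normal((spec.n_persons, si.size))
    return theta


def simulate_responses(thetas: np.ndarray, spec: SimulationSpec) -> ResponseMatrix:
    """Draw each response from the graded model at the person's theta."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape[1] != spec.structure.n_factors:
        raise ValueError("thetas do not match the structure's factor count")
    rng = np.random.default_rng([spec.seed % (2**31), 13])
    n = thetas.shape[0]
    J = len(spec.items)
    u = rng.random((n, J))
    out = np.empty((n, J), dtype=np.int64)
    for j, params in enumerate(spec.items):
        z = thetas @ params.slopes
        cum = expit(z[:, None] + params.intercepts[None, :])  # (n, K-1)
        out[:, j] = (u[:, j, None] < cum).sum(axis=1)
    return ResponseMatrix(out, spec.item_labels)


def inject_missing(data: ResponseMatrix, rate: float, seed: int = 0) -> ResponseMatrix:
    """Blank each cell independently with probability ``rate`` (MCAR).

    Persons left all-missing are retained; exclusion is a fit-time policy.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return ResponseMatrix(data.values.copy(), data.item_labels, data.person_ids)
    rng = np.random.default_rng([seed % (2**31), 17])
    mask = rng.random(data.values.shape) < rate
    values = np.where(mask, MISSING, data.values)
    return ResponseMatrix(values, data.item_labels, data.person_ids)


def simulate(spec: SimulationSpec) -> ResponseMatrix:
    """Full chain: thetas -> responses -> MCAR missingness."""
    thetas = simulate_thetas(spec)
    data = simulate_responses(thetas, spec)
    return inject_missing(data, spec.missing_rate, spec.seed)


# ---------------------------------------------------------------------------
# Instrument presets.

# Internal seed fixing the preset parameter draw; independent of user seeds.
_PARAM_SEED = 202319


def _draw_intercepts(rng, K: int, center: float = 0.0,
                     spread: float = 2.2) -> np.ndarray:
    """K-1 strictly decreasing intercepts around ``center``."""
    raw = np.sort(rng.uniform(-spread, spread, K - 1))[::-1]
    gaps = np.clip(np.abs(np.diff(raw)), 0.4, None)
    d = np.empty(K - 1)
    d[0] = raw[0]
    for i, g in enumerate(gaps):
        d[i + 1] = d[i] - g
    return d + center


def _sf36_category_counts() -> list:
    K = {}
    for i in (1, 2, 20, 22, 32, 33, 34, 35, 36):
        K[i] = 5
    for i in range(3, 13):
        K[i] = 3
    for i in list(range(13, 20)):
        K[i] = 2
    K[21] = 6
    for i in list(range(23, 32)):
        K[i] = 6
    return [K[i] for i in range(1, 37)]


def _preset_sf36(rng) -> SimulationSpec:
    sub = [None] * 36
    for name, nums in SF36_SUBSCALES.items():
        for i in nums:
            sub[i - 1] = name
    labels = [f"sf{i}" for i in range(1, 37)]
    structure = build_structure("two_tier", 36, sub, n_general=2,
                                item_labels=labels)
    Ks = _sf36_category_counts()
    cluster_of = structure.cluster_of()
    items = []
    for j in range(36):
        own_physical = sub[j] in SF36_PHYSICAL
        slopes = np.zeros(structure.n_factors)
        primary = rng.uniform(1.1, 1.9)
        cross = rng.uniform(0.15, 0.5)
        slopes[0] = primary if own_physical else cross
        slopes[1] = cross if own_physical else primary
        slopes[cluster_of[j]] = rng.uniform(0.5, 1.0)
        items.append(ItemParameters(slopes, _draw_intercepts(rng, Ks[j])))
    return SimulationSpec(structure, items, REGISTRY_N,
                          _PRESET_MISSING["sf36"], name="sf36")


def _preset_sf36_reduced(rng) -> SimulationSpec:
    # Three items from each of four polytomous subscales (PF, GH, VT, MH).
    # The dichotomous role-limitation clusters are deliberately not sampled:
    # three binary indicators cannot pin down a specific factor at the
    # sample sizes this scale model is meant for.
    clusters = ["PF"] * 3 + ["GH"] * 3 + ["VT"] * 3 + ["MH"] * 3
    labels = [f"sfr{i + 1}" for i in range(12)]
    structure = build_structure("two_tier", 12, clusters, n_general=2,
                                item_labels=labels)
    cluster_of = structure.cluster_of()
    Ks = [3, 3, 3, 5, 5, 5, 6, 6, 6, 5, 5, 5]
    items = []
    for j in range(12):
        own_physical = j < 6
        slopes = np.zeros(structure.n_factors)
        primary = rng.uniform(1.2, 1.8)
        cross = rng.uniform(0.2, 0.45)
        slopes[0] = primary if own_physical else cross
        slopes[1] = cross if own_physical else primary
        slopes[cluster_of[j]] = rng.uniform(0.5, 0.9)
        items.append(ItemParameters(slopes, _draw_intercepts(rng, Ks[j])))
    return SimulationSpec(structure, items, REGISTRY_N,
                          _PRESET_MISSING["sf36_reduced"], name="sf36_reduced")


def _preset_eq5d(rng) -> SimulationSpec:
    labels = [f"eq{i}" for i in range(1, 6)]
    structure = build_structure("unidimensional", 5, item_labels=labels)
    # higher theta = worse HRQoL; chronic-pain margins are heavily shifted
    # toward "some problems", most extremely for the pain dimension.
    slopes = [1.3, 1.7, 1.2, 0.9, 0.7]
    centers = [0.3, -0.3, 0.8, 2.2, 0.5]
    items = [ItemParameters(np.array([a]), _draw_intercepts(rng, 3, center=c))
             for a, c in zip(slopes, centers)]
    return SimulationSpec(structure, items, REGISTRY_N,
                          _PRESET_MISSING["eq5d"], name="eq5d")


def _preset_hads(rng) -> SimulationSpec:
    labels = [f"hads{i}" for i in range(1, 15)]
    structure = candidate_models("hads")["bifactor_2_specifics"]
    structure = LatentStructure(structure.kind, structure.pattern,
                                structure.tier, structure.oblique_general,
                                structure.positive_loadings,
                                structure.factor_names, tuple(labels))
    cluster_of = structure.cluster_of()
    items = []
    for j in range(14):
        is_anx = cluster_of[j] == 1  # anxiety cluster = first specific factor
        slopes = np.zeros(structure.n_factors)
        slopes[0] = rng.uniform(1.5, 2.1) if is_anx else rng.uniform(1.2, 1.8)
        slopes[cluster_of[j]] = rng.uniform(0.55, 0.95)
        items.append(ItemParameters(slopes, _draw_intercepts(rng, 4)))
    return SimulationSpec(structure, items, REGISTRY_N,
                          _PRESET_MISSING["hads"], name="hads")


def preset(name: str, n_persons: int | None = None, seed: int = 0) -> SimulationSpec:
    """A complete, documented :class:`SimulationSpec` for one instrument."""
    rng = np.random.default_rng(_PARAM_SEED)
    builders = {"sf36": _preset_sf36, "eq5d": _preset_eq5d,
                "hads": _preset_hads, "sf36_reduced": _preset_sf36_reduced}
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(builders)}")
    spec = builders[name](rng)
    if n_persons is not None:
        spec.n_persons = int(n_persons)
    spec.seed = int(seed)
    return spec


def spec_to_config(spec: SimulationSpec) -> dict:
    """Serialize a simulation spec to the structure-config dict format."""
    from .structures import structure_to_config

    return {
        "name": spec.name,
        "structure": structure_to_config(spec.structure),
        "items": [
            {"label": spec.item_labels[j],
             "slopes": [float(a) for a in p.slopes],
             "intercepts": [float(d) for d in p.intercepts]}
            for j, p in enumerate(spec.items)
        ],
        "n_persons": int(spec.n_persons),
        "missing_rate": float(spec.missing_rate),
        "general_corr": [[float(v) for v in row] for row in spec.general_corr],
        "seed": int(spec.seed),
    }


def spec_from_config(cfg: dict) -> SimulationSpec:
    from .structures import structure_from_config

    return SimulationSpec(
        structure=structure_from_config(cfg["structure"]),
        items=[ItemParameters(np.asarray(it["slopes"]),
                              np.asarray(it["intercepts"]))
               for it in cfg["items"]],
        n_persons=int(cfg["n_persons"]),
        missing_rate=float(cfg.get("missing_rate", 0.0)),
        general_corr=np.asarray(cfg["general_corr"], dtype=float),
        seed=int(cfg.get("seed", 0)),
        name=cfg.get("name", "custom"),
    )


# ---------------------------------------------------------------------------
# Screening description.


def describe_responses(data: ResponseMatrix):
    """Category counts per item and floor/ceiling rates of total scores.

    Returns ``(counts, summary)``: a DataFrame of per-item category counts
    (plus missing counts) and a dict with the complete-case floor and
    ceiling proportions (the fraction of persons at the minimum / maximum
    possible total score — values above ~0.1% flag floor/ceiling effects).
    """
    if data.n_persons == 0:
        raise ValueError("empty response matrix")
    values = data.values
    K_obs = [int(values[:, j].max()) + 1 if (values[:, j] != MISSING).any() else 0
             for j in range(data.n_items)]
    K_max = max(K_obs)
    rows = []
    for j in range(data.n_items):
        col = values[:, j]
        row = {"item": data.item_labels[j]}
        for k in range(K_max):
            row[f"cat{k}"] = int(np.sum(col == k))
        row["missing"] = int(np.sum(col == MISSING))
        rows.append(row)
    counts = pd.DataFrame(rows).set_index("item")
    complete = values[~(values == MISSING).any(axis=1)]
    if complete.shape[0]:
        totals = complete.sum(axis=1)
        max_total = sum(k - 1 for k in K_obs)
        floor = float(np.mean(totals == 0))
        ceiling = float(np.mean(totals == max_total))
    else:
        floor = ceiling = np.nan
    summary = {"n_complete": int(complete.shape[0]), "floor": floor,
               "ceiling": ceiling,
               "min_category_count": int(min(
                   counts[f"cat{k}"][counts[f"cat{k}"] > 0].min()
                   if (counts[f"cat{k}"] > 0).any() else 0
                   for k in range(K_max)))}
    return counts, summary
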