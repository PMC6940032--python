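"""Declarative latent-structure specifications.

Four families of confirmatory structures are supported:

* ``unidimensional`` — all items load on one factor.
* ``correlated_traits`` — item subsets load on separate, mutually correlated
  group factors (between-item multidimensionality).
* ``bifactor`` — every item loads on one general factor plus exactly one
  orthogonal specific (cluster) factor (within-item multidimensionality).
* ``two_tier`` — a bifactor structure with several general factors
  (orthogonal or oblique) plus orthogonal specifics.

A second-order model is a constrained two-tier model and is not a separate
code path.  Factors are ordered generals first, then specifics.  The scale
of every factor is fixed by the standard-normal prior (mean 0, variance 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LatentStructure",
    "build_structure",
    "validate_structure",
    "integral_dimension",
    "candidate_models",
    "structure_to_config",
    "structure_from_config",
]

KINDS = ("unidimensional", "correlated_traits", "bifactor", "two_tier")


@dataclass(frozen=True)
class LatentStructure:
    """Item-factor incidence pattern plus tier labels and constraint flags.

    ``pattern[j, f]`` is True when item ``j`` may load on factor ``f``.
    ``tier[f]`` is ``"general"`` or ``"specific"``; specific factors are
    orthogonal to everything, general factors may be correlated when
    ``oblique_general`` is set.  ``positive_loadings`` bounds all free
    slopes at zero during estimation.
    """

    kind: str
    pattern: np.ndarray
    tier: tuple
    oblique_general: bool = False
    positive_loadings: bool = False
    factor_names: tuple = ()
    item_labels: tuple = ()

    def __post_init__(self) -> None:
        pattern = np.asarray(self.pattern, dtype=bool)
        object.__setattr__(self, "pattern", pattern)
        if not self.factor_names:
            names = tuple(
                f"{'G' if t == 'general' else 'S'}{i}" for i, t in enumerate(self.tier)
            )
            object.__setattr__(self, "factor_names", names)
        if not self.item_labels:
            object.__setattr__(
                self, "item_labels", tuple(f"item{j + 1}" for j in range(pattern.shape[0]))
            )

    @property
    def n_items(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    @property
    def general_indices(self) -> np.ndarray:
        return np.array([f for f, t in enumerate(self.tier) if t == "general"], dtype=int)

    @property
    def specific_indices(self) -> np.ndarray:
        return np.array([f for f, t in enumerate(self.tier) if t == "specific"], dtype=int)

    @property
    def n_general(self) -> int:
        return self.general_indices.size

    def cluster_of(self) -> np.ndarray:
        """Specific-factor index per item (-1 when the item has none)."""
        out = np.full(self.n_items, -1, dtype=int)
        for f in self.specific_indices:
            members = np.nonzero(self.pattern[:, f])[0]
            out[members] = f
        return out


def _normalize_clusters(clusters, n_items: int) -> dict:
    """Accept {name: [item indices]} or a per-item label sequence."""
    if clusters is None:
        return {}
    if isinstance(clusters, dict):
        return {str(k): list(v) for k, v in clusters.items()}
    labels = list(clusters)
    if len(labels) != n_items:
        raise ValueError(
            f"per-item cluster labels have length {len(labels)}, expected {n_items}"
        )
    out: dict = {}
    for j, lab in enumerate(labels):
        out.setdefault(str(lab), []).append(j)
    return out


def build_structure(
    kind: str,
    n_items: int,
    clusters=None,
    n_general: int = 1,
    oblique_general: bool = False,
    positive_loadings: bool = False,
    item_labels=None,
) -> LatentStructure:
    """Construct a valid :class:`LatentStructure` of the requested family.

    ``clusters`` maps items to specific-factor clusters (bifactor, two-tier)
    or to group factors (correlated-traits); it is required for every kind
    except ``unidimensional``.  ``n_general >= 2`` is only meaningful for
    ``two_tier``; bifactor implies one general factor.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown structure kind {kind!r}; expected one of {KINDS}")
    if n_general < 1:
        raise ValueError("n_general must be >= 1")
    cl = _normalize_clusters(clusters, n_items)
    if kind != "unidimensional":
        if not cl:
            raise ValueError(f"clusters are required for kind={kind!r}")
        seen: set = set()
        for name, members in cl.items():
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"cluster {name!r} overlaps another cluster at items {sorted(overlap)}")
            seen.update(members)

    labels = tuple(item_labels) if item_labels is not None else ()

    if kind == "unidimensional":
        pattern = np.ones((n_items, 1), dtype=bool)
        return LatentStructure(kind, pattern, ("general",), False, positive_loadings,
                               ("theta",), labels)

    cluster_names = list(cl)
    if kind == "correlated_traits":
        F = len(cluster_names)
        pattern = np.zeros((n_items, F), dtype=bool)
        for f, name in enumerate(cluster_names):
            pattern[cl[name], f] = True
        return LatentStructure(kind, pattern, ("general",) * F, True, positive_loadings,
                               tuple(cluster_names), labels)

    if kind == "bifactor":
        n_general = 1
        oblique_general = False
    F = n_general + len(cluster_names)
    pattern = np.zeros((n_items, F), dtype=bool)
    pattern[:, :n_general] = True  # every item loads on every general factor
    for i, name in enumerate(cluster_names):
        pattern[cl[name], n_general + i] = True
    tier = ("general",) * n_general + ("specific",) * len(cluster_names)
    fnames = tuple(f"G{g + 1}" for g in range(n_general)) + tuple(cluster_names)
    return LatentStructure(kind, pattern, tier, oblique_general, positive_loadings,
                           fnames, labels)


def validate_structure(s: LatentStructure) -> list:
    """Return a list of human-readable invariant violations (empty if valid)."""
    violations = []
    pattern = s.pattern
    orphan = np.nonzero(~pattern.any(axis=1))[0]
    for j in orphan:
        violations.append(f"item {j} loads on no factor")
    spec = s.specific_indices
    if spec.size:
        spec_counts = pattern[:, spec].sum(axis=1)
        for j in np.nonzero(spec_counts > 1)[0]:
            violations.append(
                f"item {j} assigned to {spec_counts[j]} specific clusters (must be exactly 1)"
            )
        for j in np.nonzero(spec_counts == 0)[0]:
            violations.append(f"item {j} belongs to no specific cluster")
        gen = s.general_indices
        if gen.size:
            incomplete = np.nonzero(~pattern[:, gen].all(axis=1))[0]
            for j in incomplete:
                violations.append(
                    f"item {j} does not load on every general factor (required with specifics)"
                )
    if s.kind == "correlated_traits" and not s.oblique_general:
        violations.append(
            "correlated-traits structure carries an orthogonality flag on the general tier"
        )
    if s.kind == "bifactor" and s.n_general != 1:
        violations.append(f"bifactor structure has {s.n_general} general factors (must be 1)")
    if len(s.tier) != s.n_factors:
        violations.append("tier labels do not match the number of factors")
    return violations


def integral_dimension(s: LatentStructure) -> int:
    """Quadrature dimensionality after two-tier reduction.

    With cluster-partitioned orthogonal specifics, items are conditionally
    independent across clusters given the generals, so only the generals
    plus one specific at a time need numerical integration:
    ``n_general + 1``.  Without specifics, every factor is integral.
    """
    violations = validate_structure(s)
    if violations:
        raise ValueError("invalid structure: " + "; ".join(violations))
    if s.specific_indices.size:
        return s.n_general + 1
    return s.n_factors


# ---------------------------------------------------------------------------
# Named candidate-model presets per instrument.
#
# The study design enumerates 16, 1, and 9 confirmatory candidates for
# SF-36, EQ-5D, and HADS.  Only a handful are described explicitly
# (unidimensional EQ-5D; HADS bifactor with 2 specifics; SF-36 two-tier
# with 2 orthogonal/oblique generals and 8 specifics, bifactor models of the
# whole questionnaire and of each component section); the remaining presets
# below are documented reconstructions of the alternatives the instruments'
# literatures discuss, not ground truth.

# 1-based item numbers per SF-36 subscale (standard Ware ordering).  The
# health-transition item 2 is conventionally reported outside the subscales;
# for latent-structure clustering it is grouped with general health here.
SF36_SUBSCALES = {
    "PF": list(range(3, 13)),
    "RP": list(range(13, 17)),
    "BP": [21, 22],
    "GH": [1, 2, 33, 34, 35, 36],
    "VT": [23, 27, 29, 31],
    "SF": [20, 32],
    "RE": [17, 18, 19],
    "MH": [24, 25, 26, 28, 30],
}
SF36_PHYSICAL = ("PF", "RP", "BP", "GH")
SF36_MENTAL = ("VT", "SF", "RE", "MH")

# HADS: odd items anxiety, even items depression (1-based).
HADS_ANXIETY = [1, 3, 5, 7, 9, 11, 13]
HADS_DEPRESSION = [2, 4, 6, 8, 10, 12, 14]
# Three-construct reconstructions (item sets are literature-inspired splits).
HADS_RESTLESSNESS = [7, 11, 13]
HADS_AGITATION = [1, 9, 11]
HADS_NEGATIVE_AFFECTIVITY = [3, 5, 9, 13]


def _to0(idx):
    return [i - 1 for i in idx]


def _sf36_cluster_labels() -> list:
    labels = [None] * 36
    for name, items in SF36_SUBSCALES.items():
        for i in items:
            labels[i - 1] = name
    return labels


def _section_items(section) -> list:
    out = []
    for name in section:
        out.extend(SF36_SUBSCALES[name])
    return sorted(out)


def _sf36_candidates() -> dict:
    sub = _sf36_cluster_labels()
    comp = ["physical" if sub[j] in SF36_PHYSICAL else "mental" for j in range(36)]
    cands = {
        "unidimensional": build_structure("unidimensional", 36),
        "correlated_2_components": build_structure("correlated_traits", 36, comp),
        "correlated_8_subscales": build_structure("correlated_traits", 36, sub),
        "bifactor_8_specifics": build_structure("bifactor", 36, sub),
        "bifactor_2_specifics": build_structure("bifactor", 36, comp),
        "two_tier_orthogonal": build_structure("two_tier", 36, sub, n_general=2),
        "two_tier_oblique": build_structure("two_tier", 36, sub, n_general=2,
                                            oblique_general=True),
        "two_tier_orthogonal_positive": build_structure(
            "two_tier", 36, sub, n_general=2, positive_loadings=True),
        "bifactor_complete_positive": build_structure("bifactor", 36, sub,
                                                      positive_loadings=True),
    }
    for tag, section in (("physical", SF36_PHYSICAL), ("mental", SF36_MENTAL)):
        items = _section_items(section)
        n = len(items)
        sec_sub = [sub[i - 1] for i in items]
        cands[f"{tag}_unidimensional"] = build_structure(
            "unidimensional", n, item_labels=[f"sf{i}" for i in items])
        cands[f"{tag}_bifactor"] = build_structure(
            "bifactor", n, sec_sub, item_labels=[f"sf{i}" for i in items])
        cands[f"{tag}_correlated_subscales"] = build_structure(
            "correlated_traits", n, sec_sub, item_labels=[f"sf{i}" for i in items])
    cands["correlated_4_domains"] = build_structure(
        "correlated_traits", 36,
        ["func" if sub[j] in ("PF", "RP") else
         "pain_gh" if sub[j] in ("BP", "GH") else
         "energy_social" if sub[j] in ("VT", "SF") else "emotional"
         for j in range(36)])
    assert len(cands) == 16
    return cands


def _hads_candidates() -> dict:
    def lab(groups: dict) -> list:
        out = [None] * 14
        for name, items in groups.items():
            for i in items:
                out[i - 1] = name
        return out

    anx_dep = lab({"anxiety": HADS_ANXIETY, "depression": HADS_DEPRESSION})
    # "item 7 moved" variant: item 7 treated as depression-leaning.
    anx_dep_v2 = lab({"anxiety": [i for i in HADS_ANXIETY if i != 7],
                      "depression": HADS_DEPRESSION + [7]})

    def three(extra_name, extra_items):
        return lab({
            "anxiety": [i for i in HADS_ANXIETY if i not in extra_items],
            "depression": [i for i in HADS_DEPRESSION if i not in extra_items],
            extra_name: extra_items,
        })

    return {
        "unidimensional": build_structure("unidimensional", 14),
        "correlated_anx_dep": build_structure("correlated_traits", 14, anx_dep),
        "correlated_anx_dep_item7": build_structure("correlated_traits", 14, anx_dep_v2),
        "correlated_3_restlessness": build_structure(
            "correlated_traits", 14, three("restlessness", HADS_RESTLESSNESS)),
        "correlated_3_agitation": build_structure(
            "correlated_traits", 14, three("agitation", HADS_AGITATION)),
        "correlated_3_negative_affectivity": build_structure(
            "correlated_traits", 14, three("neg_affect", HADS_NEGATIVE_AFFECTIVITY)),
        "bifactor_2_specifics": build_structure("bifactor", 14, anx_dep),
        "bifactor_3_specifics": build_structure(
            "bifactor", 14, three("restlessness", HADS_RESTLESSNESS)),
        "bifactor_2_specifics_positive": build_structure(
            "bifactor", 14, anx_dep, positive_loadings=True),
    }


def candidate_models(instrument: str) -> dict:
    """Named confirmatory candidate structures for one instrument.

    ``sf36`` ships 16 candidates, ``eq5d`` 1, ``hads`` 9 (matching the
    study protocol's counts; candidates beyond those the protocol describes
    are reconstructions).
    """
    instrument = instrument.lower()
    if instrument == "sf36":
        return _sf36_candidates()
    if instrument == "eq5d":
        return {"unidimensional": build_structure("unidimensional", 5)}
    if instrument == "hads":
        return _hads_candidates()
    raise ValueError(f"unknown instrument {instrument!r}; expected sf36, eq5d, or hads")


# ---------------------------------------------------------------------------
# Config serialization (plain dicts; YAML handling lives in irtqol.io).


def structure_to_config(s: LatentStructure) -> dict:
    return {
        "kind": s.kind,
        "factors": [
            {"name": name, "tier": tier,
             "items": [s.item_labels[j] for j in np.nonzero(s.pattern[:, f])[0]]}
            for f, (name, tier) in enumerate(zip(s.factor_names, s.tier))
        ],
        "items": list(s.item_labels),
        "oblique_general": bool(s.oblique_general),
        "positive_loadings": bool(s.positive_loadings),
    }


def structure_from_config(cfg: dict) -> LatentStructure:
    items = list(cfg["items"])
    index = {lab: j for j, lab in enumerate(items)}
    factors = cfg["factors"]
    pattern = np.zeros((len(items), len(factors)), dtype=bool)
    for f, fac in enumerate(factors):
        for lab in fac["items"]:
            pattern[index[lab], f] = True
    return LatentStructure(
        kind=cfg["kind"],
        pattern=pattern,
        tier=tuple(fac["tier"] for fac in factors),
        oblique_general=bool(cfg.get("oblique_general", False)),
        positive_loadings=bool(cfg.get("positive_loadings", False)),
        factor_names=tuple(fac["name"] for fac in factors),
        item_labels=tuple(items),
    )
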