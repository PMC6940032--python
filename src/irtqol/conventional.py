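"""Conventional (classical) questionnaire scores used as IRT comparators.

* HADS: anxiety and depression subscale sums (0-21 each; no proration —
  any missing member item makes the sum missing).
* SF-36: the 8 subscale scores on 0-100 via config-driven recode tables
  (half-scale missing rule), plus physical/mental component summaries from
  config-driven z-scoring weights.
* EQ-5D: the preference-based index from a value set (the UK time
  trade-off set ships as the default config).

All scoring tables live in editable YAML config files under
``irtqol/config`` — coefficients are never hard-coded.  All functions
accept a single response vector or a 2-D (persons x items) batch, and are
deterministic and order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .items import MISSING
from .structures import HADS_ANXIETY, HADS_DEPRESSION

__all__ = [
    "ValueSet",
    "load_value_set",
    "load_sf36_scoring",
    "load_sf36_component_weights",
    "eq5d_index",
    "hads_sums",
    "sf36_subscales",
    "sf36_component_summaries",
]


def _read_packaged_yaml(name: str) -> dict:
    with resources.files("irtqol.config").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ValueSet:
    """Preference weights converting an EQ-5D profile to a utility index."""

    name: str
    full_health: float
    any_dysfunction_constant: float
    worst_level_constant: float
    dimensions: tuple
    decrements: dict  # dimension -> {level: decrement}

    def __post_init__(self) -> None:
        # invariant: the full-health state scores exactly full_health
        for dim in self.dimensions:
            if dim not in self.decrements:
                raise ValueError(f"value set missing decrements for {dim!r}")


def load_value_set(path=None) -> ValueSet:
    """Load a value set config (default: the UK TTO set shipped in-package)."""
    if path is None:
        cfg = _read_packaged_yaml("eq5d_uk_tto.yaml")
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    return ValueSet(
        name=cfg["name"],
        full_health=float(cfg["full_health"]),
        any_dysfunction_constant=float(cfg["any_dysfunction_constant"]),
        worst_level_constant=float(cfg["worst_level_constant"]),
        dimensions=tuple(cfg["dimensions"]),
        decrements={k: {int(l): float(v) for l, v in d.items()}
                    for k, d in cfg["decrements"].items()},
    )


def load_sf36_scoring(path=None) -> dict:
    if path is None:
        return _read_packaged_yaml("sf36_scoring.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_sf36_component_weights(path=None) -> dict:
    if path is None:
        return _read_packaged_yaml("sf36_component_weights_synthetic.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _as_batch(responses, n_items: int) -> tuple:
    arr = np.asarray(responses, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != n_items:
        raise ValueError(f"expected {n_items} items, got {arr.shape[1]}")
    arr = np.where(arr == MISSING, np.nan, arr)
    return arr, single


def eq5d_index(responses, value_set: ValueSet | None = None):
    """EQ-5D utility index from 5 dimension levels coded 1-3.

    Any missing dimension makes the index missing; a level outside 1-3 is
    an error.  The index decreases (weakly) as any dimension worsens for a
    valid value set.
    """
    vs = value_set if value_set is not None else load_value_set()
    arr, single = _as_batch(responses, 5)
    obs = ~np.isnan(arr)
    bad = obs & ((arr < 1) | (arr > 3))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"level {arr[i, j]} outside 1..3 (row {i}, dim {j})")
    idx = np.full(arr.shape[0], vs.full_health)
    any_dysfunction = np.nanmax(arr, axis=1, initial=1.0) > 1
    any_worst = np.nanmax(arr, axis=1, initial=1.0) >= 3
    idx -= np.where(any_dysfunction, vs.any_dysfunction_constant, 0.0)
    idx -= np.where(any_worst, vs.worst_level_constant, 0.0)
    for d, dim in enumerate(vs.dimensions):
        dec = vs.decrements[dim]
        col = arr[:, d]
        idx -= np.where(col == 2, dec[2], 0.0)
        idx -= np.where(col == 3, dec[3], 0.0)
    idx = np.where(obs.all(axis=1), idx, np.nan)
    return float(idx[0]) if single else idx


def hads_sums(responses, anxiety_items=None, depression_items=None):
    """HADS anxiety and depression sums (each 0-21) from 14 items coded 0-3.

    Items are assumed reverse-keyed upstream.  The default subscale map is
    the original alternating assignment (odd items anxiety, even items
    depression, 1-based).  No proration: a missing member item makes that
    subscale sum missing.  Returns ``(anxiety, depression)``.
    """
    arr, single = _as_batch(responses, 14)
    if np.nanmax(arr, initial=0.0) > 3 or np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("HADS responses must be coded 0-3")
    anx = [i - 1 for i in (anxiety_items or HADS_ANXIETY)]
    dep = [i - 1 for i in (depression_items or HADS_DEPRESSION)]
    a = np.where(np.isnan(arr[:, anx]).any(axis=1), np.nan,
                 np.nansum(arr[:, anx], axis=1))
    d = np.where(np.isnan(arr[:, dep]).any(axis=1), np.nan,
                 np.nansum(arr[:, dep], axis=1))
    if single:
        return float(a[0]), float(d[0])
    return a, d


def sf36_subscales(responses, scoring: dict | None = None,
                   item_labels=None) -> pd.DataFrame:
    """The 8 SF-36 subscale scores on 0-100 from a 36-item response batch.

    Each item is recoded through its config value table (category code ->
    0-100 value) and subscales average their member items; a subscale is
    computed when at least half its member items are present (half-scale
    rule), otherwise missing.
    """
    cfg = scoring if scoring is not None else load_sf36_scoring()
    arr, single = _as_batch(responses, 36)
    labels = list(item_labels) if item_labels is not None else [
        f"sf{j + 1}" for j in range(36)]
    col = {lab: j for j, lab in enumerate(labels)}
    recoded = np.full_like(arr, np.nan)
    for lab, spec in cfg["items"].items():
        values = np.asarray(spec["values"], dtype=float)
        j = col[lab]
        x = arr[:, j]
        ok = ~np.isnan(x)
        if ok.any():
            codes = x[ok].astype(int)
            if codes.min() < 0 or codes.max() >= values.size:
                raise ValueError(
                    f"item {lab!r}: category outside the recode table "
                    f"(0..{values.size - 1})")
            out = np.full(x.shape, np.nan)
            out[ok] = values[codes]
            recoded[:, j] = out
    scores = {}
    for name, members in cfg["subscales"].items():
        cols = [col[lab] for lab in members]
        block = recoded[:, cols]
        present = (~np.isnan(block)).sum(axis=1)
        enough = present >= np.ceil(len(cols) / 2)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=1)
        scores[name] = np.where(enough, mean, np.nan)
    df = pd.DataFrame(scores)
    return df.iloc[0] if single else df


def sf36_component_summaries(subscales, weights: dict | None = None):
    """Physical and mental component summaries from the 8 subscale scores.

    Subscales are z-scored against config reference means/SDs, combined
    with config factor weights, and linearly transformed
    (``center + scale * weighted_sum``).  Any missing subscale makes both
    summaries missing for that person.  Returns a DataFrame with columns
    ``physical`` and ``mental`` (or a Series for a single person).
    """
    cfg = weights if weights is not None else load_sf36_component_weights()
    single = isinstance(subscales, pd.Series)
    df = subscales.to_frame().T if single else pd.DataFrame(subscales)
    names = list(cfg["reference_means"])
    z = pd.DataFrame(index=df.index)
    for name in names:
        z[name] = (df[name] - cfg["reference_means"][name]) / cfg["reference_sds"][name]
    out = pd.DataFrame(index=df.index)
    for comp in ("physical", "mental"):
        w = cfg["weights"][comp]
        out[comp] = (cfg["transform"]["center"]
                     + cfg["transform"]["scale"]
                     * sum(z[name] * w[name] for name in names))
    out[z.isna().any(axis=1)] = np.nan
    return out.iloc[0] if single else out
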