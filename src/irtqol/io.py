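"""Response-matrix container, CSV readers/writers, config files, manifests.

The canonical on-disk format for response data is a wide CSV: a header row
of item labels, one row per person, integer category codes ``0..K-1``, and
blank cells for missing responses.  In memory the matrix is an integer
array with :data:`irtqol.items.MISSING` (-1) marking missingness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .items import MISSING

logger = logging.getLogger("irtqol")

__all__ = [
    "ResponseMatrix",
    "read_responses",
    "write_responses",
    "read_config",
    "write_config",
    "RunManifest",
]


@dataclass
class ResponseMatrix:
    """Persons x items ordinal response codes with missingness.

    ``values`` is an ``(N, J)`` integer array; -1 marks a missing cell.
    Persons with all-missing rows are retained here — they are excluded at
    fit time, where the exclusion count is logged.
    """

    values: np.ndarray
    item_labels: tuple
    person_ids: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D persons x items array")
        self.item_labels = tuple(self.item_labels)
        if len(self.item_labels) != self.values.shape[1]:
            raise ValueError("item_labels length must match number of columns")
        if len(set(self.item_labels)) != len(self.item_labels):
            raise ValueError("duplicated item labels")
        if not self.person_ids:
            self.person_ids = tuple(range(self.values.shape[0]))
        else:
            self.person_ids = tuple(self.person_ids)
        if len(self.person_ids) != self.values.shape[0]:
            raise ValueError("person_ids length must match number of rows")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def observed_categories(self, j: int) -> np.ndarray:
        """Sorted distinct observed category codes of item ``j``."""
        col = self.values[:, j]
        return np.unique(col[col != MISSING])

    def subset(self, person_index) -> "ResponseMatrix":
        person_index = np.asarray(person_index)
        return ResponseMatrix(
            self.values[person_index],
            self.item_labels,
            tuple(np.asarray(self.person_ids, dtype=object)[person_index]),
        )

    def complete_cases(self) -> "ResponseMatrix":
        keep = ~self.missing_mask.any(axis=1)
        return self.subset(np.nonzero(keep)[0])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(float), columns=list(self.item_labels),
                          index=list(self.person_ids))
        return df.where(self.values != MISSING)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        vals = df.to_numpy(dtype=float)
        out = np.where(np.isnan(vals), MISSING, vals).astype(np.int64)
        return cls(out, tuple(map(str, df.columns)), tuple(df.index))


def read_responses(path, schema=None) -> ResponseMatrix:
    """Read a wide-format response CSV.

    ``schema`` optionally maps item label -> number of categories K; when
    given, category codes are validated against ``0..K-1`` and offending
    cells are reported by row and column.
    """
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicated item label(s) in header: {dupes}")
    df = pd.read_csv(path, index_col=None)
    vals = df.to_numpy(dtype=float)
    frac = vals[~np.isnan(vals)] % 1
    if frac.size and np.any(frac != 0):
        raise ValueError("non-integer category codes in response file")
    data = ResponseMatrix.from_dataframe(df)
    if schema is not None:
        for j, lab in enumerate(data.item_labels):
            if lab not in schema:
                raise ValueError(f"item {lab!r} absent from schema")
            K = int(schema[lab])
            col = data.values[:, j]
            bad = np.nonzero((col != MISSING) & ((col < 0) | (col >= K)))[0]
            if bad.size:
                raise ValueError(
                    f"item {lab!r}, row {bad[0]}: category {col[bad[0]]} outside 0..{K - 1}"
                )
    n_missing = int(data.missing_mask.sum())
    logger.info("read %s: shape (%d, %d), %d missing cells",
                path, data.n_persons, data.n_items, n_missing)
    return data


def write_responses(data: ResponseMatrix, path) -> None:
    """Write the CSV dialect read by :func:`read_responses` (blank = missing)."""
    df = data.to_dataframe()
    df.to_csv(path, index=False, float_format="%.0f")


def write_parameter_tables(model, slopes_path, intercepts_path) -> None:
    """Serialize item parameters as two CSVs.

    Slopes: columns item, factor, slope (free loadings only).
    Intercepts: columns item, k, intercept (k = 1..K-1).
    """
    srows, irows = [], []
    s = model.structure
    labels = model.item_labels or tuple(f"item{j + 1}" for j in range(model.n_items))
    for j, params in enumerate(model.items):
        for f in np.nonzero(s.pattern[j])[0]:
            srows.append({"item": labels[j], "factor": s.factor_names[f],
                          "slope": params.slopes[f]})
        for k, d in enumerate(params.intercepts, start=1):
            irows.append({"item": labels[j], "k": k, "intercept": d})
    pd.DataFrame(srows).to_csv(slopes_path, index=False)
    pd.DataFrame(irows).to_csv(intercepts_path, index=False)


def write_fit_log(model, path) -> None:
    """Plain-text fit log: per-iteration marginal log-likelihood."""
    with open(path, "w") as fh:
        fh.write(f"converged: {model.converged}\n")
        fh.write(f"iterations: {model.iterations}\n")
        for note in model.notes:
            fh.write(f"note: {note}\n")
        fh.write("iteration,loglik\n")
        for i, ll in enumerate(model.loglik_history, start=1):
            fh.write(f"{i},{ll:.8f}\n")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(path)

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["config_hash"] = hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
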