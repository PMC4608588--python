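"""Data containers and delimited-text I/O.

The package works on stratified case-control samples where the observed
label ``z`` may be wrong for controls only (one-sided noise): every z = 1
row is a true case, while z = 0 rows are a mixture of true controls and
mislabeled cases.  When the true label ``y`` is known (validation
experiments, artificial contamination) it travels alongside as ``y_true``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ContaminatedDataset", "Term", "ColumnSpec", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContaminatedDataset:
    """A covariate matrix with observed labels and optional true labels.

    Invariants enforced at construction: labels are binary, both label
    values occur, X is finite, and if ``y_true`` is present then every
    z = 1 row has y_true = 1 (mislabeling runs in one direction only).
    """

    X: np.ndarray
    z: np.ndarray
    y_true: np.ndarray | None = None
    names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        z = np.asarray(self.z)
        if z.shape != (X.shape[0],):
            raise ValueError("z length must match rows of X")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("observed labels z must all be 0 or 1")
        z = z.astype(np.int8)
        if z.min() == z.max():
            raise ValueError("both label values (z = 0 and z = 1) must be present")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing or non-finite values")
        y = self.y_true
        if y is not None:
            y = np.asarray(y)
            if y.shape != z.shape or not np.isin(y, (0, 1)).all():
                raise ValueError("y_true must be binary and match z in length")
            y = y.astype(np.int8)
            if np.any((z == 1) & (y == 0)):
                raise ValueError(
                    "one-sided noise violated: a z = 1 row has y_true = 0"
                )
        names = self.names
        if names is None:
            names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
        names = tuple(names)
        if len(names) != X.shape[1]:
            raise ValueError("names length must match number of covariates")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "y_true", y)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n0(self) -> int:
        """Number of rows labeled control (z = 0)."""
        return int(np.sum(self.z == 0))

    @property
    def n1(self) -> int:
        """Number of rows labeled case (z = 1)."""
        return int(np.sum(self.z == 1))

    def with_labels(self, z) -> "ContaminatedDataset":
        return replace(self, z=np.asarray(z))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df.insert(0, "z", self.z)
        if self.y_true is not None:
            df.insert(0, "y", self.y_true)
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        label: str = "z",
        covariates: list[str] | None = None,
        true_label: str | None = None,
    ) -> "ContaminatedDataset":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (label, true_label)]
        return cls(
            X=df[covariates].to_numpy(dtype=float),
            z=df[label].to_numpy(),
            y_true=df[true_label].to_numpy() if true_label else None,
            names=tuple(covariates),
        )


@dataclass(frozen=True)
class Term:
    """One model term: a raw column with an optional (x - shift)/scale
    transform raised to ``power``, e.g. Term("age", 50, 10) for
    (age - 50)/10 and Term("age", 50, 10, power=2) for its square."""

    column: str
    shift: float = 0.0
    scale: float = 1.0
    power: float = 1.0
    name: str | None = None

    def __post_init__(self):
        for v in (self.shift, self.scale, self.power):
            if not np.isfinite(v):
                raise ValueError(f"non-finite transform parameter in term {self.column!r}")
        if self.scale == 0:
            raise ValueError(f"scale must be nonzero in term {self.column!r}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        s = self.column
        if self.shift != 0 or self.scale != 1:
            s = f"({self.column}-{self.shift:g})/{self.scale:g}"
        if self.power != 1:
            s = f"[{s}]^{self.power:g}"
        return s

    def apply(self, x: np.ndarray) -> np.ndarray:
        return ((np.asarray(x, dtype=float) - self.shift) / self.scale) ** self.power


@dataclass(frozen=True)
class ColumnSpec:
    """Maps file columns to the analysis: which column carries the observed
    label z, optionally which carries the true label y, and the ordered
    covariate terms."""

    label_column: str
    covariates: tuple[Term, ...]
    true_label_column: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        labels = [t.label for t in self.covariates]
        if len(set(labels)) != len(labels):
            raise ValueError("covariate term names must be unique")


def _sniff_delimiter(path: Path) -> str | None:
    """Return ',' or '\\t', or None meaning any-whitespace."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return None


def read_dataset(path, spec: ColumnSpec) -> ContaminatedDataset:
    """Read a delimited text file (whitespace, comma, or tab; header row
    required) and assemble a :class:`ContaminatedDataset` per ``spec``.

    Missing values must be encoded as an empty field or ``NA``; any other
    non-numeric token is a parse error reporting the file line.  Rows with
    a missing value in any used column are dropped and the count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else r"\s+",
        na_values=["NA", ""],
        keep_default_na=False,
        dtype=str,
        skip_blank_lines=True,
    )
    df.columns = [str(c).strip() for c in df.columns]

    used = [spec.label_column] + [t.column for t in spec.covariates]
    if spec.true_label_column:
        used.append(spec.true_label_column)
    for col in dict.fromkeys(used):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path.name}; available: {list(df.columns)}"
            )

    numeric = {}
    for col in dict.fromkeys(used):
        raw = df[col].str.strip() if df[col].dtype == object else df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
            raise ValueError(
                f"column {col!r}: unparseable value(s) at file line(s) {lines[:10]}"
                " (missing data must be empty or 'NA')"
            )
        numeric[col] = vals

    used_df = pd.DataFrame(numeric)
    complete = used_df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing values in used columns", n_dropped)
    used_df = used_df[complete]

    zraw = used_df[spec.label_column]
    if not zraw.isin([0, 1]).all():
        raise ValueError(f"label column {spec.label_column!r} is not binary 0/1")

    X = np.column_stack([t.apply(used_df[t.column].to_numpy()) for t in spec.covariates])
    y = None
    if spec.true_label_column:
        yraw = used_df[spec.true_label_column]
        if not yraw.isin([0, 1]).all():
            raise ValueError(f"true-label column {spec.true_label_column!r} is not binary 0/1")
        y = yraw.to_numpy()
    return ContaminatedDataset(
        X=X,
        z=zraw.to_numpy(),
        y_true=y,
        names=tuple(t.label for t in spec.covariates),
    )


def write_dataset(data: ContaminatedDataset, path, sep: str = "\t") -> None:
    """Write a dataset as delimited text with header, full float precision."""
    data.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")
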