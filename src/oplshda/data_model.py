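"""Dataset container, column preprocessing, and dummy-response encoding.

Every downstream stage (pairwise OPLS-DA models, cross-validation, the
hierarchical decision tree) consumes the :class:`Dataset` defined here: a
samples x variables matrix of real numbers with one categorical class label
per sample.  Preprocessing (mean centering with optional unit-variance or
Pareto scaling) is always *fit on training samples only* and applied to
held-out samples, so no information leaks into cross-validated predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Floor for per-column scale factors; a constant column is divided by this
#: instead of zero, so it survives scaling as an (effectively) all-zero column.
EPSILON = 1e-12

SCALING_MODES = ("center", "uv", "pareto", "none")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OplsHdaError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(OplsHdaError):
    """An option or parameter is outside its valid domain."""


class ValidationError(OplsHdaError):
    """Input data violates a structural invariant."""


class ParseError(OplsHdaError):
    """A file could not be interpreted as a numeric data table."""


class DegenerateResponseError(OplsHdaError):
    """The response vector has no variance; no discriminant direction exists."""


class RankError(OplsHdaError):
    """More latent components requested than the data can support."""


class ShapeError(OplsHdaError):
    """A matrix does not have the expected dimensions."""


class InsufficientSamplesError(ValidationError):
    """A group is too small for the requested statistic."""


class BuildError(OplsHdaError):
    """The hierarchical model could not be assembled."""


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A samples x variables data matrix with per-sample class labels.

    Parameters
    ----------
    values
        Numeric matrix, shape ``(n_samples, n_variables)``.  Must be free of
        NaN/inf after ingestion.
    sample_ids
        Unique sample identifiers, length ``n_samples``.
    variable_names
        Unique variable (feature) names, length ``n_variables``.
    labels
        Class name per sample, or ``None`` for unlabeled data (prediction
        input).  When present, every class must have at least two samples —
        the pooled standard deviation behind Cohen's d is undefined otherwise.
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_names: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variable_names) != p:
            raise ValidationError(
                f"{len(self.variable_names)} variable names for {p} columns")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if len(set(self.variable_names)) != p:
            dup = _first_duplicate(self.variable_names)
            raise ValidationError(f"duplicate variable name: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_names[j]!r}")
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValidationError(
                    f"{len(self.labels)} labels for {n} rows")
            counts = pd.Series(self.labels).value_counts()
            small = counts[counts < 2]
            if len(small):
                raise ValidationError(
                    f"class {small.index[0]!r} has only {int(small.iloc[0])} "
                    "sample(s); every class needs at least 2")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list[str]:
        """Class names present, in lexicographic order."""
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        return sorted(set(self.labels))

    def class_indices(self, name: str) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        return np.flatnonzero(np.asarray(self.labels) == name)

    def subset_classes(self, names: Iterable[str]) -> "Dataset":
        """Rows belonging to the given classes, original order preserved."""
        wanted = set(names)
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        unknown = wanted - set(self.labels)
        if unknown:
            raise ValidationError(f"unknown class: {sorted(unknown)[0]!r}")
        mask = np.array([lab in wanted for lab in self.labels])
        return Dataset(
            values=self.values[mask],
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            variable_names=list(self.variable_names),
            labels=[l for l, m in zip(self.labels, mask) if m],
        )

    def subset_rows(self, index: np.ndarray) -> "Dataset":
        index = np.asarray(index)
        return Dataset(
            values=self.values[index],
            sample_ids=[self.sample_ids[i] for i in index],
            variable_names=list(self.variable_names),
            labels=None if self.labels is None
            else [self.labels[i] for i in index],
        )

    def to_csv(self, path: str | Path, label_column: str = "class",
               delimiter: str = ",") -> None:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df.insert(1, label_column, self.labels)
        df.to_csv(path, sep=delimiter, index=False)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate")  # pragma: no cover


def load_dataset(path: str | Path, label_column: str | None = "class",
                 delimiter: str = ",", id_column: str | None = "sample_id",
                 impute_missing: bool = False) -> Dataset:
    """Read a CSV/TSV table into a :class:`Dataset`.

    The first row is the header.  ``label_column`` holds class names (pass
    ``None`` for unlabeled prediction input); ``id_column`` holds sample ids
    (``None`` generates ``s0``, ``s1``, ...).  All remaining columns must be
    numeric; column order is preserved.  Missing entries are rejected unless
    ``impute_missing`` replaces them with the column mean.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str,
                         keep_default_na=True, encoding="utf-8")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not read {path}: {exc}") from exc

    if id_column is not None and id_column in df.columns:
        sample_ids = [str(v) for v in df.pop(id_column)]
    else:
        sample_ids = [f"s{i}" for i in range(len(df))]

    labels: list[str] | None = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ConfigurationError(
                f"label column {label_column!r} not in header "
                f"(columns: {', '.join(df.columns[:8])}...)")
        labels = [str(v) for v in df.pop(label_column)]

    variable_names = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} in row "
                f"{sample_ids[i]!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)

    if np.isnan(values).any():
        if impute_missing:
            col_means = np.nanmean(values, axis=0)
            holes = np.isnan(values)
            values[holes] = np.take(col_means, np.where(holes)[1])
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at row {sample_ids[i]!r}, column "
                f"{variable_names[j]!r} (use impute_missing to fill with "
                "column means)")

    return Dataset(values=values, sample_ids=sample_ids,
                   variable_names=variable_names, labels=labels)


# ---------------------------------------------------------------------------
# Preprocessor
# ---------------------------------------------------------------------------

@dataclass
class Preprocessor:
    """Column centering/scaling state, fit on training data only.

    Modes: ``center`` (mean only), ``uv`` (unit variance: divide by sample
    SD), ``pareto`` (divide by sqrt of SD), ``none``.  Scales are floored at
    :data:`EPSILON` so constant columns map to ~0 rather than dividing by
    zero.
    """

    column_means: np.ndarray
    column_scales: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_scales = np.asarray(self.column_scales, dtype=float)
        if self.mode not in SCALING_MODES:
            raise ConfigurationError(
                f"unknown scaling mode {self.mode!r}; "
                f"choose from {SCALING_MODES}")
        if np.any(self.column_scales < EPSILON):
            raise ValidationError("column scales must be >= epsilon floor")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.column_means.shape[0]:
            raise ShapeError(
                f"expected {self.column_means.shape[0]} columns, "
                f"got {X.shape[-1]}")
        return (X - self.column_means) / self.column_scales

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X * self.column_scales + self.column_means

    def to_dict(self) -> dict:
        return {"column_means": self.column_means.tolist(),
                "column_scales": self.column_scales.tolist(),
                "mode": self.mode}

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        return cls(np.array(d["column_means"], dtype=float),
                   np.array(d["column_scales"], dtype=float), d["mode"])


def fit_preprocessor(X: np.ndarray | Dataset, mode: str = "uv") -> Preprocessor:
    """Fit column means/scales on training data.

    ``uv`` uses the sample standard deviation (ddof=1); ``pareto`` its square
    root.  Scales are floored at :data:`EPSILON`.
    """
    if isinstance(X, Dataset):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("expected a 2-D matrix")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to fit preprocessing")
    if mode not in SCALING_MODES:
        raise ConfigurationError(
            f"unknown scaling mode {mode!r}; choose from {SCALING_MODES}")
    p = X.shape[1]
    if mode == "none":
        means = np.zeros(p)
        scales = np.ones(p)
    else:
        means = X.mean(axis=0)
        if mode == "center":
            scales = np.ones(p)
        else:
            sd = X.std(axis=0, ddof=1)
            if mode == "pareto":
                sd = np.sqrt(sd)
            scales = np.maximum(sd, EPSILON)
    return Preprocessor(column_means=means, column_scales=scales, mode=mode)


# ---------------------------------------------------------------------------
# Dummy response
# ---------------------------------------------------------------------------

@dataclass
class DummyResponse:
    """0/1 class-membership response for a two-group OPLS-DA model.

    ``class0`` samples are coded 0, ``class1`` samples 1; the two sets are
    disjoint and jointly cover every label encoded.  For a balanced two-class
    set the mean of ``y`` is exactly 0.5, which is where a weak model's
    predictions collapse.
    """

    y: np.ndarray
    class0: frozenset[str]
    class1: frozenset[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.class0 = frozenset(self.class0)
        self.class1 = frozenset(self.class1)
        if self.class0 & self.class1:
            raise ValidationError("class0 and class1 overlap")

    def to_dict(self) -> dict:
        return {"y": self.y.tolist(),
                "class0": sorted(self.class0),
                "class1": sorted(self.class1)}

    @classmethod
    def from_dict(cls, d: dict) -> "DummyResponse":
        return cls(np.array(d["y"], dtype=float),
                   frozenset(d["class0"]), frozenset(d["class1"]))


def encode_dummy(labels: Sequence[str], class0: Iterable[str],
                 class1: Iterable[str]) -> DummyResponse:
    """Encode class labels as a 0/1 response vector."""
    class0 = frozenset(class0)
    class1 = frozenset(class1)
    if class0 & class1:
        raise ValidationError("class0 and class1 overlap")
    y = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab in class0:
            y[i] = 0.0
        elif lab in class1:
            y[i] = 1.0
        else:
            raise ValidationError(
                f"label {lab!r} belongs to neither group")
    return DummyResponse(y=y, class0=class0, class1=class1)
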