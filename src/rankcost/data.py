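"""Loading, encoding and simulation of binary-labeled tabular data.

Datasets are delimited text (CSV with a header row) or ARFF attribute files
in the UCI dialect.  After loading, nominal attributes are one-hot encoded,
missing values are imputed (median for numeric columns, mode for nominal
ones) and labels are mapped to {+1, -1} with +1 reserved for the caller's
declared positive (minority) class.  The synthetic generator produces
imbalanced two-class Gaussian fixtures with a known amount of class
separation, optional nominal attributes and optional missing entries, so
every downstream component can be exercised without external downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = [
    "FeatureMeta",
    "LabeledDataset",
    "SyntheticSpec",
    "load_table",
    "generate_synthetic",
    "synthetic_frame",
    "encode_frame",
    "apply_encoding",
    "dataset_to_frame",
]

MISSING_TOKEN = "?"


@dataclass(frozen=True)
class FeatureMeta:
    """Per original attribute: name, kind, levels and imputation value.

    ``kind`` is "numeric" or "nominal".  ``levels`` lists the category
    levels of a nominal attribute in encoding order (empty for numeric).
    ``fill_value`` is the value imputation substitutes for missing entries
    (median for numeric, modal level for nominal), recorded even when the
    training column had none so the same rule can be re-applied to new data.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    fill_value: object | None = None


@dataclass
class LabeledDataset:
    """Encoded numeric feature matrix with {+1, -1} labels.

    +1 marks the minority (positive / abnormal) class, -1 the majority
    (negative / normal) class.  ``features`` is dense float64 with one-hot
    columns expanded; ``columns`` names the encoded columns.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_meta: list[FeatureMeta] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match the number of rows")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1 or -1, found {sorted(bad)}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite entries")
        if not self.columns:
            self.columns = [f"x{j}" for j in range(self.features.shape[1])]

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_pos(self) -> int:
        """Minority class size S."""
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        """Majority class size T = n - S."""
        return int(np.sum(self.labels == -1))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class Gaussian mixture generator.

    ``separation`` is the Euclidean distance between the class mean vectors
    in units of the (unit) within-class standard deviation.  ``n_nominal``
    adds that many 3-level nominal attributes whose level probabilities
    depend on the class.  ``missing_rate`` blanks that fraction of feature
    cells before imputation.
    """

    n_pos: int
    n_neg: int
    dim: int = 2
    separation: float = 0.0
    n_nominal: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("each class needs at least one sample")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.n_nominal < 0:
            raise ValueError("n_nominal must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# encoding / imputation


def _impute_column(col: pd.Series, kind: str) -> tuple[pd.Series, object]:
    if col.isna().all():
        raise ValueError(f"column '{col.name}' has all values missing")
    if kind == "numeric":
        fill = float(col.median())
    else:
        fill = col.mode(dropna=True).iloc[0]
    return col.fillna(fill), fill


def encode_frame(frame: pd.DataFrame) -> tuple[np.ndarray, list[FeatureMeta], list[str]]:
    """One-hot encode nominal columns and impute missing values.

    Columns of object/category dtype are treated as nominal; everything
    else as numeric.  Returns the dense float matrix, per-attribute
    metadata, and the encoded column names.
    """
    meta: list[FeatureMeta] = []
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for name in frame.columns:
        col = frame[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype("string").str.strip()
            col = col.mask(col == MISSING_TOKEN)
            col, fill = _impute_column(col, "nominal")
            levels = tuple(sorted(col.dropna().unique()))
            onehot = np.column_stack([(col == lv).to_numpy(dtype=np.float64) for lv in levels])
            meta.append(FeatureMeta(str(name), "nominal", levels, fill))
            blocks.append(onehot)
            names.extend(f"{name}={lv}" for lv in levels)
        else:
            col = pd.to_numeric(col, errors="coerce")
            col, fill = _impute_column(col, "numeric")
            meta.append(FeatureMeta(str(name), "numeric", (), fill))
            blocks.append(col.to_numpy(dtype=np.float64)[:, None])
            names.append(str(name))
    matrix = np.hstack(blocks) if blocks else np.empty((len(frame), 0))
    return matrix, meta, names


def apply_encoding(frame: pd.DataFrame, meta: Sequence[FeatureMeta]) -> np.ndarray:
    """Re-apply a training-time encoding (levels + imputation) to new rows.

    Nominal levels unseen at training time encode as an all-zero one-hot
    block; missing entries take the stored training fill value.
    """
    blocks: list[np.ndarray] = []
    for fm in meta:
        if fm.name not in frame.columns:
            raise ValueError(f"input is missing the attribute '{fm.name}'")
        col = frame[fm.name]
        if fm.kind == "nominal":
            col = col.astype("string").str.strip()
            col = col.mask(col == MISSING_TOKEN).fillna(fm.fill_value)
            blocks.append(
                np.column_stack(
                    [(col == lv).to_numpy(dtype=np.float64) for lv in fm.levels]
                )
            )
        else:
            col = pd.to_numeric(col, errors="coerce").fillna(fm.fill_value)
            blocks.append(col.to_numpy(dtype=np.float64)[:, None])
    return np.hstack(blocks) if blocks else np.empty((len(frame), 0))


def _map_labels(raw: pd.Series, positive_label: object) -> np.ndarray:
    raw = raw.astype("string").str.strip()
    pos = str(positive_label)
    values = set(raw.dropna().unique())
    if pos not in values:
        raise ValueError(f"positive label {positive_label!r} never occurs in the label column")
    others = values - {pos}
    if len(others) != 1:
        raise ValueError(
            "label column must be binary: expected exactly one value besides "
            f"{positive_label!r}, found {sorted(others)}"
        )
    if raw.isna().any():
        raise ValueError("label column contains missing values")
    return np.where(raw == pos, 1, -1).astype(np.int64)


# ---------------------------------------------------------------------------
# readers


def _read_arff(path: Path) -> pd.DataFrame:
    data, meta_info = scipy_arff.loadarff(str(path))
    frame = pd.DataFrame(data)
    for name in frame.columns:
        if frame[name].dtype == object:
            decoded = frame[name].str.decode("utf-8")
            frame[name] = decoded.mask(decoded == MISSING_TOKEN)
    return frame


def load_table(
    path: str | Path,
    label_column: str,
    positive_label: object,
    *,
    fmt: str | None = None,
    sep: str = ",",
) -> LabeledDataset:
    """Load a CSV or ARFF file into an encoded, imputed :class:`LabeledDataset`.

    ``positive_label`` names the raw label value of the minority class; it
    must be stated explicitly (rarity-based auto-detection is refused as it
    is ambiguous on balanced subsets).  The file format is inferred from
    the extension unless ``fmt`` ("csv" or "arff") is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = fmt or ("arff" if path.suffix.lower() == ".arff" else "csv")
    if kind == "arff":
        frame = _read_arff(path)
    else:
        frame = pd.read_csv(
            path, sep=sep, na_values=[MISSING_TOKEN], skipinitialspace=True,
            comment="#",
        )
    if label_column not in frame.columns:
        raise ValueError(
            f"label column '{label_column}' not found; columns are {list(frame.columns)}"
        )
    labels = _map_labels(frame[label_column], positive_label)
    matrix, meta, names = encode_frame(frame.drop(columns=[label_column]))
    return LabeledDataset(matrix, labels, meta, names)


# ---------------------------------------------------------------------------
# synthetic generator

_NOMINAL_LEVELS = ("u", "v", "w")
# class-conditional level probabilities: mildly informative nominal signal
_NOMINAL_P_POS = (0.6, 0.3, 0.1)
_NOMINAL_P_NEG = (0.2, 0.3, 0.5)


def synthetic_frame(spec: SyntheticSpec) -> pd.DataFrame:
    """Raw (pre-imputation) synthetic table with a ``label`` column.

    Numeric features come from unit-variance isotropic Gaussians whose
    means differ by ``spec.separation`` along the first coordinate axis.
    Missing cells are left as NaN (numeric) / NA (nominal); the encoding
    pipeline or a written '?' token downstream handles them.
    The first ``n_pos`` rows are the minority ("pos") class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    x = rng.standard_normal((n, spec.dim))
    x[: spec.n_pos, 0] += spec.separation
    frame = pd.DataFrame(x, columns=[f"num{j}" for j in range(spec.dim)])
    for j in range(spec.n_nominal):
        pos_draw = rng.choice(_NOMINAL_LEVELS, size=spec.n_pos, p=_NOMINAL_P_POS)
        neg_draw = rng.choice(_NOMINAL_LEVELS, size=spec.n_neg, p=_NOMINAL_P_NEG)
        frame[f"nom{j}"] = pd.array(np.concatenate([pos_draw, neg_draw]), dtype="string")
    if spec.missing_rate > 0:
        mask = rng.random((n, frame.shape[1])) < spec.missing_rate
        for j, name in enumerate(frame.columns):
            col_mask = mask[:, j]
            if col_mask.all():  # keep every column imputable
                col_mask[rng.integers(n)] = False
            frame.loc[col_mask, name] = pd.NA if frame[name].dtype == "string" else np.nan
    frame["label"] = ["pos"] * spec.n_pos + ["neg"] * spec.n_neg
    return frame


def generate_synthetic(spec: SyntheticSpec) -> LabeledDataset:
    """Deterministic synthetic :class:`LabeledDataset` for a given spec/seed."""
    frame = synthetic_frame(spec)
    labels = _map_labels(frame["label"], "pos")
    work = frame.drop(columns=["label"])
    for name in work.columns:
        if work[name].dtype == "string":
            work[name] = work[name].astype(object)
    matrix, meta, names = encode_frame(work)
    return LabeledDataset(matrix, labels, meta, names)


def dataset_to_frame(data: LabeledDataset, positive_label: str = "pos",
                     negative_label: str = "neg") -> pd.DataFrame:
    """Encoded dataset as a DataFrame with a trailing ``label`` column."""
    frame = pd.DataFrame(data.features, columns=data.columns)
    frame["label"] = np.where(data.labels == 1, positive_label, negative_label)
    return frame
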