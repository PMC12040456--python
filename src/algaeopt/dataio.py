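"""Experiment-table CSV schema, feature encoding, splitting and scaling.

The long-format table has one row per (genus, treatment series, level,
replicate): three metadata columns, five factor columns and nine
response columns.  Feature encoding excludes the metadata, one-hot
encodes light colour and passes the four numeric factors through,
giving eight feature columns for the default design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic_data import RESPONSES, FactorDesign, build_design

META_COLUMNS = ("genus", "varied_factor", "replicate")
FACTOR_COLUMNS = ("co2_pct", "pH", "temperature_C", "light_intensity_lux",
                  "light_colour")
NUMERIC_FACTORS = ("co2_pct", "pH", "temperature_C", "light_intensity_lux")
CATEGORICAL_FACTORS = ("light_colour",)
RESPONSE_COLUMNS = RESPONSES
#: responses expressed as percentages of dry weight, hence bounded by 100
PERCENT_RESPONSES = ("lipid", "protein", "fibre", "ash", "moisture", "nfe")
COLUMN_ORDER = META_COLUMNS + FACTOR_COLUMNS + RESPONSE_COLUMNS


class SchemaError(ValueError):
    """Raised when a table does not conform to the experiment schema."""


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in COLUMN_ORDER if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in NUMERIC_FACTORS + RESPONSE_COLUMNS:
        if len(table) and not pd.api.types.is_numeric_dtype(table[col]):
            raise SchemaError(f"column {col!r} must be numeric")
    for col in RESPONSE_COLUMNS:
        if len(table) and (table[col] < 0).any():
            raise SchemaError(f"negative values in response column {col!r}")
    for col in PERCENT_RESPONSES:
        if len(table) and (table[col] > 100).any():
            raise SchemaError(f"percentage response {col!r} exceeds 100")


def read_experiment_csv(path) -> pd.DataFrame:
    """Read an experiment table, validating the schema.

    Comma-separated, UTF-8, '.' decimal, header required.  An empty file
    with a valid header yields an empty table.
    """
    table = pd.read_csv(path, encoding="utf-8")
    validate_table(table)
    return table[list(COLUMN_ORDER)]


def write_experiment_csv(table: pd.DataFrame, path) -> None:
    validate_table(table)
    table[list(COLUMN_ORDER)].to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# encoding and scaling


@dataclass(frozen=True)
class EncodedMatrix:
    """Numeric design matrix with provenance of every encoded column.

    ``column_map`` sends each encoded column name to its source factor,
    so indicator columns can later be pooled back into 'light_colour'.
    ``scaling_stats`` is ``(mean, scale)`` after standardization, else None.
    """

    X: np.ndarray
    columns: tuple[str, ...]
    column_map: dict
    scaling_stats: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.columns))


def encode_features(table: pd.DataFrame, design: FactorDesign | None = None) -> EncodedMatrix:
    """Encode factor columns into a numeric matrix.

    Metadata columns are excluded; numeric factors pass through in design
    order; the colour factor becomes one indicator column per level (no
    reference level is dropped, so importances can be pooled per factor).
    """
    if table.empty:
        raise ValueError("cannot encode an empty table")
    design = design or build_design()
    cols, mats, cmap = [], [], {}
    for name in NUMERIC_FACTORS:
        cols.append(name)
        mats.append(table[name].to_numpy(dtype=float)[:, None])
        cmap[name] = name
    for name in CATEGORICAL_FACTORS:
        levels = design.factor(name).levels
        unknown = set(table[name]) - set(levels)
        if unknown:
            raise ValueError(f"unknown {name} categories: {sorted(unknown)}")
        for level in levels:
            col = f"{name}={level}"
            cols.append(col)
            mats.append((table[name] == level).to_numpy(dtype=float)[:, None])
            cmap[col] = name
    return EncodedMatrix(np.hstack(mats), tuple(cols), cmap)


def standardize(matrix: EncodedMatrix, fit_stats: tuple | None = None) -> EncodedMatrix:
    """Centre to zero mean and scale to unit variance per column.

    When ``fit_stats`` is given (stats from the training matrix) it is
    applied unchanged, so test data never leaks into the scaling.
    Constant columns are centred only (scale forced to 1).
    """
    if matrix.X.size == 0:
        raise ValueError("cannot standardize an empty matrix")
    if fit_stats is None:
        mean = matrix.X.mean(axis=0)
        scale = matrix.X.std(axis=0)  # population sd, matching StandardScaler
        scale = np.where(scale == 0.0, 1.0, scale)
    else:
        mean, scale = (np.asarray(a, dtype=float) for a in fit_stats)
    return replace(matrix, X=(matrix.X - mean) / scale,
                   scaling_stats=(mean.copy(), scale.copy()))


def split(table: pd.DataFrame, train_fraction: float = 0.7, seed: int | None = None):
    """Seeded row-level shuffle split into train and test tables.

    The train partition gets round(n * fraction) rows; partitions are
    disjoint and their union is the input.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction + 0.5))
    train = table.iloc[perm[:n_train]].reset_index(drop=True)
    test = table.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test
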