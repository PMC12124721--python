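"""Descriptor table assembly, nonlinear transform expansion and min-max scaling.

The table starts from constitutional descriptors, is merged with externally
computed (DFT-derived) descriptor columns read from CSV, is expanded with the
transform family {1/x, x^2, 1/x^2, log x} applied to raw values, and is then
min-max scaled to [0,1] as the final preprocessing step.  Per-column (min, max)
records are kept so the same affine map can be applied to prediction inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import TableError

logger = logging.getLogger(__name__)

PROVENANCES = ("constitutional", "dft_ingested", "transform")

#: canonical descriptor names; QMPSA is accepted as an alias of QPSA.
ALIASES = {"QMPSA": "QPSA"}

_EPS_ZERO = 1e-12
CONSTANT_RANGE_TOL = 1e-12


@dataclass
class Transform:
    name: str
    func: Callable[[np.ndarray], np.ndarray]
    valid: Callable[[np.ndarray], bool]
    label: Callable[[str], str]


DEFAULT_TRANSFORMS: tuple[Transform, ...] = (
    Transform("inverse", lambda x: 1.0 / x,
              lambda x: bool(np.all(np.abs(x) > _EPS_ZERO)),
              lambda c: f"1/{c}"),
    Transform("square", lambda x: x ** 2,
              lambda x: True,
              lambda c: f"{c}^2"),
    Transform("inverse_square", lambda x: 1.0 / x ** 2,
              lambda x: bool(np.all(np.abs(x) > _EPS_ZERO)),
              lambda c: f"1/{c}^2"),
    Transform("log", np.log,
              lambda x: bool(np.all(x > 0)),
              lambda c: f"log({c})"),
)


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix with provenance and scaling state."""

    values: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise TableError("descriptor table contains missing values")
        for col, prov in self.provenance.items():
            if prov not in PROVENANCES:
                raise TableError(f"unknown provenance {prov!r} for column {col!r}")

    @property
    def compound_ids(self) -> list:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_scaled(self) -> bool:
        return bool(self.scaling) and set(self.scaling) >= set(self.values.columns)

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            self.values.copy(), dict(self.provenance), dict(self.scaling),
            dict(self.parents),
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "dft_ingested") -> "DescriptorTable":
        df = _read_numeric_csv(path)
        return cls(df, provenance={c: provenance for c in df.columns})


def _read_numeric_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parser: written values must read back bit-identically
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise TableError(f"{path}: need an id column plus >=1 descriptor column")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index.name = "compound_id"
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise TableError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced.astype(float)
    df = df.rename(columns=ALIASES)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableError(f"{path}: duplicate descriptor column {dup!r}")
    return df


def ingest_dft_descriptors(
    path: str | Path, base: DescriptorTable | None = None
) -> DescriptorTable:
    """Read a DFT descriptor CSV and merge it with ``base`` by compound id.

    Compounds missing from either side are dropped with a logged warning;
    ids in the CSV that do not exist in ``base`` raise ``TableError``, as do
    column-name collisions and non-numeric cells.
    """
    df = _read_numeric_csv(path)
    if base is None:
        return DescriptorTable(df, provenance={c: "dft_ingested" for c in df.columns})

    unknown = [i for i in df.index if i not in set(base.values.index)]
    if unknown:
        raise TableError(f"{path}: unknown compound id(s) {unknown!r}")
    collisions = set(df.columns) & set(base.values.columns)
    if collisions:
        raise TableError(f"{path}: column name collision(s) {sorted(collisions)!r}")

    common = [i for i in base.values.index if i in set(df.index)]
    dropped = [i for i in base.values.index if i not in set(df.index)]
    if dropped:
        logger.warning("dropping compounds lacking DFT descriptors: %s", dropped)
        warnings.warn(f"compounds dropped at assembly (missing descriptors): {dropped}")
    merged = pd.concat([base.values.loc[common], df.loc[common]], axis=1)
    provenance = dict(base.provenance)
    provenance.update({c: "dft_ingested" for c in df.columns})
    return DescriptorTable(merged, provenance=provenance, parents=dict(base.parents))


def expand_transforms(
    t: DescriptorTable, transforms: tuple[Transform, ...] = DEFAULT_TRANSFORMS
) -> DescriptorTable:
    """Add transform columns for every base column where the map is finite.

    A transform is applied only if it is valid for *all* compounds; otherwise
    it is skipped entirely and the skip is logged (never partially applied).
    """
    if t.is_scaled:
        raise TableError("expand_transforms expects an unscaled table")
    out = t.copy()
    base_cols = [c for c in t.values.columns if c not in t.parents]
    new_cols: dict[str, np.ndarray] = {}
    for col in base_cols:
        x = t.values[col].to_numpy(dtype=float)
        for tr in transforms:
            new_name = tr.label(col)
            if new_name in out.values.columns or new_name in new_cols:
                continue
            if not tr.valid(x):
                logger.info("skipping transform %s on %r (invalid domain)", tr.name, col)
                continue
            y = tr.func(x)
            if not np.all(np.isfinite(y)):
                logger.info("skipping transform %s on %r (non-finite result)", tr.name, col)
                continue
            new_cols[new_name] = y
            out.provenance[new_name] = "transform"
            out.parents[new_name] = (col, tr.name)
    if new_cols:
        out.values = pd.concat(
            [out.values, pd.DataFrame(new_cols, index=out.values.index)], axis=1
        )
    return out


def scale_minmax(t: DescriptorTable) -> DescriptorTable:
    """Min-max scale every column to [0,1], recording per-column (min, max).

    Constant columns (range < ``CONSTANT_RANGE_TOL``) are dropped with a
    warning before scaling; a constant column reaching the scaler itself is a
    defensive error.
    """
    values = t.values.copy()
    constant = [
        c for c in values.columns
        if float(values[c].max() - values[c].min()) < CONSTANT_RANGE_TOL
    ]
    if constant:
        logger.warning("dropping constant columns before scaling: %s", constant)
        warnings.warn(f"constant descriptor columns dropped: {constant}")
        values = values.drop(columns=constant)
    scaling: dict[str, tuple[float, float]] = {}
    for col in values.columns:
        lo, hi = float(values[col].min()), float(values[col].max())
        values[col] = _scale_column(values[col].to_numpy(dtype=float), lo, hi)
        scaling[col] = (lo, hi)
    provenance = {c: p for c, p in t.provenance.items() if c in values.columns}
    parents = {c: p for c, p in t.parents.items() if c in values.columns}
    return DescriptorTable(values, provenance=provenance, scaling=scaling, parents=parents)


def _scale_column(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi - lo < CONSTANT_RANGE_TOL:
        raise TableError("constant column reached the scaler")
    return (x - lo) / (hi - lo)


def apply_scaling(
    scaling: dict[str, tuple[float, float]], df: pd.DataFrame, warn: bool = True
) -> pd.DataFrame:
    """Apply stored training (min, max) records to new descriptor values.

    Out-of-range results (outside [0,1]) are allowed but flagged with a
    warning: the corresponding prediction is an extrapolation.
    """
    out = df.copy()
    for col in out.columns:
        if col not in scaling:
            raise TableError(f"no scaling record for column {col!r}")
        lo, hi = scaling[col]
        out[col] = (out[col].astype(float) - lo) / (hi - lo)
    if warn:
        mask = (out < 0) | (out > 1)
        if mask.any().any():
            where = [
                (idx, col)
                for idx in out.index
                for col in out.columns
                if bool(mask.loc[idx, col])
            ]
            warnings.warn(f"scaled inputs outside [0,1] (extrapolation): {where}")
    return out


def inverse_scaling(
    scaling: dict[str, tuple[float, float]], df: pd.DataFrame
) -> pd.DataFrame:
    """Undo :func:`apply_scaling` (exact algebraic inverse)."""
    out = df.copy()
    for col in out.columns:
        lo, hi = scaling[col]
        out[col] = out[col].astype(float) * (hi - lo) + lo
    return out
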