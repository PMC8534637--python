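"""Spectral dataset container and its CSV dialect.

A dataset is a matrix of absorbance spectra (one row per sample) on a common,
strictly increasing wavelength grid, with per-sample metadata: a purchase-day
group (``D1``..``D8`` in the default design), a meat-type covariate, and a
binary freshness label. ``"fresh"`` is the positive class throughout the
package.

The on-disk format is a single UTF-8 CSV with a header row: the four metadata
columns ``sample_id, day, meat_type, label`` followed by one column per
wavelength whose header is the wavelength in nm written as a decimal string.
The grid is therefore self-describing; no sidecar file is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    IntegrityError,
    ParseError,
    SchemaError,
)

METADATA_COLUMNS = ("sample_id", "day", "meat_type", "label")
LABEL_FRESH = "fresh"
LABEL_NONFRESH = "non-fresh"
VALID_LABELS = frozenset({LABEL_FRESH, LABEL_NONFRESH})

#: integer coding used by the classifiers: fresh (positive class) -> 1
POSITIVE_LABEL = LABEL_FRESH


@dataclass
class SpectraDataset:
    """In-memory spectral dataset.

    Attributes
    ----------
    sample_ids : array of str, unique identifiers, one per row of ``X``.
    X : float array of shape (m, n), absorbance (unitless).
    wavelengths : float array of length n, strictly increasing, in nm.
    day : array of str, group label per sample (batch / purchase day).
    meat_type : array of str, categorical covariate per sample.
    label : array of str, each ``"fresh"`` or ``"non-fresh"``.
    """

    sample_ids: np.ndarray
    X: np.ndarray
    wavelengths: np.ndarray
    day: np.ndarray
    meat_type: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.day = np.asarray(self.day, dtype=object)
        self.meat_type = np.asarray(self.meat_type, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        m, n = self.X.shape if self.X.ndim == 2 else (len(self.X), -1)
        if self.X.ndim != 2:
            raise IntegrityError("X must be a 2-D matrix (samples x wavelengths)")
        for name, arr in (
            ("sample_ids", self.sample_ids),
            ("day", self.day),
            ("meat_type", self.meat_type),
            ("label", self.label),
        ):
            if len(arr) != m:
                raise IntegrityError(
                    f"{name} has length {len(arr)} but X has {m} rows"
                )
        if len(self.wavelengths) != n:
            raise IntegrityError(
                f"wavelength grid has {len(self.wavelengths)} points "
                f"but X has {n} columns"
            )
        if not np.all(np.isfinite(self.wavelengths)):
            raise SchemaError("wavelength grid contains non-finite values")
        if n > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SchemaError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ParseError(
                f"spectral matrix contains a missing/non-finite value at "
                f"row {bad[0]}, column {bad[1]}"
            )
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise IntegrityError(f"duplicate sample_id: {dup!r}")
        bad_labels = set(map(str, self.label)) - VALID_LABELS
        if bad_labels:
            raise SchemaError(
                f"labels must be 'fresh' or 'non-fresh', got {sorted(bad_labels)}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def y(self) -> np.ndarray:
        """Integer labels: fresh (positive) -> 1, non-fresh -> 0."""
        return (self.label == LABEL_FRESH).astype(int)

    def equals(self, other: "SpectraDataset", tol: float = 1e-9) -> bool:
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.day, other.day)
            and np.array_equal(self.meat_type, other.meat_type)
            and np.array_equal(self.label, other.label)
            and np.allclose(self.wavelengths, other.wavelengths, atol=tol, rtol=0)
            and self.X.shape == other.X.shape
            and np.allclose(self.X, other.X, atol=tol, rtol=0)
        )


@dataclass
class DatasetSlice:
    """A view onto a parent dataset through an explicit index list."""

    parent: SpectraDataset
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise IntegrityError("slice indices must be unique")
        if len(idx) and (idx.min() < 0 or idx.max() >= self.parent.n_samples):
            raise IntegrityError("slice indices out of range")
        self.indices = idx

    def materialize(self) -> SpectraDataset:
        return subset(self.parent, indices=self.indices)


def read_dataset(path: str | Path) -> SpectraDataset:
    """Read a dataset from the package CSV dialect.

    Raises
    ------
    SchemaError
        if a metadata column is missing or a wavelength header is not a
        finite decimal number (or the grid is not strictly increasing;
        non-monotone grids are rejected rather than silently sorted).
    ParseError
        if a spectral cell is blank or non-numeric; the message names the
        offending row (by sample_id) and column (by wavelength header).
    IntegrityError
        on duplicate sample ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")
    wl_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not wl_cols:
        raise SchemaError("no wavelength columns found after metadata columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SchemaError(f"wavelength header not parseable as float: {exc}") from exc

    m = len(df)
    X = np.empty((m, len(wl_cols)))
    for j, col in enumerate(wl_cols):
        # python float() is correctly rounded (pandas' fast parser is not),
        # which the byte-exact round-trip guarantee relies on
        for i, cell in enumerate(df[col].to_numpy()):
            try:
                X[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric or blank spectral cell at row {i} "
                    f"(sample_id={df['sample_id'].iloc[i]!r}), column {col!r}"
                ) from None
        if not np.all(np.isfinite(X[:, j])):
            i = int(np.flatnonzero(~np.isfinite(X[:, j]))[0])
            raise ParseError(
                f"non-finite spectral cell at row {i} "
                f"(sample_id={df['sample_id'].iloc[i]!r}), column {col!r}"
            )

    return SpectraDataset(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        X=X,
        wavelengths=wavelengths,
        day=df["day"].to_numpy(dtype=object),
        meat_type=df["meat_type"].to_numpy(dtype=object),
        label=df["label"].to_numpy(dtype=object),
    )


def write_dataset(dataset: SpectraDataset, path: str | Path) -> Path:
    """Write a dataset to the package CSV dialect.

    Floats are written with Python's shortest round-trip repr, so
    ``read_dataset(write_dataset(d))`` reproduces ``d`` exactly and a second
    write is byte-identical to the first.
    """
    if dataset.n_samples == 0:
        raise SchemaError("refusing to write a dataset with no samples (labels required)")
    path = Path(path)
    cols: dict[str, object] = {
        "sample_id": dataset.sample_ids,
        "day": dataset.day,
        "meat_type": dataset.meat_type,
        "label": dataset.label,
    }
    frame = pd.DataFrame(cols)
    spectra = pd.DataFrame(
        dataset.X, columns=[repr(float(w)) for w in dataset.wavelengths]
    )
    pd.concat([frame, spectra], axis=1).to_csv(path, index=False)
    return path


def subset(
    dataset: SpectraDataset,
    indices: Sequence[int] | np.ndarray | None = None,
    where: Callable[[dict], bool] | None = None,
) -> SpectraDataset:
    """Select rows by explicit indices or by a predicate on metadata.

    The predicate receives one dict per sample with keys ``sample_id``,
    ``day``, ``meat_type``, ``label``. Original row order is preserved;
    metadata rows always travel with their own spectra.
    """
    if (indices is None) == (where is None):
        raise ValueError("provide exactly one of `indices` or `where`")
    if where is not None:
        records = (
            {
                "sample_id": dataset.sample_ids[i],
                "day": dataset.day[i],
                "meat_type": dataset.meat_type[i],
                "label": dataset.label[i],
            }
            for i in range(dataset.n_samples)
        )
        idx = np.array([i for i, rec in enumerate(records) if where(rec)], dtype=int)
    else:
        idx = np.asarray(indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise IntegrityError("subset indices must be unique")
        if len(idx) and (idx.min() < 0 or idx.max() >= dataset.n_samples):
            raise IntegrityError("subset indices out of range")
    if idx.size == 0:
        raise EmptySelectionError("selection matched no samples")
    return SpectraDataset(
        sample_ids=dataset.sample_ids[idx],
        X=dataset.X[idx],
        wavelengths=dataset.wavelengths,
        day=dataset.day[idx],
        meat_type=dataset.meat_type[idx],
        label=dataset.label[idx],
    )
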