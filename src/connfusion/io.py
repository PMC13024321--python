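"""Core data types, manifest IO, Pearson connectivity, and triangle packing.

A dataset is described by a tab-separated *manifest* (columns ``subject_id``,
``label``, ``site``, ``path``) pointing at per-subject delimited-text
matrices of shape ``T x R`` (time points x ROIs).  Labels may be the strings
``ASD``/``TD`` or the integers ``1``/``0`` (1 = case, 0 = control).

Functional connectivity is the Pearson correlation matrix between ROI
columns; models consume its strict upper triangle flattened row-major
(``(0,1), (0,2), ..., (0,R-1), (1,2), ...``).  That ordering is a package-wide
convention so that edge index <-> ROI pair mappings are deterministic across
the encoders and the interpretability module.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["subject_id", "label", "site", "path"]
_LABEL_TOKENS = {"ASD": 1, "TD": 0, "1": 1, "0": 0}


class SchemaError(ValueError):
    """Manifest file does not have the expected columns."""


class ValidationError(ValueError):
    """Data violates an invariant (duplicate ids, bad label, asymmetry...)."""


class DegenerateInputError(ValueError):
    """Input is numerically unusable (e.g. zero-variance ROI)."""


def _column_stds_degenerate(series: np.ndarray) -> np.ndarray:
    """Zero-variance test with a scale-aware tolerance (a constant nonzero
    column has std ~ 1e-16 * |mean| from float cancellation, not exactly 0)."""
    std = series.std(axis=0)
    scale = np.maximum(1.0, np.abs(series.mean(axis=0)))
    return std <= 1e-12 * scale


@dataclass
class SubjectRecord:
    """One subject: a ``T x R`` BOLD ROI time-series matrix plus metadata."""

    subject_id: str
    label: int          # 0 = control (TD), 1 = case (ASD)
    site: str
    series: np.ndarray

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValidationError(f"{self.subject_id}: series must be 2-D")
        T, R = self.series.shape
        if T < 3 or R < 2:
            raise ValidationError(f"{self.subject_id}: need T >= 3 and R >= 2, got {T}x{R}")
        if not np.all(np.isfinite(self.series)):
            raise ValidationError(f"{self.subject_id}: series contains NaN/Inf")
        if np.any(_column_stds_degenerate(self.series)):
            raise DegenerateInputError(
                f"{self.subject_id}: zero-variance ROI column (failed QC)")
        if self.label not in (0, 1):
            raise ValidationError(f"{self.subject_id}: label must be 0 or 1")

    @property
    def T(self) -> int:
        return self.series.shape[0]

    @property
    def R(self) -> int:
        return self.series.shape[1]


@dataclass
class DatasetManifest:
    """Index of a dataset: (subject_id, label, site, path) rows + ROI count."""

    records: list  # list of dicts with keys subject_id/label/site/path
    atlas_R: int = 0

    def __post_init__(self):
        ids = [r["subject_id"] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        labels = {r["label"] for r in self.records}
        if self.records and labels != {0, 1}:
            raise ValidationError("both labels (0 and 1) must be present")

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r["label"] for r in self.records])

    @property
    def sites(self) -> list:
        return [r["site"] for r in self.records]

    def subset(self, indices: Sequence[int]) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices], self.atlas_R)


def parse_label(token) -> int:
    token = str(token).strip()
    if token not in _LABEL_TOKENS:
        raise ValidationError(f"unknown label token {token!r} (expected ASD/TD/1/0)")
    return _LABEL_TOKENS[token]


def load_manifest(path) -> DatasetManifest:
    """Read and validate a TSV manifest; labels are parsed to {0, 1}."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append({
            "subject_id": str(row.subject_id),
            "label": parse_label(row.label),
            "site": str(row.site),
            "path": str(row.path),
        })
    return DatasetManifest(records)


def save_manifest(manifest: DatasetManifest, path) -> None:
    rows = [{"subject_id": r["subject_id"], "label": r["label"],
             "site": r["site"], "path": r["path"]} for r in manifest.records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_series(path) -> np.ndarray:
    """Read a T x R numeric matrix from delimited text (TSV/CSV, no header)."""
    path = str(path)
    delim = "," if path.endswith(".csv") else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def write_series(series: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(series), delimiter="\t", fmt="%.8g")


def load_records(manifest: DatasetManifest, root=None, archive=None,
                 skip_failed_qc: bool = True) -> list:
    """Materialise :class:`SubjectRecord` objects for a manifest.

    Subjects failing quality control (zero-variance ROI, non-finite values)
    are excluded and logged, mirroring the usual cohort-cleaning step, unless
    ``skip_failed_qc`` is False in which case the error propagates.  When
    ``archive`` (an open ``h5py.File``-like mapping keyed by subject_id) is
    given it takes precedence over per-subject text files.
    """
    out = []
    for rec in manifest.records:
        if archive is not None:
            series = np.asarray(archive[rec["subject_id"]])
        else:
            p = rec["path"]
            if root is not None and not os.path.isabs(p):
                p = os.path.join(root, p)
            series = read_series(p)
        try:
            out.append(SubjectRecord(rec["subject_id"], rec["label"], rec["site"], series))
        except (ValidationError, DegenerateInputError) as exc:
            if not skip_failed_qc:
                raise
            logger.warning("QC rejection of subject %s: %s", rec["subject_id"], exc)
    return out


# ---------------------------------------------------------------------------
# Pearson connectivity
# ---------------------------------------------------------------------------

def compute_pcc(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between ROI columns of a ``T x R`` series.

    Raises :class:`DegenerateInputError` on zero-variance columns rather than
    silently producing NaN.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValidationError("series must be T x R with T >= 3")
    if np.any(_column_stds_degenerate(series)):
        raise DegenerateInputError("zero-variance ROI column: correlation undefined")
    pcc = np.corrcoef(series, rowvar=False)
    np.fill_diagonal(pcc, 1.0)
    return np.clip(pcc, -1.0, 1.0)


@dataclass
class ConnectivityVector:
    """Flattened strict upper triangle of a correlation matrix."""

    values: np.ndarray
    R: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        D = self.R * (self.R - 1) // 2
        if self.values.shape != (D,):
            raise ValidationError(f"expected length {D} for R={self.R}")

    @property
    def D(self) -> int:
        return self.values.size


def n_rois_for_length(D: int) -> int:
    """Invert D = R(R-1)/2; raises if no integer solution exists."""
    R = int(round((1 + math.isqrt(1 + 8 * D)) / 2))
    if R * (R - 1) // 2 != D:
        raise ValidationError(f"length {D} is not R(R-1)/2 for any integer R")
    return R


def upper_indices(R: int):
    """Row/col indices of the strict upper triangle in the package ordering."""
    return np.triu_indices(R, k=1)


def flatten_upper(matrix: np.ndarray, tol: float = 1e-6) -> ConnectivityVector:
    """Extract the strict upper triangle row-major (i<j, i then j ascending)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("matrix must be square")
    if np.max(np.abs(matrix - matrix.T)) > tol:
        raise ValidationError(f"matrix asymmetric beyond tolerance {tol}")
    R = matrix.shape[0]
    iu = upper_indices(R)
    return ConnectivityVector(matrix[iu], R)


def unflatten_upper(vec) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from a packed vector."""
    if isinstance(vec, ConnectivityVector):
        values, R = vec.values, vec.R
    else:
        values = np.asarray(vec, dtype=float)
        R = n_rois_for_length(values.size)
    mat = np.eye(R)
    iu = upper_indices(R)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return mat


def stack_dataset(records: Sequence[SubjectRecord]):
    """Stack records into arrays: series (n,T,R), pcc vectors (n,D), y, sites."""
    X = np.stack([r.series for r in records])
    P = np.stack([flatten_upper(compute_pcc(r.series)).values for r in records])
    y = np.array([r.label for r in records])
    sites = np.array([r.site for r in records])
    return X, P, y, sites
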