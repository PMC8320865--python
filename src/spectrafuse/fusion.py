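"""Mid-level sensor fusion: per-column max normalization + concatenation.

Each sensor's selected-wavelength matrix is normalized column-by-column by
the maximum value of that column over the *calibration* rows, and the two
normalized blocks are concatenated sample-wise.  The stored calibration
maxima are reapplied unchanged to prediction rows, which may therefore
exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SpectralDataset

__all__ = ["FusedDataset", "column_max_normalize_fit",
           "column_max_normalize_apply", "concatenate_blocks"]

_MAX_TOL = 1e-12


def column_max_normalize_fit(X_cal: np.ndarray) -> np.ndarray:
    """Per-column calibration maxima (the normalization divisors).

    The literal signed maximum is used; a maximum at or below zero means
    the column cannot carry this normalization and is an error.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    norms = X_cal.max(axis=0)
    if np.any(norms <= _MAX_TOL):
        bad = np.flatnonzero(norms <= _MAX_TOL)
        raise ValueError(
            f"column maximum not positive at columns {bad[:10].tolist()}; "
            "cannot column-max normalize")
    return norms


def column_max_normalize_apply(X: np.ndarray, column_norms: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    column_norms = np.asarray(column_norms, dtype=float)
    if column_norms.shape != (X.shape[1],):
        raise ValueError("column_norms length must match column count")
    return X / column_norms


@dataclass
class FusedDataset:
    """Row-aligned concatenation of two normalized sensor blocks."""

    matrix: np.ndarray
    block_boundary: int           # first column of the second sensor block
    column_norms: np.ndarray      # calibration maxima, per column
    sensor_tags: np.ndarray       # per-column provenance
    wavelengths: np.ndarray       # per-column nm
    sample_ids: np.ndarray
    lc: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        """CSV with a two-row header: sensor tag row, wavelength row."""
        path = Path(path)
        header1 = ",".join(["sample_id", "lc"] + [str(t) for t in self.sensor_tags])
        header2 = ",".join(["", ""] + [f"{w:.2f}" for w in self.wavelengths])
        body = pd.DataFrame(self.matrix)
        body.insert(0, "lc", self.lc)
        body.insert(0, "sample_id", self.sample_ids)
        with open(path, "w") as fh:
            fh.write(header1 + "\n" + header2 + "\n")
            body.to_csv(fh, index=False, header=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FusedDataset":
        path = Path(path)
        with open(path) as fh:
            tags = fh.readline().rstrip("\n").split(",")[2:]
            wls = [float(w) for w in fh.readline().rstrip("\n").split(",")[2:]]
            body = pd.read_csv(fh, header=None)
        tags_arr = np.array(tags)
        boundary = int(np.argmax(tags_arr != tags_arr[0])) if len(set(tags)) > 1 \
            else len(tags)
        return cls(
            matrix=body.iloc[:, 2:].to_numpy(float),
            block_boundary=boundary,
            column_norms=np.ones(len(tags)),
            sensor_tags=tags_arr,
            wavelengths=np.array(wls),
            sample_ids=body.iloc[:, 0].to_numpy(),
            lc=body.iloc[:, 1].to_numpy(float),
        )


def concatenate_blocks(a: SpectralDataset, b: SpectralDataset,
                       column_norms: np.ndarray | None = None) -> FusedDataset:
    """Concatenate two sensors' matrices sample-wise, aligning rows by id.

    ``b`` is reordered to ``a``'s sample order when the id sets match but
    the order differs; a genuine id mismatch is an error.  Pass
    ``column_norms`` (from :func:`column_max_normalize_fit` on the fused
    calibration matrix) to record the normalization provenance.
    """
    if b.n_samples and a.n_samples != b.n_samples:
        raise ValueError("sensor blocks cover different sample counts")
    if b.n_samples:
        if not np.array_equal(a.sample_ids, b.sample_ids):
            order = {sid: i for i, sid in enumerate(b.sample_ids)}
            try:
                perm = np.array([order[sid] for sid in a.sample_ids])
            except KeyError as exc:
                raise ValueError(f"sample id {exc} missing from second sensor")
            b = b.take_samples(perm)
        matrix = np.hstack([a.X, b.X])
        tags = np.array([a.sensor] * a.n_wavelengths + [b.sensor] * b.n_wavelengths)
        wl = np.concatenate([a.wavelengths, b.wavelengths])
    else:
        matrix = a.X.copy()
        tags = np.array([a.sensor] * a.n_wavelengths)
        wl = a.wavelengths.copy()
    if column_norms is None:
        column_norms = np.ones(matrix.shape[1])
    return FusedDataset(
        matrix=matrix,
        block_boundary=a.n_wavelengths,
        column_norms=np.asarray(column_norms, dtype=float),
        sensor_tags=tags,
        wavelengths=wl,
        sample_ids=a.sample_ids.copy(),
        lc=a.lc.copy(),
    )
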