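"""In-memory containers for spectral data and hyperspectral line-scan cubes.

A :class:`SpectralDataset` is the unit that flows through the pipeline:
a samples x wavelengths matrix with a strictly increasing wavelength axis
(nm), per-sample reference values (primordial leaf count, LC) and sample
identifiers, tagged with the originating sensor.

A :class:`LineScanCube` holds one tuber's stack of hyperspectral line-scan
frames together with the background and reference (Teflon) frames needed
for radiometric correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "LineScanCube"]


@dataclass
class SpectralDataset:
    """Matrix of spectra with wavelength axis, sensor tag and LC values."""

    X: np.ndarray  # (n_samples, n_wavelengths)
    wavelengths: np.ndarray  # (n_wavelengths,) nm, strictly increasing
    lc: np.ndarray  # (n_samples,) reference leaf counts
    sample_ids: np.ndarray  # (n_samples,)
    sensor: str = "sensor"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.lc = np.asarray(self.lc, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavelengths)")
        n, k = self.X.shape
        if self.wavelengths.shape != (k,):
            raise ValueError("wavelength axis length does not match X columns")
        if k > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.lc.shape != (n,) or self.sample_ids.shape != (n,):
            raise ValueError("lc / sample_ids length does not match X rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def take_samples(self, idx: np.ndarray) -> "SpectralDataset":
        """Row subset (e.g. a calibration/prediction split)."""
        return SpectralDataset(
            self.X[idx], self.wavelengths, self.lc[idx],
            self.sample_ids[idx], self.sensor,
        )

    def take_columns(self, idx: np.ndarray) -> "SpectralDataset":
        """Column subset, e.g. IPLS-selected wavelengths (sorted order kept)."""
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            self.X[:, idx], self.wavelengths[idx], self.lc,
            self.sample_ids, self.sensor,
        )

    # --- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """CSV layout: sample_id, lc, then one column per wavelength (2 dp)."""
        cols = [f"{w:.2f}" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "lc", self.lc)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sensor: str = "sensor") -> "SpectralDataset":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["sample_id", "lc"]:
            raise ValueError("expected leading columns 'sample_id', 'lc'")
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(df.iloc[:, 2:].to_numpy(float), wl,
                   df["lc"].to_numpy(float), df["sample_id"].to_numpy(), sensor)

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path, X=self.X, wavelengths=self.wavelengths, lc=self.lc,
            sample_ids=self.sample_ids.astype(str), sensor=np.array(self.sensor),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "SpectralDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["X"], z["wavelengths"], z["lc"], z["sample_ids"],
                       str(z["sensor"]))


@dataclass
class LineScanCube:
    """One sample's line-scan stack plus background and reference frames.

    ``frames`` has shape (n_scan_lines, line_length, n_bands); the
    background and reference stacks share that shape class (they may have a
    different number of lines but the same pixel/band geometry).
    """

    frames: np.ndarray
    background_frames: np.ndarray
    reference_frames: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.background_frames = np.asarray(self.background_frames, dtype=float)
        self.reference_frames = np.asarray(self.reference_frames, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name, a in (("frames", self.frames),
                        ("background_frames", self.background_frames),
                        ("reference_frames", self.reference_frames)):
            if a.ndim != 3:
                raise ValueError(f"{name} must be 3-D (lines x pixels x bands)")
            if a.shape[0] < 1:
                raise ValueError(f"{name} needs at least one scan line")
            if a.shape[2] != self.wavelengths.size:
                raise ValueError(f"{name} spectral dim does not match wavelengths")

    # Band-sequential binary + JSON sidecar; text-free formats are only
    # written to caller-chosen output directories, never shipped.
    def to_bsq(self, path: str | Path) -> None:
        path = Path(path)
        stacked = np.concatenate(
            [self.frames, self.background_frames, self.reference_frames], axis=0
        ).astype(np.float32)
        # band-sequential: (band, line, pixel)
        np.transpose(stacked, (2, 0, 1)).tofile(path)
        sidecar = {
            "dims": {
                "n_sample_lines": int(self.frames.shape[0]),
                "n_background_lines": int(self.background_frames.shape[0]),
                "n_reference_lines": int(self.reference_frames.shape[0]),
                "line_length": int(self.frames.shape[1]),
                "n_bands": int(self.frames.shape[2]),
            },
            "dtype": "float32",
            "interleave": "bsq",
            "wavelengths_nm": [float(w) for w in self.wavelengths],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def from_bsq(cls, path: str | Path) -> "LineScanCube":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        d = meta["dims"]
        n_lines = d["n_sample_lines"] + d["n_background_lines"] + d["n_reference_lines"]
        raw = np.fromfile(path, dtype=np.float32).reshape(
            d["n_bands"], n_lines, d["line_length"])
        stacked = np.transpose(raw, (1, 2, 0)).astype(float)
        i0 = d["n_sample_lines"]
        i1 = i0 + d["n_background_lines"]
        return cls(stacked[:i0], stacked[i0:i1], stacked[i1:],
                   np.array(meta["wavelengths_nm"], dtype=float))
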