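"""Radiometric normalization: raw intensities to relative spectra.

Interactance spectra are ratioed against a Teflon reference after dark
subtraction; hyperspectral cubes are first averaged over the spatial
coordinates and the same background-corrected ratio is then applied to the
average spectra (mean-then-ratio, not ratio-then-mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LineScanCube

__all__ = [
    "RawIntensityRecord", "DegenerateDenominatorError",
    "relative_interactance", "mean_cube_spectrum", "relative_reflectance",
]

#: relative tolerance below which a reference-minus-background denominator
#: is treated as degenerate (silent clamping would corrupt calibration)
DENOM_RTOL = 1e-9


class DegenerateDenominatorError(ValueError):
    """Reference and background intensities coincide at some wavelengths."""

    def __init__(self, wavelengths: np.ndarray):
        self.wavelengths = np.asarray(wavelengths)
        wl = ", ".join(f"{w:g}" for w in self.wavelengths[:10])
        more = "" if self.wavelengths.size <= 10 else ", ..."
        super().__init__(
            f"reference minus background is degenerate at {self.wavelengths.size} "
            f"wavelength(s): {wl}{more} nm")


@dataclass
class RawIntensityRecord:
    """One tuber's raw sample/reference/background intensity vectors."""

    I_s: np.ndarray
    I_r: np.ndarray
    I_d: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.I_s = np.asarray(self.I_s, dtype=float)
        self.I_r = np.asarray(self.I_r, dtype=float)
        self.I_d = np.asarray(self.I_d, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        k = self.wavelengths.size
        if not (self.I_s.shape == self.I_r.shape == self.I_d.shape == (k,)):
            raise ValueError("intensity vectors must share the wavelength axis")
        if k > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


def _safe_ratio(num: np.ndarray, den: np.ndarray, wavelengths: np.ndarray,
                ref: np.ndarray) -> np.ndarray:
    tol = DENOM_RTOL * max(np.max(np.abs(ref)), 1.0)
    bad = np.abs(den) <= tol
    if np.any(bad):
        raise DegenerateDenominatorError(wavelengths[bad])
    return num / den


def relative_interactance(rec: RawIntensityRecord) -> np.ndarray:
    """(I_s - I_d) / (I_r - I_d) elementwise.

    Raises :class:`DegenerateDenominatorError` naming the offending
    wavelengths when the reference and background coincide anywhere.
    """
    return _safe_ratio(rec.I_s - rec.I_d, rec.I_r - rec.I_d,
                       rec.wavelengths, rec.I_r)


def mean_cube_spectrum(cube: LineScanCube) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average spectra (AS_s, AS_b, AS_r) over all spatial positions."""
    if cube.frames.shape[0] * cube.frames.shape[1] == 0:
        raise ValueError("empty cube")
    as_s = cube.frames.mean(axis=(0, 1))
    as_b = cube.background_frames.mean(axis=(0, 1))
    as_r = cube.reference_frames.mean(axis=(0, 1))
    return as_s, as_b, as_r


def relative_reflectance(as_s: np.ndarray, as_b: np.ndarray, as_r: np.ndarray,
                         wavelengths: np.ndarray | None = None) -> np.ndarray:
    """RR = (AS_s - AS_b) / (AS_r - AS_b) elementwise."""
    as_s = np.asarray(as_s, dtype=float)
    as_b = np.asarray(as_b, dtype=float)
    as_r = np.asarray(as_r, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(as_s.size, dtype=float)
    return _safe_ratio(as_s - as_b, as_r - as_b, np.asarray(wavelengths), as_r)
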