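"""Two-stage spectral preprocessing grid and reference-value transforms.

The grid enumerates 7 first-stage codes (A0 none, A1/A2 Savitzky-Golay
first/second derivative, A3 unit-norm row normalization, A4 SNV, A5 MSC,
A6 median center), 3 second-stage codes (B1 mean center, B2 MSC, B3
orthogonal signal correction) and 3 reference transforms (C0 none, C1
log10, C2 power), i.e. 63 recipes.  Every stateful step is fitted on the
calibration split only and the stored statistics are reapplied unchanged
to prediction data — the no-leakage contract the cross-validated model
search depends on.

Row-wise scatter corrections (SNV, unit-norm) act on whole rows;
MSC references and derivative windows respect sensor block boundaries,
because scatter and band structure are per-instrument properties.
Derivatives on wavelength-selected data are computed within contiguous
runs of selected channel indices; runs shorter than the filter window pass
through unchanged (with a warning) rather than being extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "STAGE1_CODES", "STAGE2_CODES", "REF_CODES", "ColumnBlock",
    "PreprocessingRecipe", "all_recipes",
    "sg_derivative", "snv", "msc_fit_reference", "msc", "normalize_rows",
    "center_fit", "center_apply", "OSCModel", "osc_fit", "osc_apply",
    "transform_reference", "inverse_transform_reference",
]

STAGE1_CODES = ("A0", "A1", "A2", "A3", "A4", "A5", "A6")
STAGE2_CODES = ("B1", "B2", "B3")
REF_CODES = ("C0", "C1", "C2")

_FLAT_ROW_TOL = 1e-12


@dataclass(frozen=True)
class ColumnBlock:
    """A sensor block inside a (possibly fused) matrix.

    ``columns`` are positions in the matrix being preprocessed;
    ``source_indices`` are the original channel indices within the sensor,
    used to find contiguous runs after wavelength selection.
    """
    columns: np.ndarray
    source_indices: np.ndarray

    def runs(self) -> list[np.ndarray]:
        """Matrix-column runs whose source indices are contiguous."""
        if self.columns.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.source_indices) != 1) + 1
        return np.split(np.asarray(self.columns), breaks)


def _whole_block(n_cols: int) -> list[ColumnBlock]:
    idx = np.arange(n_cols)
    return [ColumnBlock(idx, idx)]


# ---------------------------------------------------------------------------
# Row-wise transforms
# ---------------------------------------------------------------------------

def sg_derivative(X: np.ndarray, order: int, window: int = 7,
                  polyorder: int = 2,
                  runs: list[np.ndarray] | None = None) -> np.ndarray:
    """Savitzky-Golay smoothed derivative per row, within contiguous runs.

    Channel spacing is treated as a uniform unit grid within each run.
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if order > polyorder:
        raise ValueError("derivative order must not exceed polyorder")
    if runs is None:
        runs = [np.arange(X.shape[1])]
    out = X.copy()
    for run in runs:
        if run.size == 0:
            continue
        if run.size < window:
            warnings.warn(
                f"run of {run.size} selected channels shorter than the "
                f"Savitzky-Golay window ({window}); passed through unchanged",
                stacklevel=2)
            continue
        out[:, run] = savgol_filter(X[:, run], window_length=window,
                                    polyorder=polyorder, deriv=order,
                                    delta=1.0, axis=1, mode="interp")
    return out


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, SD 1."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd <= _FLAT_ROW_TOL):
        raise ValueError("SNV undefined for zero-variance rows")
    return (X - mu) / sd


def normalize_rows(X: np.ndarray) -> np.ndarray:
    """Divide each row by its Euclidean norm."""
    X = np.asarray(X, dtype=float)
    nrm = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(nrm <= _FLAT_ROW_TOL):
        raise ValueError("cannot normalize zero rows")
    return X / nrm


def msc_fit_reference(X_cal: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the mean calibration spectrum."""
    return np.asarray(X_cal, dtype=float).mean(axis=0)


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a stored reference.

    Per row i the affine fit x_i ~ a_i + b_i * ref is inverted:
    output (x_i - a_i) / b_i.
    """
    X = np.asarray(X, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length must match row length")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom <= _FLAT_ROW_TOL:
        raise ValueError("MSC reference spectrum is flat")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) <= 1e-10):
        raise ValueError("MSC gain near zero for a spectrally flat row")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# Column-wise (fitted) transforms
# ---------------------------------------------------------------------------

def center_fit(X_cal: np.ndarray, statistic: str = "mean") -> np.ndarray:
    """Column center vector (mean or median) from calibration data."""
    X_cal = np.asarray(X_cal, dtype=float)
    if statistic == "mean":
        return X_cal.mean(axis=0)
    if statistic == "median":
        return np.median(X_cal, axis=0)
    raise ValueError(f"unknown centering statistic {statistic!r}")


def center_apply(X: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) - np.asarray(center, dtype=float)


# ---------------------------------------------------------------------------
# Orthogonal signal correction (classic Wold)
# ---------------------------------------------------------------------------

@dataclass
class OSCModel:
    weights: np.ndarray   # (k, ncomp)
    loadings: np.ndarray  # (k, ncomp)
    scores: np.ndarray    # (n_cal, ncomp), orthogonalized against y


def osc_fit(Xc: np.ndarray, y: np.ndarray, ncomp: int = 1,
            max_iter: int = 50, tol: float = 1e-12) -> OSCModel:
    """Fit OSC on centered calibration data.

    Each component starts from the dominant principal score, is
    orthogonalized against the response, projected back onto the spectra to
    obtain weights, and iterated to convergence; the deflating score is
    exactly y-orthogonal by construction.
    """
    Xd = np.array(Xc, dtype=float)
    y = np.asarray(y, dtype=float)
    if ncomp < 0:
        raise ValueError("ncomp must be >= 0")
    if ncomp >= np.linalg.matrix_rank(Xd) and ncomp > 0:
        raise ValueError("osc_ncomp must be below the rank of X")
    yy = y @ y
    W, P, T = [], [], []
    for _ in range(ncomp):
        # dominant PC score as the starting point
        u, s, vt = np.linalg.svd(Xd, full_matrices=False)
        t = u[:, 0] * s[0]
        w = vt[0]
        for _ in range(max_iter):
            t_orth = t - y * (y @ t) / yy
            w, *_ = np.linalg.lstsq(Xd, t_orth, rcond=None)
            w = w / np.linalg.norm(w)
            t_new = Xd @ w
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        t = t - y * (y @ t) / yy  # exact orthogonality for the deflation
        tt = t @ t
        if tt <= _FLAT_ROW_TOL:
            raise ValueError("OSC component degenerate (no y-orthogonal variance)")
        p = Xd.T @ t / tt
        Xd -= np.outer(t, p)
        W.append(w)
        P.append(p)
        T.append(t)
    k = Xc.shape[1]
    return OSCModel(
        weights=np.column_stack(W) if W else np.empty((k, 0)),
        loadings=np.column_stack(P) if P else np.empty((k, 0)),
        scores=np.column_stack(T) if T else np.empty((Xc.shape[0], 0)),
    )


def osc_apply(model: OSCModel, Xc: np.ndarray) -> np.ndarray:
    """Deflate new (already centered) data with the stored weights/loadings."""
    Xd = np.array(Xc, dtype=float)
    for j in range(model.weights.shape[1]):
        t = Xd @ model.weights[:, j]
        Xd -= np.outer(t, model.loadings[:, j])
    return Xd


# ---------------------------------------------------------------------------
# Reference transforms
# ---------------------------------------------------------------------------

def transform_reference(y: np.ndarray, code: str,
                        power_exponent: float = 0.5) -> np.ndarray:
    """C0 identity, C1 log10, C2 power (default exponent 0.5)."""
    y = np.asarray(y, dtype=float)
    if code == "C0":
        return y.copy()
    if code == "C1":
        if np.any(y <= 0):
            raise ValueError("log10 reference transform requires positive values")
        return np.log10(y)
    if code == "C2":
        if power_exponent < 1 and np.any(y < 0):
            raise ValueError("fractional power transform requires non-negative values")
        return np.power(y, power_exponent)
    raise ValueError(f"unknown reference transform {code!r}")


def inverse_transform_reference(y_t: np.ndarray, code: str,
                                power_exponent: float = 0.5) -> np.ndarray:
    """Exact inverse of :func:`transform_reference` on valid ranges.

    Model predictions on a fractional-power scale may dip below zero; they
    are clipped at zero before inversion, which is the monotone completion
    of the inverse.
    """
    y_t = np.asarray(y_t, dtype=float)
    if code == "C0":
        return y_t.copy()
    if code == "C1":
        return np.power(10.0, y_t)
    if code == "C2":
        inv = 1.0 / power_exponent
        if inv < 1 and np.any(y_t < 0):
            raise ValueError("cannot invert the power transform on negative values")
        base = np.clip(y_t, 0.0, None) if inv >= 1 else y_t
        return np.power(base, inv)
    raise ValueError(f"unknown reference transform {code!r}")


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

@dataclass
class PreprocessingRecipe:
    """A (stage1, stage2; reference) preprocessing triple with fitted stats.

    ``fit`` consumes calibration spectra (and the transformed reference for
    OSC); ``transform`` replays the stored statistics on any data.
    """

    stage1: str
    stage2: str
    ref_transform: str
    sg_window: int = 7
    sg_polyorder: int = 2
    osc_ncomp: int = 1
    power_exponent: float = 0.5
    fitted_stats: dict | None = field(default=None, repr=False)
    _blocks: list[ColumnBlock] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stage1 not in STAGE1_CODES:
            raise ValueError(f"unknown stage-1 code {self.stage1!r}")
        if self.stage2 not in STAGE2_CODES:
            raise ValueError(f"unknown stage-2 code {self.stage2!r}")
        if self.ref_transform not in REF_CODES:
            raise ValueError(f"unknown reference code {self.ref_transform!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")

    @property
    def code(self) -> str:
        """Serialized label, e.g. ``\"A5,B2;C2\"``."""
        return f"{self.stage1},{self.stage2};{self.ref_transform}"

    @classmethod
    def from_code(cls, code: str, **kwargs) -> "PreprocessingRecipe":
        stages, _, ref = code.partition(";")
        s1, _, s2 = stages.partition(",")
        return cls(s1.strip(), s2.strip(), ref.strip() or "C0", **kwargs)

    # -- stage application ------------------------------------------------

    def _stage1(self, X: np.ndarray, blocks: list[ColumnBlock],
                fit: bool) -> np.ndarray:
        s = self.stage1
        if s == "A0":
            return np.asarray(X, dtype=float).copy()
        if s in ("A1", "A2"):
            runs = [r for b in blocks for r in b.runs()]
            return sg_derivative(X, order=1 if s == "A1" else 2,
                                 window=self.sg_window,
                                 polyorder=self.sg_polyorder, runs=runs)
        if s == "A3":
            return normalize_rows(X)
        if s == "A4":
            return snv(X)
        if s == "A5":
            out = np.asarray(X, dtype=float).copy()
            if fit:
                self.fitted_stats["msc_ref_stage1"] = [
                    msc_fit_reference(X[:, b.columns]) for b in blocks]
            for b, ref in zip(blocks, self.fitted_stats["msc_ref_stage1"]):
                out[:, b.columns] = msc(X[:, b.columns], ref)
            return out
        if s == "A6":
            if fit:
                self.fitted_stats["median_center"] = center_fit(X, "median")
            return center_apply(X, self.fitted_stats["median_center"])
        raise AssertionError(s)

    def _stage2(self, X1: np.ndarray, blocks: list[ColumnBlock],
                fit: bool, y_t: np.ndarray | None) -> np.ndarray:
        s = self.stage2
        if s == "B1":
            if fit:
                self.fitted_stats["mean_center"] = center_fit(X1, "mean")
            return center_apply(X1, self.fitted_stats["mean_center"])
        if s == "B2":
            out = X1.copy()
            if fit:
                self.fitted_stats["msc_ref_stage2"] = [
                    msc_fit_reference(X1[:, b.columns]) for b in blocks]
            for b, ref in zip(blocks, self.fitted_stats["msc_ref_stage2"]):
                out[:, b.columns] = msc(X1[:, b.columns], ref)
            return out
        if s == "B3":
            if fit:
                if y_t is None:
                    raise ValueError("OSC stage requires the reference vector at fit")
                mu = center_fit(X1, "mean")
                yc = y_t - y_t.mean()
                model = osc_fit(center_apply(X1, mu), yc, self.osc_ncomp)
                self.fitted_stats["osc_center"] = mu
                self.fitted_stats["osc"] = model
            return osc_apply(self.fitted_stats["osc"],
                             center_apply(X1, self.fitted_stats["osc_center"]))
        raise AssertionError(s)

    # -- public API -------------------------------------------------------

    def fit(self, X_cal: np.ndarray, y_cal_transformed: np.ndarray | None = None,
            blocks: list[ColumnBlock] | None = None) -> "PreprocessingRecipe":
        X_cal = np.asarray(X_cal, dtype=float)
        self._blocks = blocks if blocks is not None else _whole_block(X_cal.shape[1])
        self.fitted_stats = {}
        X1 = self._stage1(X_cal, self._blocks, fit=True)
        self._stage2(X1, self._blocks, fit=True, y_t=y_cal_transformed)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.fitted_stats is None:
            raise RuntimeError("recipe applied before fit")
        X1 = self._stage1(np.asarray(X, dtype=float), self._blocks, fit=False)
        return self._stage2(X1, self._blocks, fit=False, y_t=None)

    def fit_transform(self, X_cal: np.ndarray,
                      y_cal_transformed: np.ndarray | None = None,
                      blocks: list[ColumnBlock] | None = None) -> np.ndarray:
        self.fit(X_cal, y_cal_transformed, blocks)
        return self.transform(X_cal)

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return transform_reference(y, self.ref_transform, self.power_exponent)

    def inverse_transform_y(self, y_t: np.ndarray) -> np.ndarray:
        return inverse_transform_reference(y_t, self.ref_transform,
                                           self.power_exponent)


def all_recipes(**kwargs) -> list[PreprocessingRecipe]:
    """The full 7 x 3 x 3 = 63 recipe grid, in lexicographic code order."""
    return [PreprocessingRecipe(s1, s2, c, **kwargs)
            for s1, s2, c in product(STAGE1_CODES, STAGE2_CODES, REF_CODES)]
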