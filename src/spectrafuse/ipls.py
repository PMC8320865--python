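"""Forward interval PLS (IPLS) wavelength selection.

The spectrum is tiled into fixed-width contiguous intervals; a greedy
forward search adds, at each step, the interval whose inclusion minimizes
the 4-fold cross-validated RMSE of a PLS1 model (latent variables scanned
1..20 and the best kept), and stops when the best candidate no longer
improves the RMSECV by a relative tolerance.  One seeded fold assignment
is shared by every candidate evaluation within a search so candidates
compete on equal folds.

Interval scoring runs in Gram space: each fold's centered X'X and X'y are
precomputed once over all channels, and a candidate subset only slices
them, so the per-candidate cost does not grow with the sample count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import rmse
from .plsr import MAX_LV, gram_pls_coefficients, make_folds

__all__ = ["IntervalGrid", "IPLSSelection", "make_intervals", "forward_ipls",
           "count_by_range"]

#: default visible / NIR split used for reporting selected-channel counts
VISIBLE_NIR_BOUNDARY_NM = 700.0


@dataclass
class IntervalGrid:
    n_variables: int
    width: int
    intervals: list[tuple[int, int]]  # [start, end) index ranges


def make_intervals(n_variables: int, width: int) -> IntervalGrid:
    """Tile [0, n_variables) into width-W intervals (last may be shorter)."""
    if n_variables < 1:
        raise ValueError("n_variables must be positive")
    if width < 1:
        raise ValueError("window width must be >= 1")
    if width > n_variables:
        raise ValueError("window width exceeds the number of variables")
    starts = range(0, n_variables, width)
    return IntervalGrid(n_variables, width,
                        [(s, min(s + width, n_variables)) for s in starts])


@dataclass
class IPLSSelection:
    selected_intervals: list[tuple[int, int]]  # in selection order
    selected_wavelength_indices: np.ndarray    # sorted union
    rmsecv_trace: np.ndarray                   # RMSECV after each accepted step
    lv_per_step: list[int]
    width: int
    folds: list[np.ndarray] = field(default_factory=list, repr=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "width": self.width,
            "selected_intervals": [list(iv) for iv in self.selected_intervals],
            "selected_wavelength_indices":
                [int(i) for i in self.selected_wavelength_indices],
            "rmsecv_trace": [float(v) for v in self.rmsecv_trace],
            "lv_per_step": [int(v) for v in self.lv_per_step],
        }, indent=1))

    def write_wavelength_list(self, path: str | Path,
                              wavelengths: np.ndarray) -> None:
        """One selected wavelength (nm) per line."""
        Path(path).write_text("\n".join(
            f"{wavelengths[i]:.2f}" for i in self.selected_wavelength_indices) + "\n")


class _FoldScorer:
    """Shared per-fold Gram precomputation for candidate subset scoring."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 fold_indices: list[np.ndarray], max_lv: int):
        self.X = X
        self.y = y
        self.n = X.shape[0]
        self.max_lv = max_lv
        self.fold = []
        for va in fold_indices:
            tr = np.setdiff1d(np.arange(self.n), va)
            xbar = X[tr].mean(axis=0)
            ybar = y[tr].mean()
            Xc = X[tr] - xbar
            yc = y[tr] - ybar
            self.fold.append({
                "va": va, "n_tr": tr.size, "xbar": xbar, "ybar": ybar,
                "G": Xc.T @ Xc, "s": Xc.T @ yc, "Xva": X[va],
            })

    def score(self, cols: np.ndarray) -> tuple[float, int]:
        """Min-over-LV 4-fold RMSECV of a PLS model on the given columns."""
        cap = min(self.max_lv, cols.size,
                  min(f["n_tr"] for f in self.fold) - 1)
        oof = np.empty((self.n, cap))
        ix = np.ix_(cols, cols)
        for f in self.fold:
            B = gram_pls_coefficients(f["G"][ix], f["s"][cols], cap)
            oof[f["va"]] = f["ybar"] + (f["Xva"][:, cols] - f["xbar"][cols]) @ B
        rmsecv = np.sqrt(np.mean((self.y[:, None] - oof) ** 2, axis=0))
        a = int(np.argmin(rmsecv))
        return float(rmsecv[a]), a + 1


def forward_ipls(X: np.ndarray, y: np.ndarray, grid: IntervalGrid,
                 max_lv: int = MAX_LV, folds: int = 4, rng_seed: int = 0,
                 rtol: float = 1e-4,
                 max_steps: int | None = None) -> IPLSSelection:
    """Greedy forward interval selection scored by 4-fold RMSECV.

    Stops when the best remaining candidate fails to lower the RMSECV by a
    relative ``rtol``, when every interval is included, or (optionally)
    after ``max_steps`` accepted intervals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if np.std(y) == 0:
        raise ValueError("constant response")
    if X.shape[1] != grid.n_variables:
        raise ValueError("X column count does not match the interval grid")
    fold_indices = make_folds(n, folds, rng_seed)
    scorer = _FoldScorer(X, y, fold_indices, min(max_lv, MAX_LV))

    remaining = list(range(len(grid.intervals)))
    selected: list[tuple[int, int]] = []
    sel_cols = np.empty(0, dtype=int)
    trace: list[float] = []
    lv_per_step: list[int] = []
    best_rmsecv = np.inf

    while remaining:
        if max_steps is not None and len(selected) >= max_steps:
            break
        cand_best = None  # (rmsecv, interval_position_in_remaining, lv)
        for pos, ivl_idx in enumerate(remaining):
            s, e = grid.intervals[ivl_idx]
            cols = np.concatenate([sel_cols, np.arange(s, e)])
            score, lv = scorer.score(cols)
            if cand_best is None or score < cand_best[0]:
                cand_best = (score, pos, lv)
        score, pos, lv = cand_best
        if selected and score >= best_rmsecv * (1.0 - rtol):
            break  # no candidate improves enough
        ivl_idx = remaining.pop(pos)
        s, e = grid.intervals[ivl_idx]
        selected.append((s, e))
        sel_cols = np.concatenate([sel_cols, np.arange(s, e)])
        best_rmsecv = score
        trace.append(score)
        lv_per_step.append(lv)

    return IPLSSelection(
        selected_intervals=selected,
        selected_wavelength_indices=np.sort(sel_cols),
        rmsecv_trace=np.array(trace),
        lv_per_step=lv_per_step,
        width=grid.width,
        folds=fold_indices,
    )


def count_by_range(selection: IPLSSelection, wavelengths: np.ndarray,
                   boundary_nm: float = VISIBLE_NIR_BOUNDARY_NM) -> dict:
    """Selected-channel counts split into visible (< boundary) and NIR."""
    wl = np.asarray(wavelengths)[selection.selected_wavelength_indices]
    return {
        "total": int(wl.size),
        "visible": int(np.sum(wl < boundary_nm)),
        "nir": int(np.sum(wl >= boundary_nm)),
    }
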