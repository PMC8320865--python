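"""Partial least squares regression (PLS1) with cross-validated LV choice.

Two equivalent engines are provided:

* :func:`fit_pls` — the canonical NIPALS PLS1 decomposition, exposing
  weights, loadings and scores, used for every final model.
* :func:`gram_pls_coefficients` — a kernel-space formulation operating on
  the Gram matrix X'X and cross-product X'y only (after Dayal &
  MacGregor), returning the nested coefficient paths for 1..A latent
  variables at a cost independent of the sample count.  Cross-validation
  and the interval search use it for speed; tests assert it reproduces the
  NIPALS predictions.

Latent variables are capped at 20 throughout, matching the configuration
of the wavelength-selection search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import rmse

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "make_folds",
           "cross_validate", "select_calibration_model",
           "gram_pls_coefficients"]

MAX_LV = 20
_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    n_lv: int
    x_weights: np.ndarray    # (k, A), each column unit norm
    x_loadings: np.ndarray   # (k, A)
    y_loadings: np.ndarray   # (A,)
    scores: np.ndarray       # (n, A), mutually orthogonal
    coefficients: np.ndarray  # (k,), regression vector on centered data
    x_center: np.ndarray
    y_center: float
    training_meta: dict = field(default_factory=dict)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            meta: dict | None = None) -> PLSModel:
    """NIPALS PLS1 fit with internal centering of X and y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if not (1 <= n_lv <= min(n - 1, k, MAX_LV)):
        raise ValueError(f"n_lv must be in [1, min(n-1, k, {MAX_LV})]")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xd = X - x_center
    yd = y - y_center
    W = np.zeros((k, n_lv))
    P = np.zeros((k, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    a_used = 0
    scale0 = np.linalg.norm(Xd.T @ yd)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(scale0, 1.0):
            break  # response fully explained / rank exhausted
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= _EPS * n:
            break
        p = Xd.T @ t / tt
        qa = (yd @ t) / tt
        Xd -= np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
        a_used = a + 1
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    # B = W (P'W)^-1 q via triangular solve
    coef = W @ np.linalg.solve(P.T @ W, q) if a_used else np.zeros(k)
    return PLSModel(n_lv=a_used, x_weights=W, x_loadings=P, y_loadings=q,
                    scores=T, coefficients=coef, x_center=x_center,
                    y_center=y_center, training_meta=meta or {})


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return model.y_center + (X - model.x_center) @ model.coefficients


def gram_pls_coefficients(G: np.ndarray, s: np.ndarray, n_lv: int) -> np.ndarray:
    """Nested PLS1 coefficient paths from the centered Gram matrix.

    Parameters are G = Xc'Xc and s = Xc'yc.  Returns a (k, n_lv) matrix
    whose column a-1 is the coefficient vector of the a-component model;
    if the rank is exhausted early the last valid column is repeated, so
    downstream LV scans remain well-defined.
    """
    k = s.size
    B = np.zeros((k, n_lv))
    R = np.zeros((k, n_lv))
    P = np.zeros((k, n_lv))
    beta = np.zeros(k)
    s = np.asarray(s, dtype=float).copy()
    scale0 = np.linalg.norm(s)
    for a in range(n_lv):
        ns = np.linalg.norm(s)
        if ns <= 1e-12 * max(scale0, 1.0):
            B[:, a:] = beta[:, None]
            break
        w = s / ns
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        Gr = G @ r
        tt = r @ Gr
        if tt <= _EPS * max(np.trace(G), 1.0):
            B[:, a:] = beta[:, None]
            break
        p = Gr / tt
        qa = (s @ r) / tt
        beta = beta + qa * r
        B[:, a] = beta
        R[:, a] = r
        P[:, a] = p
        s = s - (tt * qa) * p
    return B


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    folds: list[np.ndarray]
    rmsecv_by_lv: np.ndarray  # (max_lv,)
    best_lv: int
    seed: int

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_lv[self.best_lv - 1])


def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into folds whose sizes differ by at most 1."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < 2 * folds:
        raise ValueError("need at least 2 samples per fold")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, folds)]


def cross_validate(X: np.ndarray, y: np.ndarray, max_lv: int = MAX_LV,
                   folds: int = 4, rng_seed: int = 0,
                   fold_indices: list[np.ndarray] | None = None) -> CVResult:
    """Out-of-fold RMSE for each LV count in 1..max_lv; best = argmin.

    A precomputed fold assignment can be passed so that competing recipes
    or wavelength subsets are scored on identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if fold_indices is None:
        fold_indices = make_folds(n, folds, rng_seed)
    max_lv = int(min(max_lv, MAX_LV))
    cap = min(max_lv, k, min(n - f.size for f in fold_indices) - 1)
    if cap < 1:
        raise ValueError("not enough samples/variables for one latent variable")
    oof = np.empty((n, cap))
    for va in fold_indices:
        tr = np.setdiff1d(np.arange(n), va, assume_unique=False)
        xbar = X[tr].mean(axis=0)
        ybar = y[tr].mean()
        Xc = X[tr] - xbar
        yc = y[tr] - ybar
        B = gram_pls_coefficients(Xc.T @ Xc, Xc.T @ yc, cap)
        oof[va] = ybar + (X[va] - xbar) @ B
    rmsecv = np.array([rmse(y, oof[:, a]) for a in range(cap)])
    best = int(np.argmin(rmsecv)) + 1  # argmin takes the first (fewest LVs) on ties
    return CVResult(folds=fold_indices, rmsecv_by_lv=rmsecv, best_lv=best,
                    seed=rng_seed)


def select_calibration_model(candidates: list[tuple]) -> tuple:
    """Pick the candidate with minimum RMSECV.

    Candidates are (recipe_code, CVResult, payload) triples; ties go to
    fewer latent variables, then lexicographic recipe code.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    return min(candidates,
               key=lambda c: (c[1].rmsecv, c[1].best_lv, str(c[0])))
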