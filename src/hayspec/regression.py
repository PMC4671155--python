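"""Calibration engines: 2-wavelength MLR, PCR and NIPALS PLS1.

All three regress a chemistry constituent y on preprocessed spectra X
(rows = samples, columns = the trimmed wavelength axis). X columns and y are
mean-centered before factor extraction; wavelengths are not autoscaled, the
usual convention for NIR absorbance-derivative matrices. Every fit reduces
to a stored coefficient vector on the preprocessed axis plus an intercept,
so prediction is a pure function of the serialized model.

* MLR: ordinary least squares on a handful of wavelengths picked from the
  correlation spectrum (first by |r|, then greedily by joint calibration R^2).
* PCR: regression of y on the top principal-component scores of X.
* PLS1 (NIPALS): latent factors chosen to maximize covariance with y; the
  weight/loading/score triples are extracted by the classical NIPALS
  iteration with deflation of X and y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import PreprocessConfig

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class CalibrationModel:
    """A fitted calibration; prediction needs only the stored fields."""

    method: str                       # "mlr" | "pcr" | "pls"
    coef: np.ndarray                  # on the preprocessed (trimmed) axis
    intercept: float
    wavelengths: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    y_mean: float | None = None
    n_components: int | None = None
    selected_indices: list[int] | None = None   # MLR wavelength columns
    preprocess: PreprocessConfig | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.method == "mlr":
            sel = self.selected_indices or []
            if len(sel) == 0 or len(set(sel)) != len(sel):
                raise ValueError("MLR needs a non-empty, duplicate-free wavelength list")
        elif self.n_components is not None and self.n_components < 1:
            raise ValueError("component count must be >= 1")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "format_version": 1,
            "method": self.method,
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "wavelengths": None if self.wavelengths is None else np.asarray(self.wavelengths).tolist(),
            "x_mean": None if self.x_mean is None else np.asarray(self.x_mean).tolist(),
            "y_mean": None if self.y_mean is None else float(self.y_mean),
            "n_components": self.n_components,
            "selected_indices": self.selected_indices,
            "preprocess": None if self.preprocess is None else asdict(self.preprocess),
            "metadata": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in self.metadata.items()},
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            method=d["method"],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            wavelengths=None if d.get("wavelengths") is None else np.asarray(d["wavelengths"], dtype=float),
            x_mean=None if d.get("x_mean") is None else np.asarray(d["x_mean"], dtype=float),
            y_mean=d.get("y_mean"),
            n_components=d.get("n_components"),
            selected_indices=d.get("selected_indices"),
            preprocess=None if d.get("preprocess") is None else PreprocessConfig(**d["preprocess"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Apply a fitted model to preprocessed spectra on the model's axis."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"spectra have {X.shape[1]} columns but the model expects "
            f"{model.coef.shape[0]} (same preprocessing and trimmed axis required)"
        )
    return X @ model.coef + model.intercept


def correlation_spectrum(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each wavelength column with y.

    Zero-variance columns map to 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least three samples")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    if sy == 0:
        r[:] = 0.0
    return r


def _ols_r2(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    """In-sample R^2 of OLS on the given columns plus intercept."""
    A = np.column_stack([np.ones(len(y)), X[:, cols]])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / sst


def select_mlr_wavelengths(X: np.ndarray, y: np.ndarray,
                           n_wavelengths: int = 2) -> list[int]:
    """Greedy correlation-spectrum wavelength selection.

    The first wavelength maximizes |r| with y; each further wavelength
    maximizes the joint calibration R^2 of the OLS fit. Ties break toward
    the shorter wavelength (lower column index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_wavelengths < 1:
        raise ValueError("n_wavelengths must be >= 1")
    if X.shape[0] <= n_wavelengths + 1:
        raise ValueError("too few samples for the requested wavelength count")
    r = np.abs(correlation_spectrum(X, y))
    selected = [int(np.argmax(r))]       # argmax returns the first (shortest) tie
    while len(selected) < n_wavelengths:
        best, best_r2 = None, -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            r2j = _ols_r2(X, y, selected + [j])
            if r2j > best_r2 + 1e-12:
                best, best_r2 = j, r2j
        if best is None:
            break
        selected.append(best)
    return selected


def best_mlr_pair(X: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Exhaustive search for the best 2-wavelength OLS pair (verification mode)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    best, best_r2 = (0, 1), -np.inf
    for a in range(p):
        for b in range(a + 1, p):
            r2ab = _ols_r2(X, y, [a, b])
            if r2ab > best_r2 + 1e-12:
                best, best_r2 = (a, b), r2ab
    return best


def fit_mlr(X: np.ndarray, y: np.ndarray, indices: list[int],
            wavelengths: np.ndarray | None = None,
            preprocess: PreprocessConfig | None = None) -> CalibrationModel:
    """OLS on the selected wavelength columns plus intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    indices = [int(i) for i in indices]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate wavelengths selected")
    if X.shape[0] < len(indices) + 1:
        raise ValueError("too few samples for the selected wavelength count")
    A = np.column_stack([np.ones(len(y)), X[:, indices]])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("selected wavelength columns are collinear")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    coef = np.zeros(X.shape[1])
    coef[indices] = beta[1:]
    meta = {}
    if wavelengths is not None:
        meta["selected_wavelengths_nm"] = np.asarray(wavelengths)[indices].tolist()
    return CalibrationModel(
        method="mlr", coef=coef, intercept=float(beta[0]),
        wavelengths=wavelengths, selected_indices=indices,
        preprocess=preprocess, metadata=meta,
    )


def fit_pcr(X: np.ndarray, y: np.ndarray, n_components: int,
            wavelengths: np.ndarray | None = None,
            preprocess: PreprocessConfig | None = None) -> CalibrationModel:
    """Principal-component regression with ``n_components`` factors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    # guard against components with numerically zero singular value
    s_k = s[:k]
    nonzero = s_k > s[0] * 1e-12 if s[0] > 0 else s_k > 0
    gamma = np.zeros(k)
    gamma[nonzero] = (u[:, :k][:, nonzero].T @ yc) / s_k[nonzero]
    coef = vt[:k].T @ gamma
    intercept = y_mean - float(x_mean @ coef)
    return CalibrationModel(
        method="pcr", coef=coef, intercept=intercept, wavelengths=wavelengths,
        x_mean=x_mean, y_mean=y_mean, n_components=k, preprocess=preprocess,
        metadata={"singular_values": s[:k], "loadings": vt[:k]},
    )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Classical NIPALS PLS1 with deflation.

    Returns (W, P, T, q, k_used); extraction stops early if the deflated
    cross-covariance X'y vanishes (remaining factors would be null).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    X = Xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc)
    k_used = 0
    for k in range(n_components):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if scale == 0 or wn <= 1e-14 * max(scale, 1.0):
            break  # nothing left to extract
        w = w / wn
        for _ in range(_NIPALS_MAX_ITER):
            t = X @ w
            tt = t @ t
            if tt == 0:
                break
            qk = (y @ t) / tt
            w_new = X.T @ (y * qk)
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new = w_new / nw
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        else:
            raise RuntimeError("NIPALS failed to converge for a component")
        t = X @ w
        tt = t @ t
        if tt <= 0:
            break
        p_k = (X.T @ t) / tt
        q_k = (y @ t) / tt
        X = X - np.outer(t, p_k)
        y = y - t * q_k
        W[:, k], P[:, k], T[:, k], q[k] = w, p_k, t, q_k
        k_used = k + 1
    return W[:, :k_used], P[:, :k_used], T[:, :k_used], q[:k_used], k_used


def _pls_coef(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Fold factors back to a wavelength-axis coefficient vector."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    # P'W is upper unitriangular for NIPALS, but solve generally for safety
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            wavelengths: np.ndarray | None = None,
            preprocess: PreprocessConfig | None = None) -> CalibrationModel:
    """NIPALS PLS1 with ``n_components`` latent factors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    if np.allclose(y, y[0]):
        raise ValueError("y has zero variance; nothing to calibrate")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, T, q, k_used = _nipals_pls1(X - x_mean, y - y_mean, n_components)
    coef = _pls_coef(W, P, q)
    intercept = y_mean - float(x_mean @ coef)
    return CalibrationModel(
        method="pls", coef=coef, intercept=intercept, wavelengths=wavelengths,
        x_mean=x_mean, y_mean=y_mean, n_components=k_used, preprocess=preprocess,
        metadata={"weights": W, "loadings": P, "scores": T, "y_loadings": q,
                  "requested_components": n_components},
    )


# -- leave-one-out component selection ---------------------------------

def _loo_predictions_all_k(X: np.ndarray, y: np.ndarray, method: str,
                           max_pc: int) -> np.ndarray:
    """LOO predictions for every component count 1..max_pc; shape (n, max_pc).

    Each fold is refit from scratch; within a fold, predictions for all
    component counts fall out of one factor-extraction pass.
    """
    n = X.shape[0]
    preds = np.empty((n, max_pc))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        Xc, yc = Xi - x_mean, yi - y_mean
        x_new = X[i] - x_mean
        if method == "pls":
            W, P, _, q, k_used = _nipals_pls1(Xc, yc, max_pc)
            for k in range(1, max_pc + 1):
                kk = min(k, k_used)
                coef = _pls_coef(W[:, :kk], P[:, :kk], q[:kk])
                preds[i, k - 1] = y_mean + x_new @ coef
        elif method == "pcr":
            u, s, vt = np.linalg.svd(Xc, full_matrices=False)
            tol = (s[0] * 1e-12) if s.size and s[0] > 0 else 0.0
            gamma = np.where(s > tol, (u.T @ yc) / np.where(s > tol, s, 1.0), 0.0)
            proj = vt @ x_new
            contrib = proj * gamma
            cum = np.cumsum(contrib)
            for k in range(1, max_pc + 1):
                preds[i, k - 1] = y_mean + cum[min(k, len(cum)) - 1]
        else:
            raise ValueError(f"unknown factor method {method!r}")
    return preds


def select_n_components(X: np.ndarray, y: np.ndarray, method: str = "pls",
                        max_pc: int = 15, return_rmse: bool = False):
    """Pick the factor count minimizing leave-one-out RMSE (ties -> fewer)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    max_pc = min(max_pc, n - 2, p)
    if max_pc < 1:
        raise ValueError("not enough samples/wavelengths to select components")
    preds = _loo_predictions_all_k(X, y, method, max_pc)
    rmse_k = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
    best = int(np.argmin(np.round(rmse_k, 12))) + 1   # first minimum wins ties
    if return_rmse:
        return best, rmse_k
    return best
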