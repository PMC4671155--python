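"""Splitting, error metrics, RPD banding and the three-method benchmark.

Metric conventions:

* RMSEC / RMSEP: sqrt(mean squared residual) over the calibration /
  validation pairs — no degrees-of-freedom correction.
* R^2 (calibration) and r^2 (validation): squared Pearson correlation
  between reference and predicted values, the scatter-plot convention; the
  1 - SSE/SST form is reported alongside in machine-readable output.
* RPD: SD of the validation set's reference values divided by RMSEP,
  banded good (>= 2), acceptable (1.4-2) or unreliable (< 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .preprocess import preprocess_spectra, to_absorbance
from .outliers import remove_outliers
from . import regression as reg

RPD_GOOD = 2.0
RPD_ACCEPTABLE = 1.4


@dataclass(frozen=True)
class SplitSpec:
    """A calibration/validation partition of sample indices."""

    n: int
    fraction: float
    seed: int
    calibration: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        both = np.concatenate([self.calibration, self.validation])
        if len(np.unique(both)) != self.n or len(both) != self.n:
            raise ValueError("calibration/validation must partition range(n)")


def split_cal_val(n: int, fraction: float = 0.75, seed: int = 0) -> SplitSpec:
    """Random disjoint calibration/validation split, sizes (round(f*n), rest)."""
    if n < 4:
        raise ValueError("need at least four samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n_cal = int(round(fraction * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError("degenerate split: one side would be empty")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(n=n, fraction=fraction, seed=seed,
                     calibration=np.sort(perm[:n_cal]),
                     validation=np.sort(perm[n_cal:]))


def rmse(y: Sequence[float], y_pred: Sequence[float], which: str = "RMSE") -> float:
    """Root mean squared residual of (reference, predicted) pairs."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.shape != y_pred.shape:
        raise ValueError(f"{which}: need equal-length, non-empty inputs")
    return float(np.sqrt(((y_pred - y) ** 2).mean()))


def r2(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """Squared Pearson correlation between reference and predicted values."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.std() == 0 or y_pred.std() == 0:
        raise ValueError("r2 undefined when either input is constant")
    return float(np.corrcoef(y, y_pred)[0, 1] ** 2)


def r2_sse(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """1 - SSE/SST form of the coefficient of determination."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("r2 undefined for constant reference values")
    return float(1.0 - ((y - y_pred) ** 2).sum() / sst)


def rpd(sd_validation: float, rmsep: float) -> tuple[float, str]:
    """SD of the validation reference values over RMSEP, with quality band."""
    if sd_validation <= 0 or rmsep <= 0:
        raise ValueError("rpd requires positive SD and RMSEP")
    value = sd_validation / rmsep
    if value >= RPD_GOOD:
        band = "good"
    elif value >= RPD_ACCEPTABLE:
        band = "acceptable"
    else:
        band = "unreliable"
    return float(value), band


def loo_cross_validate(X: np.ndarray, y: np.ndarray, fit_predict) -> dict:
    """Leave-one-out refits; ``fit_predict(X_train, y_train, x_new) -> float``.

    Returns per-case held-out predictions and their aggregate RMSE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three samples for LOO")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            preds[i] = fit_predict(X[mask], y[mask], X[i])
        except Exception as exc:  # annotate which fold failed
            raise RuntimeError(f"LOO fold {i} failed: {exc}") from exc
    return {"predictions": preds,
            "rmse": rmse(y, preds, "RMSECV"),
            "residuals": y - preds}


@dataclass
class MetricsReport:
    """Calibration + validation scorecard for one (constituent, method) cell."""

    constituent: str
    method: str
    n_c: int
    n_p: int
    n_components: int | None
    rmsec: float
    rmsep: float
    r2_cal: float
    r2_val: float
    r2_val_sse: float
    sd_val: float
    rpd: float
    rpd_band: str
    y_cal: np.ndarray = field(repr=False, default=None)
    y_cal_pred: np.ndarray = field(repr=False, default=None)
    y_val: np.ndarray = field(repr=False, default=None)
    y_val_pred: np.ndarray = field(repr=False, default=None)
    n_outliers_removed: int = 0
    selected_wavelengths_nm: list[float] | None = None


@dataclass
class BenchmarkReport:
    """All (constituent x method) cells of one benchmark run."""

    cells: list[MetricsReport]
    config: RunConfig | None = None
    split: SplitSpec | None = None

    def cell(self, constituent: str, method: str) -> MetricsReport:
        for c in self.cells:
            if c.constituent == constituent and c.method == method:
                return c
        raise KeyError((constituent, method))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append({
                "constituent": c.constituent, "method": c.method,
                "n_c": c.n_c, "n_p": c.n_p, "PC": c.n_components,
                "R2": c.r2_cal, "RMSEC": c.rmsec,
                "r2": c.r2_val, "RMSEP": c.rmsep,
                "r2_sse": c.r2_val_sse, "SD_val": c.sd_val,
                "RPD": c.rpd, "band": c.rpd_band,
                "outliers_removed": c.n_outliers_removed,
            })
        return pd.DataFrame(rows)

    def format_tables(self) -> str:
        """Text tables in the calibration / validation benchmark layout."""
        df = self.to_frame()
        lines = ["Calibration accuracy (R2, RMSEC)"]
        header = f"{'':8s}" + "".join(f"{m.upper():>18s}" for m in ("pls", "pcr", "mlr"))
        lines.append(header)
        for const in ("CP", "ADF", "NDF"):
            row = f"{const + ' (%)':8s}"
            for m in ("pls", "pcr", "mlr"):
                sub = df[(df.constituent == const) & (df.method == m)]
                row += ("{:>9.2f}{:>9.2f}".format(sub.R2.iloc[0], sub.RMSEC.iloc[0])
                        if len(sub) else " " * 18)
            lines.append(row)
        lines.append("")
        lines.append("Validation accuracy (r2, RMSEP, RPD)")
        lines.append(f"{'':8s}" + "".join(f"{m.upper():>27s}" for m in ("pls", "pcr", "mlr")))
        for const in ("CP", "ADF", "NDF"):
            row = f"{const + ' (%)':8s}"
            for m in ("pls", "pcr", "mlr"):
                sub = df[(df.constituent == const) & (df.method == m)]
                row += ("{:>9.2f}{:>9.2f}{:>9.1f}".format(
                        sub.r2.iloc[0], sub.RMSEP.iloc[0], sub.RPD.iloc[0])
                        if len(sub) else " " * 27)
            lines.append(row)
        return "\n".join(lines)

    def scatter_frame(self, constituent: str, method: str) -> pd.DataFrame:
        c = self.cell(constituent, method)
        return pd.DataFrame({"measured": c.y_val, "predicted": c.y_val_pred})


def _fit_cell(method: str, X_cal, y_cal, wl, cfg: RunConfig, constituent: str):
    """Fit one engine per the run config; returns the model."""
    if method == "mlr":
        idx = reg.select_mlr_wavelengths(X_cal, y_cal, cfg.mlr_n_wavelengths)
        return reg.fit_mlr(X_cal, y_cal, idx, wavelengths=wl)
    if cfg.component_policy == "loo":
        k = reg.select_n_components(X_cal, y_cal, method, cfg.max_components)
    else:
        k = cfg.fixed_components[constituent]
    k = min(k, X_cal.shape[0] - 1, X_cal.shape[1])
    fit = reg.fit_pls if method == "pls" else reg.fit_pcr
    return fit(X_cal, y_cal, k, wavelengths=wl)


def benchmark(dataset, config: RunConfig | None = None) -> BenchmarkReport:
    """Run the full pipeline grid: split -> outlier screen -> fit -> score.

    For every constituent and every engine in ``config.methods``: the same
    seeded calibration/validation split is shared across methods (paired
    comparison); the Mahalanobis outlier screen runs per constituent on the
    preprocessed calibration spectra only; validation samples are never
    removed.
    """
    cfg = config or RunConfig()
    n = dataset.n_samples
    if n < 8:
        raise ValueError("benchmark needs a dataset with more samples")
    split = split_cal_val(n, cfg.split_fraction, cfg.split_seed())

    A = to_absorbance(dataset.mean_reflectance(), dataset.grid.wavelengths)
    wavelengths = dataset.grid.wavelengths

    cells: list[MetricsReport] = []
    for const in cfg.constituents:
        y = dataset.compositions[const].to_numpy(dtype=float)
        X_all, wl = preprocess_spectra(A, wavelengths, cfg.preprocess[const])
        X_cal, y_cal = X_all[split.calibration], y[split.calibration]
        X_val, y_val = X_all[split.validation], y[split.validation]

        X_clean, y_clean, rep = remove_outliers(
            X_cal, y_cal, n_scores=cfg.fixed_components[const],
            criterion_sd=cfg.outlier_criterion_sd, constituent=const,
        )

        for method in cfg.methods:
            model = _fit_cell(method, X_clean, y_clean, wl, cfg, const)
            y_cal_pred = reg.predict(model, X_clean)
            y_val_pred = reg.predict(model, X_val)
            rmsec = rmse(y_clean, y_cal_pred, "RMSEC")
            rmsep = rmse(y_val, y_val_pred, "RMSEP")
            sd_val = float(y_val.std(ddof=1))
            rpd_val, band = rpd(sd_val, rmsep)
            cells.append(MetricsReport(
                constituent=const, method=method,
                n_c=len(y_clean), n_p=len(y_val),
                n_components=model.n_components,
                rmsec=rmsec, rmsep=rmsep,
                r2_cal=r2(y_clean, y_cal_pred),
                r2_val=r2(y_val, y_val_pred),
                r2_val_sse=r2_sse(y_val, y_val_pred),
                sd_val=sd_val, rpd=rpd_val, rpd_band=band,
                y_cal=y_clean, y_cal_pred=y_cal_pred,
                y_val=y_val, y_val_pred=y_val_pred,
                n_outliers_removed=rep.n_flagged,
                selected_wavelengths_nm=model.metadata.get("selected_wavelengths_nm"),
            ))
    return BenchmarkReport(cells=cells, config=cfg, split=split)
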