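"""Spectral outlier screening by Mahalanobis distance in PCA score space.

Calibration samples whose preprocessed spectra sit unusually far from the
population centroid are flagged before model fitting. Distances are computed
on principal-component scores of the spectra (never on the chemistry), and a
sample is flagged when its distance exceeds the mean distance by three (or a
configured number of) standard deviations of the distance distribution.
Flagging is a single pass: the screen mirrors a one-shot calibration
clean-up, not an iterative trimming procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OutlierReport:
    distances: np.ndarray
    threshold: float
    flags: np.ndarray
    n_score_dimensions: int
    criterion_sd: float
    constituent: str | None = None
    sample_ids: list[str] | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or [str(i) for i in range(len(self.distances))]
        return pd.DataFrame(
            {"sample_id": ids, "distance": self.distances, "flagged": self.flags}
        )


def pca_scores(X: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-centered matrix.

    Columns are ordered by decreasing explained variance; signs follow the
    SVD convention (determined up to a flip per component).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples for PCA")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return u[:, :k] * s[:k]


def mahalanobis_outliers(scores: np.ndarray, criterion_sd: float = 3.0,
                         sample_ids: list[str] | None = None,
                         constituent: str | None = None) -> OutlierReport:
    """Flag samples whose score-space Mahalanobis distance is extreme.

    The threshold is mean(d) + criterion_sd * sd(d) over the observed
    distances d_i; a sample is flagged iff d_i >= threshold.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[0] < 3:
        raise ValueError("need at least three samples")
    center = S.mean(axis=0)
    cov = np.atleast_2d(np.cov(S, rowvar=False))
    # reject ill-conditioned covariance rather than silently inverting noise
    if np.linalg.cond(cov) > 1e12 or np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise ValueError(
            "singular score covariance; use fewer score dimensions"
        )
    prec = np.linalg.inv(cov)
    diff = S - center
    d = np.sqrt(np.einsum("ij,jk,ik->i", diff, prec, diff))
    threshold = float(d.mean() + criterion_sd * d.std(ddof=1))
    flags = d >= threshold
    return OutlierReport(
        distances=d, threshold=threshold, flags=flags,
        n_score_dimensions=S.shape[1], criterion_sd=criterion_sd,
        constituent=constituent, sample_ids=sample_ids,
    )


def remove_outliers(
    X: np.ndarray,
    y: np.ndarray | None = None,
    n_scores: int = 8,
    criterion_sd: float = 3.0,
    sample_ids: list[str] | None = None,
    constituent: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, OutlierReport]:
    """Screen a calibration matrix; returns (clean X, clean y, report).

    ``n_scores`` is capped so the score covariance stays well conditioned
    (components with negligible variance are dropped). y is only subset, it
    plays no role in flagging.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k = min(n_scores, n - 1, p)
    scores = pca_scores(X, k)
    # drop trailing components with negligible variance
    var = scores.var(axis=0)
    keep = var > 1e-10 * max(var[0], 1e-300)
    scores = scores[:, keep]
    report = mahalanobis_outliers(scores, criterion_sd, sample_ids=sample_ids,
                                  constituent=constituent)
    mask = ~report.flags
    y_clean = None if y is None else np.asarray(y, dtype=float)[mask]
    return X[mask], y_clean, report
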