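"""Reflectance-to-model-matrix preprocessing.

Order of operations for a calibration pipeline: average replicate scans,
convert reflectance to absorbance A = log10(1/R), normalize per spectrum
(vector / min-max / zero-offset), then take a second derivative with either
a Savitzky-Golay polynomial filter or a Norris gap-segment filter.

Derivatives are taken with respect to the data-point index (the convention
of filter parameters quoted as point counts); multiply by step_nm**-2 if
per-nm^2 units are needed. Edge points where a derivative stencil does not
fit are dropped and the wavelength axis trimmed to match, so calibration and
prediction always see identical columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

_NORMALIZATIONS = ("none", "vector", "minmax", "zero")
_DERIVATIVES = ("none", "savgol", "norris")


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalization + derivative-filter settings for one constituent."""

    normalization: str = "vector"
    derivative: str = "savgol"
    savgol_window: int = 3
    savgol_polyorder: int = 2
    norris_segment: int = 5
    norris_gap: int = 2
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.derivative not in _DERIVATIVES:
            raise ValueError(f"unknown derivative {self.derivative!r}")
        if self.derivative == "savgol":
            if self.savgol_window < 3 or self.savgol_window % 2 == 0:
                raise ValueError("savgol window must be odd and >= 3")
            if self.savgol_polyorder >= self.savgol_window:
                raise ValueError("savgol polyorder must be < window")
            if self.deriv_order > self.savgol_polyorder:
                raise ValueError("derivative order must be <= polyorder")
        if self.derivative == "norris":
            if self.norris_segment < 1 or self.norris_segment % 2 == 0:
                raise ValueError("norris segment must be odd and >= 1")
            if self.norris_gap < 1:
                raise ValueError("norris gap must be >= 1")

    @property
    def edge_width(self) -> int:
        """Points dropped from each end of the axis by the derivative."""
        if self.derivative == "savgol":
            return self.savgol_window // 2
        if self.derivative == "norris":
            return (self.norris_segment - 1) // 2 + self.norris_gap
        return 0


def to_absorbance(reflectance: np.ndarray,
                  wavelengths: np.ndarray | None = None) -> np.ndarray:
    """A = log10(1/R), elementwise; rejects non-positive reflectance."""
    r = np.asarray(reflectance, dtype=float)
    bad = ~(r > 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        k = int(idx[-1])
        where = (f"wavelength {wavelengths[k]:g} nm" if wavelengths is not None
                 else f"wavelength index {k}")
        raise ValueError(f"reflectance must be > 0; offending value at {where}")
    return -np.log10(r)


def average_replicates(scans: np.ndarray) -> np.ndarray:
    """Pointwise mean of replicate scans (rows) of one sample."""
    arr = np.asarray(scans, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("scans must be a non-empty (n_replicates, n_points) array")
    return arr.mean(axis=0)


def normalize(spectrum: np.ndarray, method: str = "vector") -> np.ndarray:
    """Per-spectrum normalization; rows are treated independently for 2-D input."""
    if method == "none":
        return np.asarray(spectrum, dtype=float).copy()
    x = np.asarray(spectrum, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty spectrum")
    if x.ndim == 2:
        return np.vstack([normalize(row, method) for row in x])
    if method == "vector":
        nrm = np.linalg.norm(x)
        if nrm == 0:
            raise ValueError("vector normalization undefined for all-zero spectrum")
        return x / nrm
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("min/max normalization undefined for constant spectrum")
        return (x - lo) / (hi - lo)
    if method == "zero":
        return x - x.min()
    raise ValueError(f"unknown normalization {method!r}")


def savgol_derivative(spectrum: np.ndarray, window: int = 3, polyorder: int = 2,
                      deriv: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative in index units, edges trimmed.

    Output length is ``n - 2*(window//2)``; the interior values equal the
    exact local least-squares polynomial derivative, so (window=3,
    polyorder=2, deriv=2) reproduces the central second difference.
    """
    x = np.asarray(spectrum, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than filter window")
    half = window // 2
    out = savgol_filter(x, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=1.0, axis=-1)
    return out[..., half:x.shape[-1] - half]


def norris_derivative(spectrum: np.ndarray, segment: int = 5, gap: int = 2,
                      deriv: int = 2) -> np.ndarray:
    """Norris gap-segment second derivative in index units, edges trimmed.

    With m_i the moving mean of ``segment`` points centered at i, the
    derivative is (m_{i-gap} - 2 m_i + m_{i+gap}) / gap**2 on the interior;
    ``(segment-1)//2 + gap`` points are trimmed from each end.
    """
    x = np.asarray(spectrum, dtype=float)
    if deriv != 2:
        raise NotImplementedError("only the second-order gap-segment derivative is defined")
    if segment < 1 or segment % 2 == 0:
        raise ValueError("segment must be odd and >= 1")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    half = (segment - 1) // 2
    n = x.shape[-1]
    if n < segment + 2 * gap:
        raise ValueError("spectrum too short for this segment/gap combination")
    if x.ndim == 1:
        kernel = np.full(segment, 1.0 / segment)
        m = np.convolve(x, kernel, mode="valid")  # centers half .. n-1-half
        d = (m[: -2 * gap] - 2.0 * m[gap:-gap] + m[2 * gap:]) / gap**2
        return d
    return np.vstack([norris_derivative(row, segment, gap, deriv) for row in x])


def preprocess_spectra(
    absorbance: np.ndarray,
    wavelengths: np.ndarray,
    config: PreprocessConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply normalization then derivative; returns (X, trimmed wavelengths)."""
    a = np.atleast_2d(np.asarray(absorbance, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if a.shape[1] != wl.shape[0]:
        raise ValueError("absorbance and wavelength axis disagree in length")
    x = normalize(a, config.normalization)
    if config.derivative == "savgol":
        x = savgol_derivative(x, config.savgol_window, config.savgol_polyorder,
                              config.deriv_order)
    elif config.derivative == "norris":
        x = norris_derivative(x, config.norris_segment, config.norris_gap,
                              config.deriv_order)
    e = config.edge_width
    trimmed = wl[e:len(wl) - e] if e else wl
    return x, trimmed
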