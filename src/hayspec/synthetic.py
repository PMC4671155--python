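"""Seeded generator of hay-like NIR reflectance spectra with known chemistry.

The generator produces what a grating NIR instrument would record from ground
grass-hay samples: per-sample reference chemistry (CP, ADF, NDF as % of dry
matter) drawn from field-survey population statistics, and triplicate
reflectance scans on a 950-1650 nm grid at 5 nm steps. Spectra follow an
additive Beer-Lambert mixture: each constituent contributes a fixed
pure-component absorptivity profile (sums of Gaussian overtone/combination
bands of C-H, O-H and N-H groups) scaled by its concentration, on top of a
moisture-like background band near 1450 nm, a per-sample baseline slope (two
slope groups, emulating the two spectral families seen in scanned hay), a set
of minor-constituent nuisance components, and instrument noise. Reflectance
is recovered as R = 10^(-A) per replicate scan with multiplicative scatter
and additive detector noise.

All randomness flows through a single ``numpy`` Generator per call, so every
artifact is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

CONSTITUENTS: tuple[str, ...] = ("CP", "ADF", "NDF")

#: key of the moisture/background pure component returned alongside CP/ADF/NDF
BACKGROUND: str = "background"


@dataclass(frozen=True)
class PopulationParams:
    """Truncated-normal population of one constituent, in % dry matter."""

    constituent: str
    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.constituent}: sd must be > 0, got {self.sd}")
        if not (self.min < self.mean < self.max):
            raise ValueError(
                f"{self.constituent}: need min < mean < max, got "
                f"{self.min}, {self.mean}, {self.max}"
            )


#: Population statistics of the 203-sample hay survey (total-samples rows).
TABLE1_POPULATIONS: dict[str, PopulationParams] = {
    "CP": PopulationParams("CP", 6.20, 14.33, 10.54, 1.24),
    "ADF": PopulationParams("ADF", 35.13, 42.34, 38.74, 2.33),
    "NDF": PopulationParams("NDF", 50.71, 71.08, 60.89, 2.67),
}

#: Cross-constituent correlation of the latent Gaussian copula, ordered
#: (CP, ADF, NDF). Protein trades off against both fiber fractions while the
#: fiber fractions co-vary, the usual pattern in forage surveys.
DEFAULT_CORRELATION = np.array(
    [
        [1.0, -0.4, -0.4],
        [-0.4, 1.0, 0.6],
        [-0.4, 0.6, 1.0],
    ]
)


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength axis in nanometres."""

    start_nm: float = 950.0
    end_nm: float = 1650.0
    step_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.end_nm <= self.start_nm:
            raise ValueError("grid must have positive step and end > start")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)


@dataclass(frozen=True)
class PureComponentSpectrum:
    """Per-wavelength absorptivity of one mixture component.

    Units are absorbance per % dry matter for the chemistry constituents and
    absorbance per unit concentration for the background component.
    """

    constituent: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if np.any(coeffs < 0) or not np.any(coeffs > 0):
            raise ValueError("absorptivities must be >= 0 with at least one > 0")
        object.__setattr__(self, "coefficients", coeffs)


# Gaussian band tables: (center nm, width nm, peak absorptivity per unit).
# Frozen constants so regeneration and tests are stable. Band placement
# follows the qualitative NIR assignments for forage: protein N-H near
# 1100 nm (dominant, so protein-rich samples peak there), cellulose /
# hemicellulose C-H first overtones through 1150-1550 nm, and an O-H water
# band at 1450 nm that dominates the background.
_BAND_TABLES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "CP": ((1100.0, 45.0, 2.00e-2), (1510.0, 60.0, 4.0e-3), (1020.0, 40.0, 3.0e-3)),
    "ADF": ((1200.0, 55.0, 3.5e-3), (1365.0, 40.0, 5.0e-3), (1490.0, 65.0, 3.0e-3),
            (1230.0, 32.0, 6.0e-3)),
    "NDF": ((1170.0, 60.0, 2.8e-3), (1320.0, 40.0, 4.5e-3), (1540.0, 70.0, 2.6e-3),
            (1587.0, 32.0, 5.5e-3)),
    BACKGROUND: ((1450.0, 70.0, 3.5e-1), (940.0, 80.0, 1.0e-1)),
}

# Minor-constituent nuisance components (ash, lignin, wax, residual moisture
# shifts ...): single Gaussian bands with per-sample N(0, weight) coefficients,
# in peak-absorbance units. They give the spectra a realistic number of
# variance directions that carry no information about CP/ADF/NDF.
_NUISANCE_BANDS: tuple[tuple[float, float, float], ...] = (
    # (center nm, width nm, per-sample coefficient SD in peak absorbance)
    (1450.0, 55.0, 3.0e-2),
    (1410.0, 40.0, 1.5e-2),
    (1130.0, 45.0, 8.0e-3),
    (1070.0, 40.0, 8.0e-3),
    (1260.0, 35.0, 1.0e-2),
    (1300.0, 60.0, 1.2e-2),
    (990.0, 45.0, 1.0e-2),
    (1585.0, 40.0, 8.0e-3),
    (1620.0, 55.0, 8.0e-3),
    (1040.0, 60.0, 6.0e-3),
)


@dataclass(frozen=True)
class NoiseParams:
    """Instrument and sample-presentation noise magnitudes.

    additive_sd          per-replicate absorbance noise SD (per wavelength)
    scatter_sd           per-replicate multiplicative reflectance scatter SD
    baseline_slope_sd    per-sample spread of the absorbance baseline slope
    group2_fraction      fraction of samples in the steeper-baseline group
    replicate_sd         per-replicate additive reflectance noise SD
    group2_slope         mean baseline slope of the steeper group (group 1
                         has mean slope 0); slope is total absorbance rise
                         across the grid span
    nuisance_sd          global scale on the nuisance-component coefficient
                         SDs (1.0 = the frozen per-band weights, 0 disables)
    """

    additive_sd: float = 5.0e-5
    scatter_sd: float = 1.0e-2
    baseline_slope_sd: float = 2.0e-2
    group2_fraction: float = 0.5
    replicate_sd: float = 2.0e-5
    group2_slope: float = 1.5e-1
    nuisance_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "scatter_sd", "baseline_slope_sd",
                     "replicate_sd", "nuisance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.group2_fraction <= 1.0:
            raise ValueError("group2_fraction must lie in [0, 1]")

    def is_noiseless(self) -> bool:
        return (
            self.additive_sd == 0
            and self.scatter_sd == 0
            and self.baseline_slope_sd == 0
            and self.replicate_sd == 0
            and self.group2_slope == 0
            and self.nuisance_sd == 0
        )


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to regenerate a dataset (besides the seed)."""

    n_samples: int = 203
    n_replicates: int = 3
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    populations: Mapping[str, PopulationParams] = field(
        default_factory=lambda: dict(TABLE1_POPULATIONS)
    )
    noise: NoiseParams = field(default_factory=NoiseParams)

    def provenance(self, seed: int) -> dict:
        return {
            "seed": int(seed),
            "n_samples": self.n_samples,
            "n_replicates": self.n_replicates,
            "grid": asdict(self.grid),
            "populations": {k: asdict(v) for k, v in self.populations.items()},
            "noise": asdict(self.noise),
        }


@dataclass
class SyntheticDataset:
    """Compositions plus replicate reflectance scans and the true mixing record."""

    sample_ids: list[str]
    compositions: pd.DataFrame        # index: sample id, columns: CP/ADF/NDF
    grid: SpectralGrid
    reflectance: np.ndarray           # (n_samples, n_replicates, n_points)
    seed: int
    mixing: dict                      # true absorbance, slopes, group labels...
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_replicates(self) -> int:
        return self.reflectance.shape[1]

    def mean_reflectance(self) -> np.ndarray:
        """Replicate-averaged reflectance, one row per sample."""
        return self.reflectance.mean(axis=1)


def _gaussian_bands(wavelengths: np.ndarray,
                    bands: tuple[tuple[float, float, float], ...]) -> np.ndarray:
    out = np.zeros_like(wavelengths, dtype=float)
    for center, width, height in bands:
        out += height * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return out


def pure_component_spectra(grid: SpectralGrid | None = None,
                           ) -> dict[str, PureComponentSpectrum]:
    """Absorptivity profiles for CP, ADF, NDF and the moisture background.

    Each profile is a fixed sum of Gaussian bands evaluated on ``grid``; the
    protein profile peaks near 1100 nm and the background near 1450 nm.
    """
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    return {
        name: PureComponentSpectrum(name, _gaussian_bands(wl, bands))
        for name, bands in _BAND_TABLES.items()
    }


def nuisance_spectra(grid: SpectralGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Unit-height nuisance band shapes and their coefficient SDs.

    Returns ``(shapes, weights)`` with ``shapes`` of shape
    ``(n_components, n_points)`` and ``weights`` the per-component
    coefficient SDs in peak-absorbance units.
    """
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    shapes = np.stack(
        [np.exp(-0.5 * ((wl - c) / w) ** 2) for c, w, _ in _NUISANCE_BANDS]
    )
    weights = np.array([s for _, _, s in _NUISANCE_BANDS])
    return shapes, weights


def sample_compositions(
    n: int,
    params: Mapping[str, PopulationParams] | None = None,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw ``n`` correlated CP/ADF/NDF compositions (% dry matter).

    Marginals are normal(mean, sd) truncated to [min, max] by rejection;
    cross-constituent dependence comes from a Gaussian copula with
    ``correlation`` (default :data:`DEFAULT_CORRELATION`). Deterministic
    given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = dict(params) if params is not None else dict(TABLE1_POPULATIONS)
    missing = [c for c in CONSTITUENTS if c not in params]
    if missing:
        raise ValueError(f"missing population params for {missing}")
    for p in params.values():
        if not isinstance(p, PopulationParams):
            raise TypeError("params values must be PopulationParams")

    corr = DEFAULT_CORRELATION if correlation is None else np.asarray(correlation)
    chol = np.linalg.cholesky(corr)
    means = np.array([params[c].mean for c in CONSTITUENTS])
    sds = np.array([params[c].sd for c in CONSTITUENTS])
    lo = np.array([params[c].min for c in CONSTITUENTS])
    hi = np.array([params[c].max for c in CONSTITUENTS])

    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    accepted = 0
    # rejection sampling: resample out-of-range draws rather than clipping,
    # so the truncation introduces no boundary atoms
    while accepted < n:
        batch = max(n - accepted, 64)
        z = rng.standard_normal((batch, 3)) @ chol.T
        x = means + sds * z
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        kept = x[ok]
        rows.append(kept)
        accepted += len(kept)
    values = (
        np.concatenate(rows)[:n] if rows else np.empty((0, 3))
    )
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(values, index=pd.Index(ids, name="sample_id"),
                        columns=list(CONSTITUENTS))


def synthesize_reflectance(
    compositions: pd.DataFrame,
    pure_spectra: Mapping[str, PureComponentSpectrum],
    noise: NoiseParams | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    grid: SpectralGrid | None = None,
) -> SyntheticDataset:
    """Render replicate reflectance scans for given compositions.

    True absorbance is the Beer-Lambert mixture
    ``A = sum_k c_k e_k + baseline`` with a per-sample affine baseline (the
    steeper-slope group is a ``group2_fraction`` subpopulation) plus nuisance
    components; each replicate's reflectance is ``10**(-A)`` under
    multiplicative scatter and additive noise, clipped to (0, 1].
    """
    noise = noise or NoiseParams()
    grid = grid or SpectralGrid()
    missing = [c for c in CONSTITUENTS if c not in pure_spectra]
    if missing:
        raise ValueError(f"pure_spectra missing components {missing}")
    comp = compositions[list(CONSTITUENTS)].to_numpy(dtype=float)
    if np.any(comp < 0):
        raise ValueError("compositions must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate scan")

    n, p = len(comp), grid.n_points
    e = np.stack([pure_spectra[c].coefficients for c in CONSTITUENTS])  # (3, p)
    if e.shape[1] != p:
        raise ValueError("pure spectra not on the requested grid")
    bg = (pure_spectra[BACKGROUND].coefficients
          if BACKGROUND in pure_spectra else np.zeros(p))

    rng = np.random.default_rng(seed)
    # fixed draw order below keeps regeneration bit-identical per seed
    group2 = rng.random(n) < noise.group2_fraction
    slopes = np.where(group2, noise.group2_slope, 0.0)
    slopes = slopes + noise.baseline_slope_sd * rng.standard_normal(n)
    ramp = (grid.wavelengths - grid.start_nm) / (grid.end_nm - grid.start_nm)

    nuis_shapes, nuis_weights = nuisance_spectra(grid)
    nuis_coeffs = (noise.nuisance_sd * nuis_weights
                   * rng.standard_normal((n, len(nuis_weights))))

    absorbance = comp @ e + bg[None, :]
    absorbance = absorbance + slopes[:, None] * ramp[None, :]
    absorbance = absorbance + nuis_coeffs @ nuis_shapes

    reflectance = np.empty((n, n_replicates, p))
    for r in range(n_replicates):
        a_rep = absorbance + noise.additive_sd * rng.standard_normal((n, p))
        scatter = 1.0 + noise.scatter_sd * rng.standard_normal((n, 1))
        r_rep = 10.0 ** (-a_rep) * scatter
        r_rep = r_rep + noise.replicate_sd * rng.standard_normal((n, p))
        reflectance[:, r, :] = np.clip(r_rep, 1e-12, 1.0)

    mixing = {
        "true_absorbance": absorbance,
        "baseline_slopes": slopes,
        "group2": group2,
        "nuisance_coefficients": nuis_coeffs,
        "background_concentration": np.ones(n),
    }
    return SyntheticDataset(
        sample_ids=list(compositions.index.astype(str)),
        compositions=compositions.copy(),
        grid=grid,
        reflectance=reflectance,
        seed=seed,
        mixing=mixing,
    )


def make_dataset(
    n: int = 203,
    seed: int = 0,
    config: DatasetConfig | None = None,
) -> SyntheticDataset:
    """Generate a complete survey-like dataset (chemistry + triplicate scans)."""
    config = config or DatasetConfig(n_samples=n)
    if config.n_samples != n:
        config = DatasetConfig(
            n_samples=n,
            n_replicates=config.n_replicates,
            grid=config.grid,
            populations=config.populations,
            noise=config.noise,
        )
    # independent child streams for chemistry and spectra
    comp_seed, spec_seed = np.random.SeedSequence(seed).generate_state(2) >> 1
    comp = sample_compositions(n, config.populations, seed=int(comp_seed))
    pure = pure_component_spectra(config.grid)
    ds = synthesize_reflectance(
        comp, pure, config.noise, seed=int(spec_seed),
        n_replicates=config.n_replicates, grid=config.grid,
    )
    ds.seed = seed
    ds.provenance = config.provenance(seed)
    return ds
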