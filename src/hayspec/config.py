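"""Run configuration: one validated object driving the end-to-end workflow."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .preprocess import PreprocessConfig
from .synthetic import (
    CONSTITUENTS,
    DatasetConfig,
    NoiseParams,
    PopulationParams,
    SpectralGrid,
    TABLE1_POPULATIONS,
)

#: Best-calibration factor counts per constituent.
TABLE2_COMPONENTS: dict[str, int] = {"CP": 8, "ADF": 7, "NDF": 10}

#: Best-calibration preprocessing per constituent: vector-normalized
#: absorbance, then a second derivative — Savitzky-Golay (3 points, order 2)
#: for CP, Norris gap-segment (segment 5, gap 2) for ADF and NDF.
TABLE2_PREPROCESS: dict[str, PreprocessConfig] = {
    "CP": PreprocessConfig(normalization="vector", derivative="savgol",
                           savgol_window=3, savgol_polyorder=2),
    "ADF": PreprocessConfig(normalization="vector", derivative="norris",
                            norris_segment=5, norris_gap=2),
    "NDF": PreprocessConfig(normalization="vector", derivative="norris",
                            norris_segment=5, norris_gap=2),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a benchmark or calibration run needs, validated up front."""

    seed: int = 1
    n_samples: int = 203
    n_replicates: int = 3
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    populations: Mapping[str, PopulationParams] = field(
        default_factory=lambda: dict(TABLE1_POPULATIONS))
    noise: NoiseParams = field(default_factory=NoiseParams)
    preprocess: Mapping[str, PreprocessConfig] = field(
        default_factory=lambda: dict(TABLE2_PREPROCESS))
    split_fraction: float = 0.75
    outlier_criterion_sd: float = 3.0
    methods: Sequence[str] = ("pls", "pcr", "mlr")
    component_policy: str = "fixed"           # "fixed" | "loo"
    fixed_components: Mapping[str, int] = field(
        default_factory=lambda: dict(TABLE2_COMPONENTS))
    max_components: int = 15
    mlr_n_wavelengths: int = 2
    constituents: Sequence[str] = CONSTITUENTS
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.constituents if c not in CONSTITUENTS]
        if unknown:
            raise ValueError(f"unknown constituents {unknown}")
        for c in self.constituents:
            if c not in self.preprocess:
                raise ValueError(f"no preprocessing configured for {c}")
            if c not in self.fixed_components:
                raise ValueError(f"no component count configured for {c}")
        if self.component_policy not in ("fixed", "loo"):
            raise ValueError("component_policy must be 'fixed' or 'loo'")
        bad = [m for m in self.methods if m not in ("pls", "pcr", "mlr")]
        if bad:
            raise ValueError(f"unknown methods {bad}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.max_components < 1 or self.mlr_n_wavelengths < 1:
            raise ValueError("max_components and mlr_n_wavelengths must be >= 1")

    def split_seed(self) -> int:
        """Split stream decoupled from the generator stream, below 2**31."""
        return int(np.random.SeedSequence([self.seed, 7919]).generate_state(1)[0] >> 1)

    def dataset_config(self) -> DatasetConfig:
        return DatasetConfig(
            n_samples=self.n_samples, n_replicates=self.n_replicates,
            grid=self.grid, populations=dict(self.populations), noise=self.noise,
        )

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "n_replicates": self.n_replicates,
            "grid": asdict(self.grid),
            "populations": {k: asdict(v) for k, v in self.populations.items()},
            "noise": asdict(self.noise),
            "preprocess": {k: asdict(v) for k, v in self.preprocess.items()},
            "split_fraction": self.split_fraction,
            "outlier_criterion_sd": self.outlier_criterion_sd,
            "methods": list(self.methods),
            "component_policy": self.component_policy,
            "fixed_components": dict(self.fixed_components),
            "max_components": self.max_components,
            "mlr_n_wavelengths": self.mlr_n_wavelengths,
            "constituents": list(self.constituents),
            "output_dir": self.output_dir,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], Mapping):
            d["grid"] = SpectralGrid(**d["grid"])
        if "populations" in d:
            d["populations"] = {
                k: (v if isinstance(v, PopulationParams) else PopulationParams(**v))
                for k, v in d["populations"].items()
            }
        if "noise" in d and isinstance(d["noise"], Mapping):
            d["noise"] = NoiseParams(**d["noise"])
        if "preprocess" in d:
            d["preprocess"] = {
                k: (v if isinstance(v, PreprocessConfig) else PreprocessConfig(**v))
                for k, v in d["preprocess"].items()
            }
        for key in ("methods", "constituents"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
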