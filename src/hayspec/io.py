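"""File I/O: spectra and chemistry CSVs, JCAMP-DX reading, provenance JSON.

On-disk layout for a run: one spectra matrix CSV (row = sample-replicate;
columns ``sample_id, replicate, <wavelength nm>...``), one chemistry CSV
(``sample_id, CP, ADF, NDF``), one YAML config, plus JSON sidecars for
models and provenance. Numeric CSV cells are written with 17 significant
digits so round-tripping preserves values to 1e-12 relative.

JCAMP-DX is supported read-only for single spectra in the common AFFN
``##XYDATA=(X++(Y..Y))`` form, the interchange format most NIR instruments
export; spectra are linearly resampled onto the declared grid when their
axis is within one grid step of alignment, and rejected otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CONSTITUENTS, SpectralGrid, SyntheticDataset

_FLOAT_FMT = "%.17g"


def write_spectra_csv(path: str | Path, dataset: SyntheticDataset) -> None:
    """Spectra matrix CSV: one row per (sample, replicate) scan."""
    wl = dataset.grid.wavelengths
    n, n_rep, p = dataset.reflectance.shape
    rows = dataset.reflectance.reshape(n * n_rep, p)
    df = pd.DataFrame(rows, columns=[f"{w:g}" for w in wl])
    df.insert(0, "replicate", np.tile(np.arange(1, n_rep + 1), n))
    df.insert(0, "sample_id", np.repeat(dataset.sample_ids, n_rep))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, SpectralGrid]:
    """Read a spectra matrix CSV; returns (id/replicate frame, R, grid).

    ``R`` has one row per scan, aligned with the frame's rows. Rejects
    ragged or non-numeric data and non-uniform wavelength headers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path.name}: missing 'sample_id' column")
    if "replicate" not in df.columns:
        df.insert(1, "replicate", 1)
    wl_cols = [c for c in df.columns if c not in ("sample_id", "replicate")]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric wavelength header: {exc}") from exc
    steps = np.diff(wl)
    if len(wl) < 2 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError(f"{path.name}: wavelength axis must be uniform and ascending")
    values = df[wl_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values).any():
        bad = df.index[np.isnan(df[wl_cols].apply(
            pd.to_numeric, errors="coerce").to_numpy()).any(axis=1)]
        raise ValueError(
            f"{path.name}: non-numeric or missing cells in data rows {list(bad[:5])}"
        )
    grid = SpectralGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    return df[["sample_id", "replicate"]].copy(), values.astype(float), grid


def spectra_frame_to_replicates(meta: pd.DataFrame, R: np.ndarray
                                ) -> tuple[list[str], np.ndarray]:
    """Group scan rows by sample id into an (n, n_rep, p) array."""
    ids = list(dict.fromkeys(meta["sample_id"].astype(str)))
    counts = meta["sample_id"].value_counts()
    n_rep = int(counts.iloc[0])
    if not (counts == n_rep).all():
        raise ValueError("samples have unequal replicate counts")
    order = {s: i for i, s in enumerate(ids)}
    reps = np.zeros(len(ids), dtype=int)
    out = np.empty((len(ids), n_rep, R.shape[1]))
    for row, sid in enumerate(meta["sample_id"].astype(str)):
        i = order[sid]
        out[i, reps[i]] = R[row]
        reps[i] += 1
    return ids, out


def write_chemistry_csv(path: str | Path, compositions: pd.DataFrame) -> None:
    compositions.to_csv(path, index=True, float_format=_FLOAT_FMT)


def read_chemistry_csv(path: str | Path) -> pd.DataFrame:
    """Chemistry CSV -> composition table (% dry matter), indexed by sample id."""
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path.name}: missing 'sample_id' column")
    missing = [c for c in CONSTITUENTS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing constituent columns {missing}")
    df = df.set_index("sample_id")
    vals = df[list(CONSTITUENTS)].apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise ValueError(f"{path.name}: non-numeric chemistry values")
    if (vals < 0).any().any():
        bad = vals.index[(vals < 0).any(axis=1)]
        raise ValueError(f"{path.name}: negative values for samples {list(bad[:5])}")
    return vals


def join_spectra_chemistry(ids: list[str], chemistry: pd.DataFrame
                           ) -> pd.DataFrame:
    """Align chemistry rows to spectra sample ids; lists any unmatched ids."""
    missing = [s for s in ids if s not in chemistry.index]
    extra = [s for s in chemistry.index.astype(str) if s not in set(ids)]
    if missing:
        raise ValueError(f"chemistry missing for spectra ids {missing[:10]}")
    if extra:
        raise ValueError(f"chemistry ids without spectra: {extra[:10]}")
    return chemistry.loc[ids]


# -- JCAMP-DX (read-only) ----------------------------------------------

def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse one JCAMP-DX spectrum (AFFN ``(X++(Y..Y))``); returns (x, y)."""
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise ValueError(
                        f"{path.name}:{lineno}: only (X++(Y..Y)) XYDATA supported")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val
            in_data = False
        elif in_data:
            data_lines.append((lineno, line))
    if not data_lines:
        raise ValueError(f"{path.name}: no XYDATA table found")
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in data_lines:
        parts = line.replace(",", " ").split()
        try:
            nums = [float(t) for t in parts]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-numeric datum: {exc}") from exc
        if len(nums) < 2:
            raise ValueError(f"{path.name}:{lineno}: data line needs X plus Y values")
        xs.append(nums[0] * xfactor)
        ys.extend(v * yfactor for v in nums[1:])
    # the axis is uniform from FIRSTX to LASTX; line-start X values are checks
    n = len(ys)
    first = float(header.get("FIRSTX", xs[0]))
    last = float(header.get("LASTX", xs[-1]))
    npoints = int(header.get("NPOINTS", n))
    if npoints != n:
        raise ValueError(f"{path.name}: NPOINTS={npoints} but {n} Y values read")
    x = np.linspace(first, last, n)
    return x, np.asarray(ys)


def read_jcamp_dir(path: str | Path, grid: SpectralGrid
                   ) -> tuple[list[str], np.ndarray]:
    """Read every ``.jdx``/``.dx`` file in a directory onto ``grid``.

    Each spectrum must cover the grid and be within one grid step of
    alignment; accepted spectra are linearly interpolated onto the grid.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".jdx", ".dx"))
    if not files:
        raise ValueError(f"{path}: no .jdx/.dx files found")
    wl = grid.wavelengths
    ids, rows = [], []
    for f in files:
        x, y = read_jcamp(f)
        if x[0] > x[-1]:
            x, y = x[::-1], y[::-1]
        if x[0] > wl[0] + grid.step_nm or x[-1] < wl[-1] - grid.step_nm:
            raise ValueError(
                f"{f.name}: axis {x[0]:g}-{x[-1]:g} nm misaligned with grid "
                f"{wl[0]:g}-{wl[-1]:g} nm by more than one step")
        rows.append(np.interp(wl, x, y))
        ids.append(f.stem)
    return ids, np.vstack(rows)


def write_provenance(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
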