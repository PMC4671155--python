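# hayspec

Chemometrics for near-infrared (NIR) forage-hay analysis, with a seeded
synthetic data generator so the entire pipeline is testable end to end
without instrument data.

## The problem

Wet-chemistry assays of hay quality — crude protein (CP), acid detergent
fiber (ADF) and neutral detergent fiber (NDF), all in percent dry matter —
are slow and destructive. NIR reflectance spectroscopy predicts them in
seconds, but only after a calibration links spectra to reference chemistry.
`hayspec` implements that calibration workflow:

1. **Simulate** a survey-scale dataset: 203 samples with correlated
   CP/ADF/NDF values and triplicate reflectance scans on a 950–1650 nm grid
   (5 nm steps, 141 points), from a Beer–Lambert-style mixing model with
   known ground truth.
2. **Preprocess**: average replicates, convert reflectance to absorbance,
   normalize, and take second derivatives (Savitzky–Golay or Norris
   gap-segment filters).
3. **Screen outliers** by Mahalanobis distance in principal-component score
   space (flag at mean + 3 SD, single pass).
4. **Calibrate** with three methods: two-wavelength multiple linear
   regression (MLR), principal component regression (PCR), and partial
   least squares (PLS1, NIPALS).
5. **Validate** on a held-out 25% split with RMSEC/RMSEP, R², r², and
   RPD = SD(validation)/RMSEP, banded as good (≥ 2), acceptable (1.4–2),
   or unreliable (< 1.4).

## The model

Each sample's true absorbance is a linear mixture

```
A(λ) = Σₖ cₖ · eₖ(λ) + baseline(λ)
```

where the `cₖ` are the constituent concentrations (% DM), the `eₖ(λ)` are
fixed Gaussian-band pure-component coefficients, and the baseline is a
per-sample affine slope (steeper for one of two spectral groups).
Reflectance per replicate scan is `R = 10^(−A)` perturbed by multiplicative
scatter and additive noise; analysis inverts this with `A = log10(1/R)`.
Calibration then fits `ŷ = b₀ + Σⱼ bⱼ xⱼ` on the preprocessed spectra,
with MLR/PCR/PLS differing in how they constrain the coefficients.
See [docs/methods.md](docs/methods.md) for assumptions and parameters.

## Worked example

```python
import hayspec as hs

ds = hs.make_dataset(n=203, seed=1)                      # known chemistry
A = hs.to_absorbance(ds.mean_reflectance())
X, _ = hs.preprocess_spectra(A, ds.grid.wavelengths, hs.TABLE2_PREPROCESS["CP"])
y = ds.compositions["CP"].to_numpy()

split = hs.split_cal_val(len(y), 0.75, seed=42)          # 152 / 51
X_cal, y_cal, _ = hs.remove_outliers(X[split.calibration], y[split.calibration])
k = hs.select_n_components(X_cal, y_cal, "pls", max_pc=15)
model = hs.fit_pls(X_cal, y_cal, k)

pred = hs.predict(model, X[split.validation])
y_val = y[split.validation]
print(hs.rmse(y_val, pred), hs.r2(y_val, pred), hs.rpd(y_val.std(ddof=1), hs.rmse(y_val, pred)))
```

This is `examples/03_calibrate_and_validate.py` in condensed form; running
that script prints

```
RMSEC 0.085 %DM   RMSEP 0.326 %DM   validation r2 0.950
RPD = SD_val/RMSEP = 1.200/0.326 = 3.68 (good)
```

The other scripts in [examples/](examples/) cover simulation, preprocessing
and outlier screening, and the full 3 × 3 method benchmark;
`examples/04_benchmark_methods.py` ends with

```
  CP   PLS 0.384  PCR 0.403  MLR 0.512   ->  PLS <= PCR <= MLR
  ADF  PLS 0.948  PCR 1.280  MLR 1.349   ->  PLS <= PCR <= MLR
  NDF  PLS 0.583  PCR 1.780  MLR 1.953   ->  PLS <= PCR <= MLR
```

i.e. the full-spectrum latent-variable methods beat the two-wavelength
regression, and PLS edges out PCR.

There is also a CLI mirroring the pipeline stages:

```bash
hayspec simulate --n 203 --seed 1 --out run/
hayspec benchmark --n 203 --seed 1 --out run/
```

## Layout

- `src/hayspec/` — library: `synthetic`, `preprocess`, `outliers`,
  `regression`, `validation`, `io`, `config`, `cli`
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property and acceptance tests
- `scripts/acceptance.py` — standalone recomputation of headline numbers
- `docs/methods.md` — model, parameters, numerical choices, limitations
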