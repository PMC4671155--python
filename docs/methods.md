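# Methods

This note documents the statistical model behind `hayspec`, the frozen
default parameters, the numerical choices, and the known limitations. All
quantitative claims here are computed by the test suite
(`tests/`) or by `scripts/acceptance.py`; nothing is asserted that those do
not check.

## 1. Data model

### Chemistry

Per sample, the three constituents (CP, ADF, NDF, % dry matter) are drawn
jointly: a latent trivariate normal with correlation

|        | CP   | ADF  | NDF  |
|--------|------|------|------|
| CP     | 1    | −0.4 | −0.4 |
| ADF    | −0.4 | 1    | +0.6 |
| NDF    | −0.4 | +0.6 | 1    |

is scaled by each constituent's population mean/SD and rejection-sampled
(whole vectors redrawn, never clipped, so the bounds carry no probability
atoms) until all three values lie inside their `[min, max]` boxes.
Defaults (`TABLE1_POPULATIONS`), chosen to resemble a managed-grassland hay
survey:

| constituent | min | max | mean | SD | units |
|---|---|---|---|---|---|
| CP  | 6.20  | 14.33 | 10.54 | 1.24 | % DM |
| ADF | 35.13 | 42.34 | 38.74 | 2.33 | % DM |
| NDF | 50.71 | 71.08 | 60.89 | 2.67 | % DM |

**Truncation caveat.** The configured SDs parameterize the *parent* normal,
not the realized draws. The ADF box spans only ±1.55 parent SDs, and no
distribution in the truncated-normal family on [35.13, 42.34] can exceed
the uniform-limit SD of ≈ 2.08 < 2.33, so the realized ADF SD is ≈ 1.77 by
construction; the joint rejection also shrinks the NDF marginal SD ≈ 9%
through its correlation with ADF. Realized *means* track the configured
means closely (within ±0.02 % DM over 50 × 203 draws). The distribution-
fidelity test therefore compares ensemble moments against an independent
re-implementation of the declared sampler, plus a direct check on the
configured means.

### Spectra

True absorbance is a linear Beer–Lambert-style mixture on the 950–1650 nm
grid (5 nm steps, 141 points):

```
A_i(λ) = Σ_k c_ik · e_k(λ) + Σ_m u_im · g_m(λ) + baseline_i(λ)
```

- `e_k(λ)`: pure-component coefficient spectra for CP/ADF/NDF plus a
  constant background component, each a sum of 2–4 Gaussian bands
  (centers 940–1620 nm, widths 30–80 nm, amplitudes in absorbance units
  per % DM). Fixed package constants.
- `g_m(λ)`: ten fixed nuisance bands with per-sample standard-normal
  coefficients `u_im` (scaled by `nuisance_sd`). These model co-varying
  matrix constituents (moisture, starch, ash) that are *not* reference
  values: structured interference that a purely additive-noise model
  lacks.
- `baseline_i(λ)`: per-sample affine slope. Samples split into two groups
  (fraction `group2_fraction`); group 2's slope mean is `group2_slope`
  (total absorbance rise across the grid), both groups jittered by
  `baseline_slope_sd`. This emulates the two spectral clusters that
  particle-size/presentation differences produce.

Each of the 3 replicate scans is `R = clip(10^(−A)·(1+s) + ε, (0, 1])` with
multiplicative scatter `s ~ N(0, scatter_sd²)` per scan and additive
reflectance noise; absorbance-domain noise `N(0, additive_sd²)` is added
per wavelength before exponentiation.

### Frozen noise defaults

| parameter | default | units | role |
|---|---|---|---|
| `additive_sd` | 5·10⁻⁵ | AU | per-replicate, per-wavelength absorbance noise |
| `scatter_sd` | 1·10⁻² | relative | multiplicative reflectance scatter per scan |
| `baseline_slope_sd` | 2·10⁻² | AU/span | per-sample baseline-slope jitter |
| `group2_fraction` | 0.5 | — | share of steeper-baseline samples |
| `group2_slope` | 0.15 | AU/span | mean extra slope of group 2 |
| `replicate_sd` | 2·10⁻⁵ | reflectance | additive noise per scan |
| `nuisance_sd` | 1.0 | — | global scale on nuisance-band coefficients |

These constants (and the band tables) were tuned **once**, offline, so that
the end-to-end pipeline lands in realistic accuracy bands, then frozen.
Two tuning constraints are worth recording. First, the second-derivative
filters amplify white absorbance noise (the 3-point filter by ≈ √6), so
`additive_sd` is the binding constant for CP accuracy. Second, the method
ranking PLS ≤ PCR ≤ MLR on validation RMSEP only emerges when interference
is *structured*: with isotropic noise alone, PCR's variance-ranked
components match PLS's covariance-directed ones. The nuisance bands supply
that structure while keeping the total latent dimension (≈ 14) below the
LOO component cap (15).

## 2. Pipeline conventions

- **Absorbance:** `A = log10(1/R)`; replicates averaged in reflectance
  before conversion.
- **Normalization:** vector (unit ℓ₂ norm) by default; min-max and
  zero-mean ("zero") also provided.
- **Derivatives:** Savitzky–Golay (window 3, polyorder 2, 2nd derivative —
  numerically the central second difference) for CP; Norris gap-segment
  (segment 5, gap 2) for ADF/NDF. Both are computed in index units (one
  step = 5 nm) and trim the unsupported spectrum edges rather than padding,
  so preprocessed matrices have 139 (SG) or 133 (Norris) columns.
- **Outliers:** PCA scores (top 8 by default), Mahalanobis distance to the
  score centroid, flag at `mean(d) + 3·sd(d)`. Single pass, X-space only —
  no re-screening after removal and no y-based screening.
- **Split:** random, seeded, `n_cal = round(0.75·n)` → 152/51 at n = 203;
  shared across constituents and methods within a benchmark. Outlier
  screening applies to the calibration set only; validation samples are
  never removed.
- **Calibration:** MLR selects 2 wavelengths greedily from the correlation
  spectrum (argmax |r|, then best joint R²) and fits OLS; PCR regresses on
  SVD scores; PLS1 uses NIPALS with deflation, coefficients folded to the
  original wavelength basis via `β = W(PᵀW)⁻¹q`.
- **Component counts:** two policies. `fixed` (default) uses 8/7/10
  components for CP/ADF/NDF; `loo` picks the count minimizing leave-one-out
  RMSE on the calibration set, capped at 15, ties to the smaller count.
- **Metrics:** RMSEC/RMSEP with 1/n normalization; R² (calibration) and r²
  (validation) are squared Pearson correlations of reference vs predicted
  (scatter-plot convention); `r2_sse` (1 − SSE/SST) is also reported since
  the two diverge for biased predictions. RPD = SD(validation references,
  ddof = 1)/RMSEP, banded good ≥ 2 > acceptable ≥ 1.4 > unreliable.

## 3. Numerical choices

- float64 throughout; PCA/PCR via `numpy.linalg.svd` (no covariance
  matrices formed). NIPALS tolerance 1e-10 on the weight vector, max 500
  iterations, early stop when the residual covariance `Xᵀy` vanishes (the
  model then reports the realized component count).
- LOO component selection does one decomposition per fold and evaluates
  every `k ≤ max_pc` from it, rather than refitting per (fold, k); a test
  verifies equality with naive refits.
- Mahalanobis screening rejects score covariances with condition number
  > 1e12 ("singular") instead of silently pseudo-inverting.
- Seeding: all randomness flows from `numpy.random.SeedSequence`; child
  seeds are spawned for chemistry vs spectra so datasets are byte-identical
  given `(seed, config)`. Derived seeds are right-shifted below 2³¹ for
  portability.
- CSV numerics are written with 17 significant digits (lossless for
  float64); JCAMP-DX is read-only, AFFN `(X++(Y..Y))` form, with axis
  misalignment beyond one grid step rejected and within-step offsets
  linearly interpolated.

## 4. What the generator does and does not emulate

Emulates: survey-like constituent ranges and correlations; overtone-region
band structure with a dominant ~1450 nm background band; two baseline
groups; replicate-level instrument noise; structured co-varying
interference.

Does not emulate: instrument temperature drift, moisture re-absorption
during scanning, particle-size physics beyond the affine
baseline/multiplicative scatter terms, detector nonlinearity, wavelength
miscalibration, or real forage band assignments (band positions are
plausible but synthetic).

## 5. Open design decisions

- **RPD convention.** Published forage-NIRS tables sometimes print RPD
  values that cannot be reproduced from their own SD and RMSEP columns.
  `hayspec` computes RPD strictly as SD(validation)/RMSEP and reports the
  inputs alongside, so the arithmetic is auditable.
- **Component counts.** Reported optima in the literature vary with the
  selection protocol (fixed table values vs cross-validated). Both
  policies ship; the default benchmark uses the fixed 8/7/10 counts while
  the acceptance script uses LOO selection. Neither is claimed optimal.
- **r² vs 1 − SSE/SST.** Validation "r²" follows the scatter-plot
  (squared-correlation) convention common in NIRS papers; both values are
  reported because they differ under bias.
- **ADF population SD.** See the truncation caveat in §1: the configured
  parent SD is not attainable post-truncation, a latent inconsistency in
  survey-style (min, max, mean, SD) parameterizations that this
  implementation resolves in favor of honoring the bounds.

## 6. Limitations

- Synthetic-only validation: accuracy bands demonstrate internal
  consistency of the pipeline, not instrument performance on real hay.
- The PLS ≤ PCR ≤ MLR ranking is a property of the frozen generator
  (structured interference, modest noise); it is checked as a
  majority-of-seeds statement, not per-seed.
- MLR wavelength selection is greedy with an exhaustive-pair cross-check in
  tests; for more than 2 wavelengths the greedy result may be suboptimal.
- The outlier rule is the single-pass score-space rule only; masked
  multi-outlier configurations (e.g., symmetric pairs along one direction)
  can escape it.
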