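"""Calibrate a PLS model for crude protein and validate it on held-out samples.

Splits 203 samples 152/51, picks the PLS component count by leave-one-out
cross-validation on the calibration set, and scores prediction quality with
RMSEP, r-squared and RPD.
"""

import hayspec as hs

ds = hs.make_dataset(n=203, seed=1)
A = hs.to_absorbance(ds.mean_reflectance())
X, _ = hs.preprocess_spectra(A, ds.grid.wavelengths, hs.TABLE2_PREPROCESS["CP"])
y = ds.compositions["CP"].to_numpy()

split = hs.split_cal_val(len(y), 0.75, seed=42)
X_cal, y_cal = X[split.calibration], y[split.calibration]
X_val, y_val = X[split.validation], y[split.validation]
print(f"split: {len(split.calibration)} calibration / {len(split.validation)} validation")

X_cal, y_cal, rep = hs.remove_outliers(X_cal, y_cal, n_scores=8)
print(f"outliers removed from calibration set: {rep.n_flagged}")

k = hs.select_n_components(X_cal, y_cal, "pls", max_pc=15)
model = hs.fit_pls(X_cal, y_cal, k)
print(f"LOO-selected PLS components: {k}")

rmsec = hs.rmse(y_cal, hs.predict(model, X_cal))
pred = hs.predict(model, X_val)
rmsep = hs.rmse(y_val, pred)
r2_val = hs.r2(y_val, pred)
sd_val = y_val.std(ddof=1)
rpd_value, band = hs.rpd(sd_val, rmsep)

print(f"\nRMSEC {rmsec:.3f} %DM   RMSEP {rmsep:.3f} %DM   "
      f"validation r2 {r2_val:.3f}")
print(f"RPD = SD_val/RMSEP = {sd_val:.3f}/{rmsep:.3f} = {rpd_value:.2f} ({band})")
# An RPD above 2 means prediction error is small next to the natural
# spread of the validation samples — the calibration is usable for
# quantitative crude-protein screening.
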