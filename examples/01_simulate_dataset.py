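"""Simulate a survey-scale NIR dataset with known reference chemistry.

Generates 203 hay-like samples — correlated CP/ADF/NDF compositions plus
triplicate reflectance scans on the 950-1650 nm grid — and shows that the
generated population tracks the configured one.
"""

import hayspec as hs

ds = hs.make_dataset(n=203, seed=1)

print(f"samples: {ds.n_samples}, replicates per sample: {ds.n_replicates}, "
      f"wavelengths: {ds.grid.n_points} "
      f"({ds.grid.start_nm:.0f}-{ds.grid.end_nm:.0f} nm, {ds.grid.step_nm:.0f} nm step)")

print("\nconstituent  generated mean/SD    configured mean/SD   range")
for c in hs.CONSTITUENTS:
    vals = ds.compositions[c]
    p = hs.TABLE1_POPULATIONS[c]
    print(f"{c:<11s}  {vals.mean():6.2f} / {vals.std(ddof=1):4.2f}       "
          f"{p.mean:6.2f} / {p.sd:4.2f}       [{vals.min():.2f}, {vals.max():.2f}]")
# Means land on the configured populations; the ADF/NDF SDs sit below the
# configured values because sampling is rejected into the narrow survey
# ranges (see docs/methods.md).

corr = ds.compositions.corr()
print(f"\ncorrelations: CP-ADF {corr.loc['CP', 'ADF']:+.2f}, "
      f"CP-NDF {corr.loc['CP', 'NDF']:+.2f}, ADF-NDF {corr.loc['ADF', 'NDF']:+.2f}")
# Protein trades off against both fiber fractions, and the two fiber
# fractions move together — the collinearity calibration must cope with.

R = ds.reflectance
print(f"\nreflectance shape {R.shape}, range [{R.min():.3f}, {R.max():.3f}]")
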