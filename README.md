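# ftirbind

FTIR band-shift analysis of a protein–DNA interaction, implemented end to
end for the Endonuclease III (EndoIII) / double-stranded DNA system.
EndoIII is a base-excision-repair glycosylase carrying a [4Fe4S] cluster;
when it binds DNA, vibrational bands of both partners shift, split or
vanish, and those spectral changes carry information about the binding
geometry and energetics.

The package is for spectroscopists and computational biochemists who want
a tested, reproducible version of this inference chain:

1. **Band tracking** — baseline correction, Savitzky–Golay second
   derivatives (band centers appear as sharpened minima, resolving
   overlapped peaks), peak detection, and native↔complex peak matching.
   Marquee observations on the packaged spectra: the far-IR Fe–S
   (thiolate) stretch of the cluster downshifts 362 → 352 cm⁻¹, the
   amide-I band moves down by 3 cm⁻¹, and the DNA deoxyribose (890 cm⁻¹)
   and O–P–O (967 cm⁻¹) bands disappear.
2. **Shift → distance model** — the electrostatic interaction energy *E*
   is taken proportional to the observed frequency shift Δν = |ν − ν₀|
   and inversely proportional to the enzyme–DNA separation *r* (Å),
   giving the one-parameter inverse law **r = k / Δν**. A single global
   *k* is calibrated by anchoring the largest shift to the 7.0 Å closest
   approach; estimates are capped at 16 Å (the top of the inferred
   distance distribution), with caps flagged.
3. **Regression** — a closed-form ridge regressor (α = 1.0, intercept
   unpenalized) and a fixed 2-5-1 ReLU network predict binding distance
   from two normalized spectral features (native and complex band
   descriptors), validated with an 80/20 split and 5-fold
   cross-validation (MSE, R²).
4. **Thermodynamics** — ΔG = −RT ln K_d (R = 8.314 J/(mol·K)) and
   ΔS = (ΔH − ΔG)/T, applied literally with K_d = 10 μM, T = 298 K and
   ΔH = −30.00 kJ/mol.
5. **Structure** — [4Fe4S] cubane geometry (12 core + 4 cysteine-thiolate
   Fe–S bonds with per-class length statistics) and the *n* shortest
   protein–DNA atomic distances from PDB coordinates, histogrammed for
   comparison with the spectroscopy-derived distance range.

No instrument data ship with the package: a synthetic-spectrum generator
(`ftirbind.synthetic_spectra`) encodes the band inventory of dsDNA,
EndoIII and their complex — positions, complex-state shifts and
disappearances, widths, baseline drift and seeded noise — so every stage
is testable and reproducible from a single seed. Synthetic PDB fixtures
(an ideal cubane, a toy protein–DNA complex) play the same role for the
structure stage.

## Worked example

The analysis drivers under `analysis/` run each stage on the packaged
defaults and write their tables under `results/`:

```bash
python analysis/02_band_shifts.py
```

```
shifted bands:
  far-IR Fe-S thiolate                    362.0 ->   352.1 cm^-1  |dnu| = 9.93
  mid-IR phosphate backbone              1055.0 ->  1052.1 cm^-1  |dnu| = 2.98
  mid-IR amide-I                         1653.0 ->  1650.2 cm^-1  |dnu| = 2.84
  ...
disappeared bands:
  mid-IR deoxyribose ring               nu0 =   890.1
  mid-IR O-P-O bending                  nu0 =   966.3
```

The thiolate mode is recovered within 0.1 cm⁻¹ of its true 10 cm⁻¹
downshift; the amide-I shift lands at 2.8 cm⁻¹ against the modelled
3 cm⁻¹ (sub-grid peak interpolation under 1% noise). Feeding these
shifts to the distance model:

```bash
python analysis/03_distance_model.py
```

```
calibration: k = 69.49 Å·cm⁻¹ (anchor 7.0 Å, cap 16.0 Å)
  Fe-S thiolate                  dnu =  9.93 cm^-1  ->  r =  7.00 Å
  amide-I                        dnu =  2.84 cm^-1  ->  r = 16.00 Å (capped)
  ...
distance range: [7.00, 16.00] Å over 6 bands
```

The strongly perturbed thiolate band maps to the 7.0 Å closest approach
and weakly perturbed bands are capped at 16 Å — the distance
distribution spans exactly the 7.0–16 Å range the shift analysis
implies. Thermodynamics:

```bash
python analysis/05_thermodynamics.py
```

```
Kd = 1.0e-05 M, T = 298 K, dH = -30.00 kJ/mol
dG = 28.52 kJ/mol
dS = -196.39 J/(mol·K)
```

(ΔG is positive because −RT ln K_d is applied literally with K_d < 1 M;
the JSON output carries a convention note.) Parameter recovery for the
regressors (`analysis/04_regression.py`, noiseless forward-model data,
80 samples) gives held-out R² = 0.9951 for the 2-5-1 network and 0.94
for unpenalized least squares — the inverse-law target is nonlinear in
the band-position features, and ridge at α = 1.0 additionally shrinks
away the near-collinear difference direction that carries the signal.

A single `ftirbind` console command wraps the same stages
(`ftirbind simulate | shifts | distances | train | thermo | structure |
report`); `ftirbind report --seed 20 --out run/` writes every artifact
of the full chain with a config hash for provenance.

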