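# Methods

This note documents the models, defaults and design choices behind
`ftirbind`, and what the synthetic data can and cannot establish.

## Forward model of the spectra

A spectrum is a sum of band lineshapes on a wavenumber grid, plus a
polynomial baseline (degree ≤ 2, evaluated on the grid rescaled to
[0, 1]) and additive gaussian noise:

    A(ν) = Σᵢ aᵢ · L(ν; νᵢ, wᵢ) + baseline(ν) + ε,   ε ~ N(0, σ²)

* **Lineshape** — pseudo-Voigt with mixing η = 0.5 by default:
  condensed-phase IR bands fall between the gaussian and lorentzian
  limits. Pure gaussian and lorentzian shapes are available and the
  gaussian is used wherever a test needs a closed-form area or second
  derivative.
* **Grid** — 1 cm⁻¹ step by default (far-IR 100–700 cm⁻¹, mid-IR
  600–1800 cm⁻¹, which covers the full band inventory; the instrument's
  nominal 4 cm⁻¹ resolution is available as a coarser `grid_step`).
  Analytic tests use 0.1 cm⁻¹ where sub-grid accuracy matters.
* **Widths** — band widths are not constrained by the band inventory, so the
  defaults are editorial: FWHM 12 cm⁻¹ (far-IR) and 20 cm⁻¹ (mid-IR), chosen so that
  the 362/392 cm⁻¹ pair overlaps enough that second-derivative
  sharpening genuinely matters, while all inventory bands remain
  resolvable.
* **Noise** — σ defaults to 1% of the largest band amplitude of the
  species generated. Each (seed, species, range) triple gets its own
  deterministic stream, so native and complex spectra carry independent
  noise while the whole dataset reproduces bit-identically from one
  seed.
* **Band inventory** — dsDNA: 720, 780, 782, 890, 967, 1055 (alias
  1060), 1110, 1213, 1281, 1329, 1376 cm⁻¹; EndoIII: amide-I 1653 cm⁻¹
  (mid-IR) and Fe–S modes 443, 392, 362, 326 cm⁻¹ (far-IR). Complex
  edits: amide-I → 1650; thiolate 362 → 352; 890 and 967 removed;
  780 → 778 and 1055 → 1052 (small backbone shifts); 1376 replaced by
  two half-amplitude sub-bands at 1370/1382 cm⁻¹ ("distorted into
  several smaller peaks" — count and offsets configurable). Relative
  amplitudes are editorial (0.5–1.0). The 780/782 cm⁻¹ entries are kept
  as two distinct bands; at the default widths they merge into one
  detected feature, which is the physically expected behaviour.
  One source section cites the thiolate shift as 363 → 353 cm⁻¹ where
  the main band table says 362 → 352; the library uses 362 → 352 and
  this note records the 1 cm⁻¹ discrepancy.

What the generator does **not** emulate: ATR penetration-depth effects,
detector response, atmospheric water/CO₂ lines, scattering baselines,
band asymmetry, or chemical imaging. Tests passing on these spectra
show the *analysis chain* is correct under the stated statistical
structure — they do not certify performance on real instrument data
with structured artifacts.

## Preprocessing

* **Baseline** — iterative polynomial (degree 0–2, default 1): fit,
  mask points more than 2 residual SDs *above* the fit (band regions),
  refit, repeat until the mask stabilises (≤ 30 rounds). Masking only
  the positive side lets the fit settle on the band-free baseline, makes
  the residual mean zero over peak-free regions, and makes the operation
  idempotent to ~1e-6 — a fixed two-round scheme leaves band-tail bias
  three orders of magnitude larger, which is why the iterated variant
  was adopted.
* **Second derivative** — Savitzky–Golay, polynomial order 3, window 17
  points. A narrower 11-point window preserves band shape slightly
  better but transmits enough noise at the default σ that band centers
  jitter by > 1 cm⁻¹ and spurious minima appear; 17 points on a 1 cm⁻¹
  grid still spans only ~1.4× the narrowest FWHM and keeps every
  inventory band resolved.
* **Peak picking** — minima of the second derivative whose prominence is
  ≥ 0.35 × the deepest minimum's prominence (window-restricted when a
  range window such as 300–460 cm⁻¹ is given), refined to sub-grid
  precision by a three-point parabola. The 0.35 fraction rejects
  noise-induced minima at σ = 1% while keeping the weakest inventory
  band (relative amplitude 0.5).
* **Matching** — greedy nearest-neighbour within 20 cm⁻¹, ties broken by
  smaller |Δν| then lower wavenumber. A matched pair with Δν ≤ 0.5 cm⁻¹
  (half the default grid step) is classed `unchanged`: displacements
  below the sampling resolution would otherwise generate spurious
  near-infinite distance estimates. Unmatched native peaks are
  `disappeared` (with `confirm_disappearance` checking the complex
  intensity at ν₀ against 3× a robust noise estimate), unmatched complex
  peaks `new`. Intensity changes are relative, on baseline-corrected
  spectra.

## The shift-to-distance model

With interaction energy E ∝ 1/r and E ∝ Δν, the unique one-parameter
law is r = k/Δν. The algebraic form with its constants is not fixed by those
proportionalities alone, so the reconstruction is deliberately minimal
and explicit:

* k is a single global constant calibrated as k = r_anchor · max(Δν):
  the most-perturbed band is assigned the closest-approach distance
  (r_anchor = 7.0 Å, the bottom of the inferred distance range).
* Estimates are capped at r_max = 16 Å (the top of that range); capped
  values are flagged, and Δν = 0 maps to the cap ("no detectable
  interaction"). Both anchors are config keys.
* The supervised targets fed to the regressors are exactly these
  inverse-law outputs — the "actual" distances are themselves derived
  from the shifts, and the package treats that assumption as given.

On the default run the thiolate shift (≈10 cm⁻¹) sets k ≈ 70 Å·cm⁻¹ and
maps to 7.0 Å; the remaining shifted bands (≈1–3 cm⁻¹) cap at 16 Å, so
the estimate set spans [7.0, 16] Å by construction of the calibration.

## Regression

* **Ridge** — exact closed form. Centering X and y removes the
  (unpenalized) intercept; coefficients solve (XᶜᵀXᶜ + αI)w = Xᶜᵀyᶜ with
  α = 1.0 by default. Verified in tests against a brute-force solve of
  the penalized normal equations and against an independent library
  implementation.
* **Network** — fixed 2-5-1 architecture, ReLU hidden layer, full-batch
  gradient descent on mean squared error. Weights initialize uniformly
  in [−0.5, 0.5] from the seed; `epochs=0` returns exactly that
  initialization. The trainer standardizes the target internally (undone
  at prediction) purely for optimization conditioning. A non-finite loss
  raises instead of being clipped.
* **Validation** — seeded 80/20 split plus 5-fold cross-validation with
  folds as contiguous blocks of a seeded shuffle; fold assignments and
  the test index set are reproducible from the split seed alone. R² is
  undefined (NaN) on single-sample folds, which the small default run
  produces; the pipeline warns whenever n < 10 that metrics are
  descriptive.
* **Parameter recovery** (`ftirbind.validation`) — a balanced factorial
  design: 4 far-IR bands × 20 known distances spanning 7.0–15.8 Å,
  assigned Latin-style across 20 noiseless spectrum pairs on a 0.1 cm⁻¹
  grid, pushed through the full detection chain. The (ν₀, ν) features
  are nearly collinear (r ≈ 0.999) and the target r = k/Δν is nonlinear
  in them, so: ridge at α = 1.0 shrinks away the informative difference
  direction (R² ≈ 0); unpenalized least squares recovers the linear
  share (R² ≈ 0.94); the network reaches held-out R² ≥ 0.99 (150k
  epochs, learning rate 0.2). The ≥ 0.99 recovery claim therefore
  belongs to the nonlinear predictor.

## Thermodynamics

ΔG = −RT ln K_d (R = 8.314 J/(mol·K), output in kJ/mol) and
ΔS = (ΔH − ΔG)·1000/T. Applied literally, a micromolar K_d gives a
*positive* ΔG (dissociation-direction convention); the package does not
"correct" the sign but attaches a convention note to every result.
K_d is a direct input (default 10 μM): no intensity-to-K_d heuristic is
implemented because no mapping is specified. Defaults: T = 298 K,
ΔH = −30.00 kJ/mol.

## Structure analysis

* Parsing via gemmi: first model only, hydrogens dropped, insertion
  codes ignored, alternate locations resolved to highest occupancy.
* **Cluster** — Fe and inorganic S of the SF4/FS4 heterogroup plus
  cysteine Sγ; Fe–S pairs under 2.6 Å are bonds, classed core vs
  thiolate, with per-class mean/SD reported separately (the reference bond-length
  averages of 2.31 Å native / 2.22 Å bound have ambiguous provenance —
  crystal vs DFT-optimized geometry, unstated class averaging — so the
  package reports all three summaries and claims no exact match).
  A cubane whose Fe atoms lack 3 core bonds or exactly one thiolate is
  warned about but still returned.
* **Protein–DNA distances** — the reference 50-distance histogram does
  not state its selection rule, so the package's rule is explicit and
  logged in the output: donors = cluster Fe/S plus backbone amide N of
  every protein residue (backbone N chosen over carbonyl O for the
  "closest amide groups"); acceptors = DNA P, OP1, OP2, O3′, O5′;
  n-shortest (default 50) retained, sorted. On real coordinates the
  expectation is a property check only: cluster bonds in (2.1, 2.6) Å
  and the 50-distance set overlapping 7–16 Å.
* Fixtures are synthetic by construction: the ideal cubane places Fe/S
  on alternating cube corners so all 12 core bonds equal the requested
  2.30 Å exactly, and the toy complex has a hand-placed 3.5 Å closest
  contact.

## Degenerate inputs and numerical choices

Empty peak lists match to empty shift sets; all-zero shift sets refuse
calibration; constant feature columns refuse normalization; collinear
features at α = 0 raise rather than silently pseudo-solve; baseline
fitting stops early when the residual SD hits numerical zero. Peak
centers are reported at parabolic sub-grid precision, clipped to ±1 grid
step around the discrete minimum.

## Known limitations

The spectra are additive-noise idealizations (see above). The inverse
law is an editorial reconstruction, with a
calibration that pins the extremes of the distance range — min and max
of the default distance set are anchored at 7.0/16 Å by construction,
so only the *interior* of the distribution carries independent
information. Regression metrics on the default run rest on ~6 shifted
bands and are descriptive. The structure stage measures crystallographic
geometry only; it performs no quantum-chemical optimization, and the
reference bond-length averages and electrochemical stabilization
potential (150 mV) are consumed as context, not reproduced.
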