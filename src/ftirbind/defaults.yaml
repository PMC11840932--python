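# Packaged defaults: every stated constant of the study in one place,
# so the reference run is a single command.
simulate:
  seed: 20
  grid_step: 1.0          # cm^-1 (4 cm^-1 resampling mode available)
  noise_sigma: null       # null -> 1% of the largest band amplitude
  baseline_coeffs: [0.0]
  far_ir: {grid_start: 100.0, grid_end: 700.0}
  mid_ir: {grid_start: 600.0, grid_end: 1800.0}
preprocess:
  baseline_degree: 1
  savgol_window: 17       # points
  savgol_order: 3
  prominence_frac: 0.35
  match_tol: 20.0         # cm^-1
  far_ir_window: [300.0, 460.0]
distance_model:
  r_anchor: 7.0           # Å, closest approach
  r_max: 16.0             # Å, top of the reported distance range
  feature_mode: position
regression:
  predictor: ridge        # ridge | mlp
  alpha: 1.0
  mlp_epochs: 20000
  mlp_learning_rate: 0.05
  split_seed: 20
  test_fraction: 0.2
  n_folds: 5
thermo:
  Kd: 1.0e-5              # molar (10 uM)
  T: 298.0                # K
  dH: -30.0               # kJ/mol
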