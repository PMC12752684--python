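# Default pipeline configuration: packaged poplar shift table, the
# 18-chain 234432 habit, noiseless simulation.
shift_table: null          # null -> packaged poplar table
habit: "234432"
surface_split: {b: 0.16666666666666666, f: 0.3333333333333333, g: 0.25, j: 0.25}
parity: 0
lineshape: lorentzian
fwhm: 0.5
noise_sigma: 0.0
seed: 0
tolerance_ppm: 0.1
hydration_threshold: 1.2
pdsd_mixing_ms: 30.0
habit_search:
  n_min: 18
  n_max: 24
  max_sheets: 7
  ratio_tol: 0.1
  require_equal_oc: false
contact_map: null          # null -> packaged defaults
water_profile: null        # null -> packaged defaults
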