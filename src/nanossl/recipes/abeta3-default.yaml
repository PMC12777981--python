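# Three-class peptide fixture: native / E22G / G37R surrogate Abeta-42 events,
# 200 events per class at moderate noise, fixed seed.
task: peptide
n_per_class: 200
seed: 20240
peptide_params:
  sequence: DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA
  depth_per_volume: 3.0
  dwell_mean_points: 12.0
  dwell_shape: 200.0
  noise_sd: 0.1
  out_len: 500
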