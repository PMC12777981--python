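# Eight-class DNA barcode-carrier fixture at low noise.
task: barcode8
n_per_class: 40
seed: 20241
barcode_params:
  n_bits: 3
  carrier_level: -0.2
  spike_amp: 0.15
  spike_width_points: 24
  event_len_range: [420, 650]
  noise_sd: 0.02
  binding_site: none
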