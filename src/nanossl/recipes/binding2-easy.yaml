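# Binary protein-binding fixture (bound vs unbound carrier) at low noise.
task: binding2
n_per_class: 80
seed: 20242
barcode_params:
  n_bits: 3
  carrier_level: -0.2
  spike_amp: 0.15
  spike_width_points: 24
  event_len_range: [420, 650]
  noise_sd: 0.02
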