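# Example phantom configuration for `dirprop phantom --config`.
# Any omitted field keeps its default (see dirprop.phantom.PhantomConfig).
shape: [64, 64, 40]
spacing: [2.0, 2.0, 3.0]
noise_sd: 12.0
bladder_semi_axes_mm: [20.0, 17.0, 15.0]
bladder_fill_sigma: 0.25
rectum_fill_sigma: 0.15
setup_translation_sd_mm: 2.0
setup_rotation_sd_deg: 0.8
n_fractions: 23
schedule: daily
cbct_model:
  gain: 0.8
  offset: -30.0
  noise_sd: 25.0
  bias_amplitude: 0.08
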