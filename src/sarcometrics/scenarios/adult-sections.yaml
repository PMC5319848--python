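# Diastole-fixed section SL distributions of the adult +/Y and -/Y arms
# (Z-disc channel morphometry only; no Tmod1 pairing at these short SLs).
scenario: adult-sections
seed: 20170102
optics:
  noise_sd: 0.02
imaging:
  channels: [alpha_actinin, phalloidin]
  groups:
    "+/Y":
      n_cells: 36
      n_sarcomeres: 12
      sl_mean: 1.81
      sl_sd: 0.09
      tfl_slope: 0.35
      tfl_intercept: 0.21
      tfl_noise_sd: 0.03
    "-/Y":
      n_cells: 36
      n_sarcomeres: 12
      sl_mean: 1.52
      sl_sd: 0.21
      tfl_slope: 0.27
      tfl_intercept: 0.38
      tfl_noise_sd: 0.05
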