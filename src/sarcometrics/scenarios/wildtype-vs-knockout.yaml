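# Adult +/Y vs -/Y comparison: diastole-fixed section morphometry,
# titin gel densitometry, qPCR isoform index and force-pCa sensitivity.
scenario: wildtype-vs-knockout
seed: 20170101
# trace-level noise: a drawn line profile averages ~8 parallel pixel rows,
# so 0.05-per-pixel imaging noise becomes ~0.02 on the 1D trace
optics:
  noise_sd: 0.02
measurement:
  prominence_frac: 0.2
  min_separation_um: 0.8
  pointed_min_separation_um: 0.3
  resolution_limit_um: 0.2
imaging:
  channels: [alpha_actinin, tmod1, phalloidin]
  groups:
    "+/Y":
      n_cells: 24
      n_sarcomeres: 12
      sl_mean: 2.6          # stretched myofibrils: pointed ends resolvable
      sl_sd: 0.18
      tfl_slope: 0.35
      tfl_intercept: 0.21
      tfl_noise_sd: 0.05
    "-/Y":
      n_cells: 24
      n_sarcomeres: 12
      sl_mean: 2.8
      sl_sd: 0.25
      tfl_slope: 0.27
      tfl_intercept: 0.38
      tfl_noise_sd: 0.08
gel:
  "+/Y": {pct_n2b: 90.5, n_lanes: 4, noise_sd: 0.5}
  "-/Y": {pct_n2b: 92.9, n_lanes: 4, noise_sd: 0.5}
qpcr:
  "+/Y": {pct_n2b: 82.4, n_samples: 8, tech_noise_sd: 0.2, replicates: 3}
  "-/Y": {pct_n2b: 93.7, n_samples: 8, tech_noise_sd: 0.2, replicates: 3}
force:
  groups:
    "+/Y": {pca50: 5.94, n_hill: 2.0, f_max: 25.0, passive_force: 2.0, noise_sd: 0.1}
    "-/Y": {pca50: 5.92, n_hill: 2.0, f_max: 25.0, passive_force: 2.0, noise_sd: 0.1}
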