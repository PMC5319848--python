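# Embryonic cardiomyocyte culture: knockout cells overshoot the %N2B
# transition by day 9 unless rescued with exogenous peptide.
scenario: culture-rescue
seed: 20170104
transition:
  stages: [day1, day5, day9]
  genotypes:
    "KO": [30.0, 62.0, 82.7]
    "KO+Tb4": [30.0, 52.0, 61.0]
  n_per_stage: 6
  noise_sd: 3.0
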