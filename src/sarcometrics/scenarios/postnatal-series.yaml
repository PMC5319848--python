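# Postnatal titin isoform transition (%N2B by the qPCR element index):
# genotypes indistinguishable through P1, -/Y precociously elevated from P5.
scenario: postnatal-series
seed: 20170103
transition:
  stages: [E14.5, E16.5, E18.5, P1, P5, P10, P21, adult]
  genotypes:
    "+/Y": [2.0, 4.0, 8.0, 20.0, 40.0, 60.0, 80.0, 82.4]
    "-/Y": [2.0, 4.0, 8.0, 20.0, 55.0, 75.0, 90.0, 93.7]
  n_per_stage: 4
  noise_sd: 3.0
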