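# Printed group summaries for the ALPS-analysis cohort (PD with anxiety,
# PD without anxiety, healthy controls). Values are n, and per-group
# [mean, sd] as printed; sex is [male, female] counts. These summaries are
# inputs to the summary-statistic layer and defaults for the cohort
# generator; no test statistics are stored here.
name: alps_cohort
groups:
  PD-A: 21
  PD-NA: 47
  HC: 38
sex_mf:
  PD-A: [10, 11]
  PD-NA: [30, 17]
  HC: [19, 19]
variables:
  age: {PD-A: [67.00, 7.11], PD-NA: [63.00, 8.84], HC: [62.61, 7.99]}
  education: {PD-A: [10.40, 2.19], PD-NA: [9.63, 3.27], HC: [9.55, 3.96]}
  ledd: {PD-A: [409.52, 230.35], PD-NA: [409.84, 224.58]}
  duration: {PD-A: [5.60, 3.65], PD-NA: [3.36, 2.38]}
  hy: {PD-A: [2.29, 0.77], PD-NA: [1.93, 0.69]}
  updrs3: {PD-A: [25.24, 11.66], PD-NA: [21.09, 10.66]}
  hama: {PD-A: [19.52, 4.85], PD-NA: [5.43, 3.25], HC: [2.61, 1.76]}
  hamd: {PD-A: [12.43, 5.84], PD-NA: [4.06, 2.83], HC: [3.05, 1.97]}
  mmse: {PD-A: [28.57, 1.69], PD-NA: [28.47, 1.44], HC: [28.97, 1.00]}
  alps_mean: {PD-A: [1.261, 0.124], PD-NA: [1.321, 0.101], HC: [1.338, 0.110]}
  alps_left: {PD-A: [1.282, 0.126], PD-NA: [1.324, 0.102], HC: [1.341, 0.128]}
  alps_right: {PD-A: [1.240, 0.131], PD-NA: [1.317, 0.110], HC: [1.334, 0.114]}
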