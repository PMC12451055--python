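# Printed group summaries for the combined gBOLD-CSF coupling + ALPS cohort
# (subjects whose fMRI covered the foramen magnum). Same layout as
# table1.yaml, plus the coupling-strength variable.
name: coupling_cohort
groups:
  PD-A: 16
  PD-NA: 36
  HC: 34
sex_mf:
  PD-A: [8, 8]
  PD-NA: [22, 14]
  HC: [17, 17]
variables:
  age: {PD-A: [66.63, 7.63], PD-NA: [62.64, 9.19], HC: [61.35, 7.03]}
  education: {PD-A: [10.66, 2.17], PD-NA: [9.35, 3.40], HC: [9.50, 3.88]}
  ledd: {PD-A: [440.63, 220.58], PD-NA: [380.90, 172.29]}
  duration: {PD-A: [5.84, 3.75], PD-NA: [3.10, 2.17]}
  hy: {PD-A: [2.34, 0.79], PD-NA: [1.79, 0.60]}
  updrs3: {PD-A: [25.50, 12.19], PD-NA: [20.36, 11.45]}
  hama: {PD-A: [18.88, 5.06], PD-NA: [5.25, 3.29], HC: [2.68, 1.79]}
  hamd: {PD-A: [11.25, 4.57], PD-NA: [4.03, 2.72], HC: [3.26, 1.96]}
  mmse: {PD-A: [28.75, 1.77], PD-NA: [28.47, 1.38], HC: [28.91, 1.03]}
  coupling: {PD-A: [0.230, 0.143], PD-NA: [0.363, 0.194], HC: [0.337, 0.177]}
  alps_mean: {PD-A: [1.256, 0.110], PD-NA: [1.320, 0.105], HC: [1.338, 0.115]}
  alps_left: {PD-A: [1.282, 0.119], PD-NA: [1.324, 0.105], HC: [1.335, 0.130]}
  alps_right: {PD-A: [1.231, 0.113], PD-NA: [1.317, 0.114], HC: [1.341, 0.119]}
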