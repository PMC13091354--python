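# Small, fast configuration for smoke tests and examples: default substrate
# panels but shortened kinetic reads and a three-step exposure ladder.
seed: 3
design:
  cycles_per_chip: {PTK: 12, STK: 16}
  exposure_times: [10, 50, 200]
cohort:
  patients:
    - [HCC-M-1, M]
    - [HCC-M-2, M]
    - [HCC-F-3, F]
  technical_replicates: 2
uka:
  mode: uka
  n_iter: 500
  n_perm: 200
trial:
  off_target_threshold: 20.0
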