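# Demo pipeline run: pooled per-sex lysates on the default chip geometry
# (196 PTK / 144 STK substrates, 94 / 124 cycles, five exposures), paired
# tumor/adjacent tissue, technical triplicate, three ABL inhibitors vs vehicle.
seed: 11
cohort:
  pooled: true
truth:
  patient_sd: 0.2
simulate:
  enabled: true
  write_raw: false
stats:
  lfc_threshold: 0.2
uka:
  mode: uka
  n_iter: 2000
  n_perm: 500
  min_substrates: 3
trial:
  off_target_threshold: 20.0
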