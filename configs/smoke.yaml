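# Desk-scale pipeline profile: small cohort, few repetitions, short training.
generator:
  n_subjects: 6
  phasic_reps: 2
  seed: 0
dataset_ids: [RPD]
models: [trivial, rf, lstm, lstm_sw]
epochs: 10
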