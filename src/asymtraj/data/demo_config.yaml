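# Small-scale demonstration run: a synthetic cohort with the default
# staggered-sigmoid biomarker panel, scaled down so the full pipeline
# finishes in well under a minute.
seed: 17

cohort:
  n_subjects: 60
  converter_fraction: 0.3
  static_mix: [0.15, 0.5, 0.35]

volumes:
  n: 1          # one synthetic paired volume, features for its first pair
  n_pairs: 1

match:
  k: 5
  n_replicates: 25

validate:
  n_boot: 200
  alpha: 0.05

fit:
  variables: all
  alpha: 0.05
  min_per_segment: 10
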