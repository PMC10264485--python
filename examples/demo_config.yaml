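# Bundled synthetic demonstration: eye-tracking mode with a planted
# mid-range dip surface, small enough to run end to end in seconds.
mode: eyetracking
dv: gaze
seed: 11
synthetic:
  n_families: 80
  n_subjects: 6
  n_sentences: 110
  sentence_length_min: 7
  sentence_length_max: 9
  surface_form: dip
lm:
  order: 3
  smoothing: add_k
  k: 1.0
model:
  k_osc: 5
  k_surprisal: 5
  surface_grid: 20
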