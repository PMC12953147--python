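# Reference pipeline configuration.  Every section mirrors one of the typed
# configs; CLI flags override individual fields.

synthetic:                  # study conditions for the simulated corpus
  t: 5                      # trait dimensions (Big Five order)
  vocab: 60                 # vocabulary size (markers + fillers)
  markers_per_trait: 4      # high and low marker words per dimension
  beta: 1.0                 # marker log-odds slope per SD of the trait
  message_length_range: [12, 24]
  n_participants: 200
  messages_per_participant: 10
  heldout_fraction: 0.2

estimator:
  lambda: 0.001             # ridge penalty for the participant-level fit

model:                      # tiny reference transformer
  num_layers: 2
  hidden_size: 64
  num_heads: 4
  num_kv_heads: 2
  head_dim: 16
  max_sequence_length: 64

adapter:
  include_bias: true        # append a constant-1 input to the projections
  inject_layers: null       # null = every layer

train:
  epochs: 10
  batch_size: 32
  learning_rate: 0.0005
  freeze_base: false

evaluation:
  levels: [-3, 0, 3]        # Low / Neutral / High
  samples_per_group: 5
  n_trials: 10
  max_new_tokens: 16
  prompt: ""
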