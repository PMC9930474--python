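# Demo run: a small synthetic cohort through the full pipeline.
schema_version: 1
out_dir: demo_out
seed: 7
stages: [synth, preprocess, connectome, graph, roistats]
synth:
  n_nodes: 24
  n_timepoints: 120
  groups: [[placebo, 3], [CBD, 3], [THC, 3]]
  sessions: [chronic, washout]
  module_sizes: [6, 6, 6, 6]
  spike_rate: 1.0
graphm:
  metrics: [strength, cpl, efficiency, clustering, transitivity, modularity]
roistats:
  q: 0.2
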