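name: striatal
cell_type: striatal spiny projection neuron, pooled archives (basal like)
provenance:
  source: published predictive diameter equations (training-set fits)
models:
- node_class: initial
  tree_label: any
  features: [TL, LP]
  coefficients: [0.00114, 0.00713]
  adj_r2: 0.8126
- node_class: branching_child
  tree_label: any
  features: [PD]
  coefficients: [0.921]
  adj_r2: 0.915
- node_class: continuing
  tree_label: any
  features: [PD]
  coefficients: [0.9834]
  adj_r2: 0.9753
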