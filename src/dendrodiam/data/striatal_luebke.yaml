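name: striatal-luebke
cell_type: striatal spiny projection neuron, Luebke D1R + D2R archives
provenance:
  source: published predictive diameter equations (training-set fits)
models:
- node_class: initial
  tree_label: any
  features: [TL]
  coefficients: [0.003]
  adj_r2: 0.75
- node_class: branching_child
  tree_label: any
  features: [PD]
  coefficients: [0.934]
  adj_r2: 0.907
- node_class: continuing
  tree_label: any
  features: [PD]
  coefficients: [0.976]
  adj_r2: 0.962
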