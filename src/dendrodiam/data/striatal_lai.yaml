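name: striatal-lai
cell_type: striatal spiny projection neuron, Lai archive
provenance:
  source: published predictive diameter equations (training-set fits)
models:
- node_class: initial
  tree_label: any
  features: [TD]
  coefficients: [0.250]
  adj_r2: 0.786
- node_class: branching_child
  tree_label: any
  features: [PD]
  coefficients: [0.861]
  adj_r2: 0.967
- node_class: continuing
  tree_label: any
  features: [PD]
  coefficients: [0.997]
  adj_r2: 0.999
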