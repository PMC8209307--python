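name: hippocampal
cell_type: hippocampal pyramidal (CA1 + CA3)
provenance:
  source: published predictive diameter equations (training-set fits)
models:
- node_class: initial
  tree_label: apical
  features: [PD, LP]
  coefficients: [0.0755, 0.0056]
  adj_r2: 0.7216
- node_class: branching_child
  tree_label: apical
  features: [PD, LP]
  coefficients: [0.2598, 0.0034]
  adj_r2: 0.9151
- node_class: continuing
  tree_label: apical
  features: [PD]
  coefficients: [0.9968]
  adj_r2: 0.9993
- node_class: initial
  tree_label: basal
  features: [PD, PS]
  coefficients: [-0.5964, 0.3535]
  adj_r2: 0.7246
  note: can yield nonpositive diameters for initial nodes close to the soma;
    predictions are floored at the configured minimum diameter.
- node_class: branching_child
  tree_label: basal
  features: [PD, PS]
  coefficients: [0.6351, 0.0033]
  adj_r2: 0.9340
- node_class: continuing
  tree_label: basal
  features: [PD]
  coefficients: [0.9926]
  adj_r2: 0.9984
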