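name: cerebellar
cell_type: cerebellar Purkinje (apical like)
provenance:
  source: published predictive diameter equations (training-set fits)
models:
- node_class: initial
  tree_label: any
  features: [PD]
  coefficients: [0.2331]
  adj_r2: 0.8879
- node_class: branching_child
  tree_label: any
  features: [PD, TL]
  coefficients: [0.6842, 0.6842]
  adj_r2: 0.8934
  note: published verbatim; with TL in micrometres this equation yields
    implausibly large diameters on realistic arbors. Applied as printed;
    a warning is emitted when this model is evaluated.
- node_class: continuing
  tree_label: any
  features: [PD]
  coefficients: [1.0121]
  adj_r2: 0.9555
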