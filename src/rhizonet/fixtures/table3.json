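{
  "traits": ["colM", "RD", "RTD", "SRA", "SRL", "RDMC", "RNC", "RC:N", "RCC"],
  "n_species": 32,
  "with_focal": {
    "degree": [6, 5, 5, 4, 3, 5, 4, 1, 3],
    "weighted_degree": [3.7, 3.2, 3.8, 3.1, 2.0, 3.5, 2.5, 0.8, 1.9],
    "betweenness": [0.3, 0.2, 0.0, 0.0, 0.0, 0.2, 0.3, 0.0, 0.0],
    "average_path_length": 1.1,
    "edge_density": 0.5,
    "clustering": 0.7,
    "connectance": 0.4
  },
  "without_focal": {
    "degree": [4, 4, 3, 3, 4, 3, 1, 2],
    "weighted_degree": [2.4, 3.1, 2.6, 2.0, 3.0, 2.0, 0.8, 1.3],
    "betweenness": [0.6, 0.0, 0.0, 0.0, 0.4, 0.3, 0.0, 0.0],
    "average_path_length": 1.3,
    "edge_density": 0.4,
    "clustering": 0.6,
    "connectance": 0.3
  }
}
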