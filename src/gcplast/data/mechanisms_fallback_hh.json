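{
  "comment": "Self-contained simplified mechanism set: HH-style Na + fast delayed-rectifier K everywhere, generic high-threshold Ca (as 'cal') and Ca-gated SK in the dendritic layers. Densities in S/cm2.",
  "densities": {
    "soma": {
      "na": 0.12,
      "kdrf": 0.04
    },
    "GCL": {
      "na": 0.023,
      "kdrf": 0.012
    },
    "IML": {
      "na": 0.018,
      "kdrf": 0.01,
      "cal": 0.002,
      "sk": 0.0001
    },
    "MML": {
      "na": 0.018,
      "kdrf": 0.01,
      "cal": 0.002,
      "sk": 0.0001
    },
    "OML": {
      "na": 0.018,
      "kdrf": 0.01,
      "cal": 0.002,
      "sk": 0.0001
    }
  },
  "cm": {
    "soma": 1.0,
    "GCL": 1.0,
    "IML": 1.0,
    "MML": 1.0,
    "OML": 1.0
  },
  "g_leak": {
    "soma": 5e-05,
    "GCL": 5e-05,
    "IML": 5e-05,
    "MML": 5e-05,
    "OML": 5e-05
  },
  "ra": 210.0,
  "e_leak": -70.0,
  "e_na": 55.0,
  "e_k": -90.0,
  "e_ca": 130.0,
  "ca_rest": 5e-05,
  "ca_tau": 10.0,
  "ca_depth": 0.2
}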