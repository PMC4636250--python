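{
  "comment": "Transcription (by the implementers, from the published dentate granule cell model with nine voltage-gated channels) of per-layer conductance densities in S/cm2 and passive parameters. Quantitative results with this source are conditional on the fidelity of this transcription.",
  "densities": {
    "soma": {"na": 0.12, "kdrf": 0.016, "kdrs": 0.006, "ka": 0.012, "cat": 3.7e-05, "can": 0.002, "cal": 0.005, "sk": 0.001, "bk": 0.0006},
    "GCL": {"na": 0.018, "kdrf": 0.004, "kdrs": 0.006, "ka": 0.008, "cat": 7.5e-05, "can": 0.003, "cal": 0.0075, "sk": 0.0004, "bk": 0.0006},
    "IML": {"na": 0.013, "kdrf": 0.004, "kdrs": 0.006, "ka": 0.008, "cat": 0.00025, "can": 0.001, "cal": 0.0075, "sk": 0.0002, "bk": 0.001},
    "MML": {"na": 0.008, "kdrf": 0.001, "kdrs": 0.006, "ka": 0.008, "cat": 0.0005, "can": 0.001, "cal": 0.0005, "sk": 0.0, "bk": 0.0008},
    "OML": {"na": 0.008, "kdrf": 0.001, "kdrs": 0.008, "ka": 0.008, "cat": 0.001, "can": 0.001, "cal": 0.0, "sk": 0.0, "bk": 0.0008}
  },
  "cm": {"soma": 1.0, "GCL": 1.0, "IML": 1.6, "MML": 1.6, "OML": 1.6},
  "g_leak": {"soma": 4e-05, "GCL": 4e-05, "IML": 6.3e-05, "MML": 6.3e-05, "OML": 6.3e-05},
  "ra": 210.0,
  "e_leak": -70.0,
  "e_na": 50.0,
  "e_k": -90.0,
  "e_ca": 130.0,
  "ca_rest": 5e-05,
  "ca_tau": 10.0,
  "ca_depth": 0.2
}
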