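{
  "source": "Published reference values (mean, SD in % weight change over 3 runs) that the headline scenarios are designed to reproduce; quantitative comparison is conditional on the 'modeldb-51781' mechanism transcription.",
  "values": {
    "dbs400_full": {"medial": [23.0, 2.3], "lateral": [-38.5, 1.3]},
    "dbs400_60pct": {"medial": [45.3, 4.4], "lateral": [-30.6, 1.5]},
    "tbs100_60pct": {"medial": [5.3, 0.3], "lateral": [-6.5, 0.3]},
    "tbs400_60pct": {"medial": [25.0, 2.0], "lateral": [-20.7, 1.6]},
    "tbs100_ap_frozen": {"medial": [36.8, 0.9]}
  },
  "scenario_map": {
    "fig1b_top": "dbs400_full",
    "fig1b_mid": "dbs400_60pct",
    "fig2a": "tbs100_60pct",
    "fig2b": "tbs400_60pct"
  }
}
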