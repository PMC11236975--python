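{
  "table": "Table 5",
  "criteria": {
    "total_reported": {"n_pass": 32, "n_applicable": 42},
    "all_samples_archived": {"n_pass": 19, "n_applicable": 42}
  }
}
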