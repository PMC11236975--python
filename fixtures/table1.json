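{
  "table": "Table 1",
  "criteria": {
    "raw_reads_archived": {"n_pass": 20, "n_applicable": 42},
    "capture_raw": {"n_pass": 10, "n_applicable": 29},
    "adapters_trimmed": {"n_pass": 9, "n_applicable": 20}
  }
}
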