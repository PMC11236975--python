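{
  "table": "Table 2",
  "criteria": {
    "alignments_archived": {"n_pass": 33, "n_applicable": 42},
    "both_archived": {"n_pass": 11, "n_applicable": 42},
    "alignments_as_analysis": {"n_pass": 2, "n_applicable": 33},
    "no_any_hardfilter": {"n_pass": 7, "n_applicable": 33},
    "no_mapq_hardfilter": {"n_pass": 21, "n_applicable": 33},
    "no_length_hardfilter": {"n_pass": 11, "n_applicable": 33},
    "rawless_unfiltered": {"n_pass": 5, "n_applicable": 22}
  }
}
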