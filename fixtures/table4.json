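{
  "table": "Table 4",
  "criteria": {
    "geo_any": {"n_pass": 25, "n_applicable": 42},
    "geo_dedicated": {"n_pass": 12, "n_applicable": 25},
    "geo_coords": {"n_pass": 3, "n_applicable": 25},
    "date_any": {"n_pass": 7, "n_applicable": 42},
    "date_dedicated": {"n_pass": 1, "n_applicable": 7},
    "date_c14": {"n_pass": 1, "n_applicable": 7},
    "tissue_any": {"n_pass": 15, "n_applicable": 42},
    "tissue_dedicated": {"n_pass": 10, "n_applicable": 15},
    "voucher_present": {"n_pass": 6, "n_applicable": 42}
  }
}
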