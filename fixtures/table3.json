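{
  "table": "Table 3",
  "criteria": {
    "sample_count_match": {"n_pass": 27, "n_applicable": 42},
    "libraries_linked_single_sample": {"n_pass": 34, "n_applicable": 42},
    "accession_reuse": {"n_pass": 0, "n_applicable": 11},
    "library_metadata_present": {"n_pass": 0, "n_applicable": 42},
    "bam_has_rg": {"n_pass": 29, "n_applicable": 33},
    "bam_sm_present": {"n_pass": 27, "n_applicable": 29},
    "bam_sm_matches": {"n_pass": 9, "n_applicable": 27},
    "bam_single_sm": {"n_pass": 22, "n_applicable": 27},
    "bam_lb_present": {"n_pass": 20, "n_applicable": 33},
    "bam_lb_matches": {"n_pass": 4, "n_applicable": 20},
    "bam_valid": {"n_pass": 20, "n_applicable": 33}
  }
}
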