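{
  "comment": "Curated transcription of experimentally validated E. coli mRNA targets of the RyhB and FnrS sRNAs, compiled from public resources (sRNATarBase, BSRD, EcoCyc, targeted mutation studies). Per-gene source flags are a best-effort reading of the source grid: 'sources' lists, in catalog order, the first n_sources supporting resources and is indicative only; analyses should rely on the gene lists.",
  "source_columns": ["sRNATarBase", "BSRD", "literature", "EcoCyc", "prediction"],
  "RyhB": [
    {"gene": "iscS", "n_sources": 5},
    {"gene": "fur", "n_sources": 2},
    {"gene": "sdhD", "n_sources": 3},
    {"gene": "sodB", "n_sources": 5, "shared": true},
    {"gene": "acnA", "n_sources": 3},
    {"gene": "fumA", "n_sources": 5},
    {"gene": "nirB", "n_sources": 4},
    {"gene": "marA", "n_sources": 3},
    {"gene": "bfr", "n_sources": 2},
    {"gene": "nagZ", "n_sources": 3},
    {"gene": "ftnA", "n_sources": 2},
    {"gene": "sdhA", "n_sources": 3},
    {"gene": "erpA", "n_sources": 4},
    {"gene": "sdhC", "n_sources": 4},
    {"gene": "sdhCDAB", "n_sources": 2},
    {"gene": "cysE", "n_sources": 4},
    {"gene": "msrB", "n_sources": 2, "alias": "yeaA"},
    {"gene": "hemB", "n_sources": 1},
    {"gene": "hemH", "n_sources": 1},
    {"gene": "uof", "n_sources": 1},
    {"gene": "sodA", "n_sources": 2},
    {"gene": "shiA", "n_sources": 3}
  ],
  "FnrS": [
    {"gene": "folX", "n_sources": 5},
    {"gene": "gpmA", "n_sources": 5},
    {"gene": "folE", "n_sources": 5},
    {"gene": "maeA", "n_sources": 5},
    {"gene": "iscR", "n_sources": 4},
    {"gene": "marA", "n_sources": 4},
    {"gene": "nagZ", "n_sources": 3},
    {"gene": "sdhA", "n_sources": 4},
    {"gene": "sodA", "n_sources": 5},
    {"gene": "sodB", "n_sources": 5, "shared": true},
    {"gene": "metE", "n_sources": 5},
    {"gene": "cydD", "n_sources": 5},
    {"gene": "yobA", "n_sources": 5}
  ]
}
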