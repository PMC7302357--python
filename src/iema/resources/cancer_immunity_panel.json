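{
  "description": "Default cancer-immunity-cycle gene panel used for immune evasion mechanism annotation. Steps follow the canonical anti-tumor response: antigen release by dying tumor cells, antigen processing/presentation by APCs, T-cell priming and activation, trafficking of effectors to the tumor, infiltration into the tumor bed, recognition of tumor cells, and killing. Checkpoint and decoy-receptor genes drive the tolerance and counterattack mechanism calls. Edit freely; the annotation rules treat this file as data.",
  "steps": {
    "antigen_release": ["CALR", "HMGB1", "ANXA1"],
    "antigen_presentation": ["HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "PSMB9", "HLA-DRA"],
    "priming_activation": ["CD80", "CD86", "CD28", "CD40", "CD40LG", "IL2", "IL12A", "IL12B"],
    "trafficking": ["CXCL9", "CXCL10", "CXCL11", "CCL5"],
    "infiltration": ["ICAM1", "VCAM1", "SELE", "ITGB2", "CXCR3"],
    "recognition": ["CD3D", "CD3E", "CD8A", "TRAC", "KLRD1"],
    "killing": ["GZMA", "GZMB", "PRF1", "IFNG", "FASLG"]
  },
  "checkpoint_genes": {
    "tolerance:CTLA4": ["CTLA4"],
    "tolerance:PD-1": ["PDCD1"],
    "tolerance:PD-L1/2": ["CD274", "PDCD1LG2"],
    "tolerance:TGF-β": ["TGFB1"]
  },
  "decoy_genes": {
    "counterattack:DcR3": ["TNFRSF6B"],
    "counterattack:TRAILR4": ["TNFRSF10D"]
  },
  "effector_genes": ["GZMB", "PRF1", "IFNG"],
  "therapy_lookup": {
    "ignorance": "Cell-based vaccination (e.g. Sipuleucel-T / DC vaccines)",
    "impaired_antigen_presentation": "Cell-based vaccination (e.g. Sipuleucel-T / DC vaccines)",
    "tolerance:CTLA4": "Anti-CTLA4",
    "tolerance:PD-1": "Anti-PD-1",
    "tolerance:PD-L1/2": "Anti-PD-L1/2",
    "tolerance:TGF-β": "TGF-β blockade",
    "counterattack:DcR3": "Anti-DcR3",
    "counterattack:TRAILR4": "Anti-TRAILR4"
  }
}
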