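{
  "format": "forensnp-phenotype-model",
  "version": 1,
  "trait": "hair",
  "categories": [
    "black_dark_brown",
    "brown_light_brown",
    "blonde_dark_blonde",
    "red"
  ],
  "reference_category": "black_dark_brown",
  "snp_ids": [
    "rs11547464",
    "rs885479",
    "rs1805008",
    "rs1805005",
    "rs1805006",
    "rs2228479",
    "rs1110400",
    "rs28777",
    "rs16891982",
    "rs12821256",
    "rs4959270",
    "rs12203592",
    "rs1042602",
    "rs1800407",
    "rs2402130",
    "rs12913832",
    "rs2378249",
    "rs683"
  ],
  "effect_alleles": [
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A",
    "A"
  ]
}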