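{
  "format": "forensnp-phenotype-model",
  "version": 1,
  "trait": "eye",
  "categories": [
    "blue",
    "intermediate",
    "brown"
  ],
  "reference_category": "blue",
  "snp_ids": [
    "rs12913832",
    "rs1800407",
    "rs12896399",
    "rs16891982",
    "rs1393350",
    "rs12203592"
  ],
  "effect_alleles": [
    "A",
    "A",
    "A",
    "A",
    "A",
    "A"
  ]
}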