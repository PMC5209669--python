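{
  "description": "Caladium leaf-trait inheritance study: five foliar loci, ten parents, the crosses whose progeny counts ship as bundled TSV tables.",
  "trait_models": [
    {
      "locus": "LEM",
      "alleles": ["LEM", "lem"],
      "phenotypes": {"LEM": "lemon", "lem": "green"}
    },
    {
      "locus": "S",
      "alleles": ["S", "s"],
      "phenotypes": {"S": "spotted", "s": "non-spotted"}
    },
    {
      "locus": "V",
      "alleles": ["V^r", "V^w", "V^g"],
      "phenotypes": {"V^r": "red", "V^w": "white", "V^g": "green"}
    },
    {
      "locus": "RLF",
      "alleles": ["RLF", "rlf"],
      "phenotypes": {"RLF": "rugose", "rlf": "non-rugose"}
    },
    {
      "locus": "F",
      "alleles": ["F", "f"],
      "codominant": true,
      "phenotypes": {"F/F": "fancy", "F/f": "lance", "f/f": "strap"}
    }
  ],
  "locus_order": ["LEM", "V", "S", "RLF", "F"],
  "parents": {
    "Miss Muffet": {
      "haplotype_a": ["LEM", "V^w", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "S", "RLF", "F"]
    },
    "Gingerland": {
      "haplotype_a": ["lem", "V^w", "S", "RLF", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "f"]
    },
    "Candidum": {
      "haplotype_a": ["lem", "V^g", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    },
    "Aaron": {
      "haplotype_a": ["lem", "V^w", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^w", "s", "rlf", "F"]
    },
    "Fairytale Princess": {
      "haplotype_a": ["lem", "V^r", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "f"]
    },
    "Fla. Moonlight": {
      "haplotype_a": ["lem", "V^w", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    },
    "Red Flash": {
      "haplotype_a": ["lem", "V^r", "S", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    },
    "UF-52": {
      "haplotype_a": ["LEM", "V^w", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    },
    "UF-53": {
      "haplotype_a": ["LEM", "V^w", "s", "rlf", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    },
    "UF-317": {
      "haplotype_a": ["lem", "V^g", "S", "RLF", "F"],
      "haplotype_b": ["lem", "V^g", "s", "rlf", "F"]
    }
  },
  "crosses": [
    {"cross_id": "t2-01", "female": "Miss Muffet", "male": "Miss Muffet", "design_tag": "self"},
    {"cross_id": "t2-02", "female": "Miss Muffet", "male": "Gingerland", "design_tag": "testcross"},
    {"cross_id": "t2-03", "female": "Gingerland", "male": "Miss Muffet", "design_tag": "testcross"},
    {"cross_id": "t2-04", "female": "Miss Muffet", "male": "Candidum", "design_tag": "testcross"},
    {"cross_id": "t2-05", "female": "Candidum", "male": "Miss Muffet", "design_tag": "testcross"},
    {"cross_id": "t2-06", "female": "Miss Muffet", "male": "Red Flash", "design_tag": "testcross"},
    {"cross_id": "t2-07", "female": "Aaron", "male": "Miss Muffet", "design_tag": "testcross"},
    {"cross_id": "t2-08", "female": "Fla. Moonlight", "male": "Miss Muffet", "design_tag": "testcross"},
    {"cross_id": "t2-09", "female": "Gingerland", "male": "Gingerland", "design_tag": "self"},
    {"cross_id": "t2-10", "female": "Candidum", "male": "Candidum", "design_tag": "self"},
    {"cross_id": "t2-11", "female": "Gingerland", "male": "Candidum", "design_tag": "mixed"},
    {"cross_id": "t2-12", "female": "Candidum", "male": "Gingerland", "design_tag": "mixed"},
    {"cross_id": "t2-13", "female": "Gingerland", "male": "Red Flash", "design_tag": "mixed"},
    {"cross_id": "t2-14", "female": "Red Flash", "male": "Gingerland", "design_tag": "mixed"},
    {"cross_id": "t2-15", "female": "Fla. Moonlight", "male": "Fairytale Princess", "design_tag": "mixed"},
    {"cross_id": "t2-16", "female": "Aaron", "male": "UF-317", "design_tag": "mixed"},
    {"cross_id": "t2-17", "female": "UF-52", "male": "UF-317", "design_tag": "testcross"},
    {"cross_id": "t2-18", "female": "UF-53", "male": "Gingerland", "design_tag": "testcross"},
    {"cross_id": "t2-19", "female": "UF-52", "male": "Miss Muffet", "design_tag": "intercross"},
    {"cross_id": "t3-02", "female": "Miss Muffet", "male": "Gingerland", "design_tag": "mixed"},
    {"cross_id": "t3-03", "female": "Gingerland", "male": "Miss Muffet", "design_tag": "mixed"},
    {"cross_id": "t3-18", "female": "UF-53", "male": "Gingerland", "design_tag": "mixed"},
    {"cross_id": "t4-02", "female": "Miss Muffet", "male": "Gingerland", "design_tag": "intercross"},
    {"cross_id": "t4-03", "female": "Gingerland", "male": "Miss Muffet", "design_tag": "intercross"},
    {"cross_id": "t4-04", "female": "Miss Muffet", "male": "Candidum", "design_tag": "pseudo_bc1"},
    {"cross_id": "t4-05", "female": "Candidum", "male": "Miss Muffet", "design_tag": "pseudo_bc1"},
    {"cross_id": "t4-15", "female": "Fla. Moonlight", "male": "Miss Muffet", "design_tag": "pseudo_bc1"},
    {"cross_id": "t4-16", "female": "Aaron", "male": "Miss Muffet", "design_tag": "pseudo_bc1"},
    {"cross_id": "t5-02", "female": "Miss Muffet", "male": "Gingerland", "design_tag": "intercross"},
    {"cross_id": "t5-03", "female": "Gingerland", "male": "Miss Muffet", "design_tag": "intercross"},
    {"cross_id": "t5-04", "female": "Miss Muffet", "male": "Candidum", "design_tag": "pseudo_bc1"},
    {"cross_id": "t5-05", "female": "Candidum", "male": "Miss Muffet", "design_tag": "pseudo_bc1"},
    {"cross_id": "t5-17", "female": "UF-52", "male": "UF-317", "design_tag": "pseudo_bc1"},
    {"cross_id": "t6-02", "female": "Miss Muffet", "male": "Gingerland", "design_tag": "intercross"},
    {"cross_id": "t6-03", "female": "Gingerland", "male": "Miss Muffet", "design_tag": "intercross"},
    {"cross_id": "t6-04", "female": "Miss Muffet", "male": "Candidum", "design_tag": "pseudo_bc1"},
    {"cross_id": "t6-05", "female": "Candidum", "male": "Miss Muffet", "design_tag": "pseudo_bc1"},
    {"cross_id": "t7-01", "female": "Miss Muffet", "male": "Candidum", "design_tag": "pseudo_bc1", "n_declared": 1267}
  ],
  "options": {
    "alpha": 0.05,
    "mapping_function": "kosambi",
    "estimator": "paper",
    "seed": 0
  }
}
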