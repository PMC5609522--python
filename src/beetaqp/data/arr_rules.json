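{
  "rules": [
    {
      "rule_id": "water_typical_fhtr",
      "arr": ["F", "H", "T", "R"],
      "note": "ar/R selectivity filter F-H-T-R typical of water-transporting plasma-membrane aquaporins"
    },
    {
      "rule_id": "formamide_higr",
      "arr": ["H", "I", "G", "R"],
      "note": "ar/R selectivity filter H-I-G-R, experimentally associated with formamide transport"
    },
    {
      "rule_id": "boric_acid_nip5_like",
      "arr": ["A", "I", "G", "R"],
      "npa_lb": "NPS",
      "npa_le": "NPV",
      "note": "NPS/NPV aqueous pore with A-I-G-R ar/R filter, the configuration of the AtNIP5;1-type boric acid transporter"
    }
  ]
}
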