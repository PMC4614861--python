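{
  "comment": "Default lineage comparisons for the TRPM8 rate-vs-time (Dickerson) curve. Times are approximate divergence dates in millions of years (MYA); human is the time-zero reference. The 390 MYA amphibian/fish and 150 MYA bird/reptile anchors follow the narrative dating of TRPM8's emergence during the Devonian; the remaining dates are standard vertebrate timetree values.",
  "reference_zero": "Human",
  "comparisons": [
    {
      "name": "non-human primates vs human",
      "group_a": ["Gibbon", "Gorilla", "Olive baboon"],
      "group_b": ["Human"],
      "mya": 30
    },
    {
      "name": "mammalian radiation vs human",
      "group_a": ["Dog", "Guinea pig", "Pig", "Rat"],
      "group_b": ["Human"],
      "mya": 100
    },
    {
      "name": "birds vs reptiles",
      "group_a": ["Zebra finch", "Chicken"],
      "group_b": ["Anole lizard"],
      "mya": 150
    },
    {
      "name": "birds vs amphibians",
      "group_a": ["Zebra finch", "Chicken"],
      "group_b": ["Xenopus"],
      "mya": 360
    },
    {
      "name": "amphibians vs mammals",
      "group_a": ["Xenopus"],
      "group_b": ["Human"],
      "mya": 360
    },
    {
      "name": "basal fish vs tetrapods",
      "group_a": ["Coelacanth"],
      "group_b": ["Human", "Xenopus"],
      "mya": 390
    }
  ]
}
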