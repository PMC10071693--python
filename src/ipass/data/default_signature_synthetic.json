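{
  "calibration": {
    "log_base": 2.0,
    "norm_threshold": -0.25,
    "pseudocount": 1.0,
    "raw_max": 1.88,
    "raw_min": 0.2,
    "raw_threshold": 0.83
  },
  "signature": {
    "genes": [
      "GENE0845",
      "GENE0654",
      "GENE0579",
      "GENE0692",
      "GENE0358",
      "GENE0277",
      "GENE0825",
      "GENE0853",
      "GENE0573",
      "GENE0368",
      "GENE0651",
      "GENE0644",
      "GENE0705",
      "GENE0544",
      "GENE0084"
    ],
    "name": "ipass_derived",
    "rank_scores": [
      0.05338552684801294,
      0.037739408895230316,
      0.036516206471569404,
      0.03471752255147571,
      0.034640580651339244,
      0.034116033897869054,
      0.03315091647524261,
      0.03221461634948358,
      0.029491667879929063,
      0.028474151020203394,
      0.026197011751194998,
      0.024847642255451927,
      0.01891222266279051,
      0.014726743704433809,
      0.009650341539398645
    ]
  }
}
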