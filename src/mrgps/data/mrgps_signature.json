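{
  "name": "MrGPS",
  "provenance": "published",
  "pairs": [
    ["EIF3A", "AK2"],
    ["EIF3A", "EMP3"],
    ["YTHDC1", "IGFBP2"],
    ["YTHDC1", "TUBA1C"],
    ["IGF2BP3", "CYP17A1"]
  ],
  "coefficients": [-0.204, -0.266, -0.439, -0.140, 0.647]
}
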