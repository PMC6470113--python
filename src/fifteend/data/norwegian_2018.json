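{
  "omega": 0.113,
  "v_pits": 1.5158,
  "source": "Norwegian 15D value algorithm (2018), disutility decrements at 4-decimal precision",
  "notes": "omega is the published rescaling constant, rounded; it is provenance metadata only and is never used for scoring. v_pits equals the level-5 row sum."
}
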