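{
  "universe": ["s1", "s2", "s3", "s4", "s5", "s6", "s7", "s8", "s9"],
  "disorders": [
    {
      "name": "MDD-like",
      "expression": {
        "and": [
          {"at_least": 5, "of": [
            {"var": "s1"}, {"var": "s2"}, {"var": "s3"}, {"var": "s4"},
            {"var": "s5"}, {"var": "s6"}, {"var": "s7"}, {"var": "s8"},
            {"var": "s9"}
          ]},
          {"at_least": 1, "of": [{"var": "s1"}, {"var": "s2"}]}
        ]
      },
      "metadata": {
        "note": "simplified DSM-style shape: at least five of nine symptoms, including at least one of the two core symptoms s1/s2; synthetic stand-in, not a transcription of any manual"
      }
    }
  ]
}
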