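{
  "universe": ["a", "b", "c", "d"],
  "disorders": [
    {
      "name": "W",
      "expression": {
        "and": [
          {"var": "a"},
          {"at_least": 1, "of": [{"var": "b"}, {"var": "c"}]}
        ]
      },
      "metadata": {"note": "symptom a and at least one of b or c"}
    },
    {
      "name": "X",
      "expression": {
        "and": [
          {"var": "d"},
          {"at_least": 1, "of": [{"var": "b"}, {"var": "c"}]}
        ]
      },
      "metadata": {"note": "symptom d and at least one of b or c"}
    },
    {
      "name": "Y",
      "expression": {
        "and": [
          {"var": "b"},
          {"at_least": 1, "of": [{"var": "c"}, {"var": "d"}]}
        ]
      },
      "metadata": {
        "note": "reconstructed so the weakly irredundant CSSCs are exactly bc, bd, bcd"
      }
    },
    {
      "name": "Z",
      "expression": {
        "or": [{"var": "a"}, {"var": "d"}]
      },
      "metadata": {"note": "at least one of a or d; minimal CSSCs are the singletons a, d"}
    }
  ]
}
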