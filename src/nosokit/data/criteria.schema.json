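{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nosokit criteria file",
  "description": "Machine-actionable diagnostic criteria: a symptom universe plus named monotone expressions (VAR / AND / OR / AT_LEAST). Shipped as documentation of the dialect; the parser performs equivalent validation itself.",
  "type": "object",
  "required": ["disorders"],
  "properties": {
    "universe": {
      "type": "array",
      "items": {"type": "string", "minLength": 1},
      "description": "Ordered symptom identifiers; order fixes matrix rows and bitset positions. Optional: defaults to the sorted union of expression supports."
    },
    "labels": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "Optional map from symptom id to a human-readable term."
    },
    "disorders": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "expression"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "expression": {"$ref": "#/$defs/expression"},
          "metadata": {"type": "object", "additionalProperties": {"type": "string"}}
        }
      }
    }
  },
  "$defs": {
    "expression": {
      "oneOf": [
        {
          "type": "object",
          "required": ["var"],
          "additionalProperties": false,
          "properties": {"var": {"type": "string", "minLength": 1}}
        },
        {
          "type": "object",
          "required": ["and"],
          "additionalProperties": false,
          "properties": {
            "and": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expression"}}
          }
        },
        {
          "type": "object",
          "required": ["or"],
          "additionalProperties": false,
          "properties": {
            "or": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expression"}}
          }
        },
        {
          "type": "object",
          "required": ["at_least", "of"],
          "additionalProperties": false,
          "properties": {
            "at_least": {"type": "integer", "minimum": 0},
            "of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/expression"}}
          }
        }
      ]
    }
  }
}
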