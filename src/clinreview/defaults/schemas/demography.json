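{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Demography chapter",
  "description": "Frequency and descriptive summary tables of baseline characteristics.",
  "type": "object",
  "required": ["dataset"],
  "properties": {
    "dataset": {"type": "string", "description": "Demographics domain code (DM-like)"},
    "categorical_vars": {"type": "array", "items": {"type": "string"}},
    "continuous_vars": {"type": "array", "items": {"type": "string"}}
  },
  "additionalProperties": false
}
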