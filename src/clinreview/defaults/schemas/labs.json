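{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Laboratory safety chapter",
  "description": "Per-parameter descriptive tables, spaghetti/shift data products, and the hepatotoxicity eDish scatter.",
  "type": "object",
  "required": ["dataset", "parameters"],
  "properties": {
    "dataset": {"type": "string", "description": "Laboratory domain code (LB-like)"},
    "parameters": {"type": "array", "items": {"type": "string"}, "description": "Lab test short codes to report"},
    "edish": {"type": "boolean", "default": false},
    "alt_code": {"type": "string", "default": "ALT"},
    "bili_code": {"type": "string", "default": "BILI"},
    "spaghetti": {"type": "boolean", "default": true},
    "shift": {"type": "boolean", "default": true},
    "subset_rule": {"type": ["string", "null"], "enum": [null, "any_abnormal"]}
  },
  "additionalProperties": false
}
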