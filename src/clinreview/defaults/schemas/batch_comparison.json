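{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Batch comparison chapter",
  "description": "Record-level diff listing between the current and previous data batches for one domain.",
  "type": "object",
  "required": ["dataset"],
  "properties": {
    "dataset": {"type": "string", "description": "Domain to compare between batches"},
    "keys": {"type": "array", "items": {"type": "string"}, "description": "Key variables; defaults ship per domain"},
    "compare_vars": {"type": "array", "items": {"type": "string"}}
  },
  "additionalProperties": false
}
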