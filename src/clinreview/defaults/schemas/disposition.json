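{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Subject disposition chapter",
  "description": "Disposition counts and discontinuation listing, plus the subjects-by-visit attendance bars.",
  "type": "object",
  "required": ["dataset"],
  "properties": {
    "dataset": {"type": "string", "description": "Disposition domain code (DS-like)"},
    "visits_dataset": {"type": "string", "description": "Subject-visits domain for the attendance bars (SV-like)"},
    "status_var": {"type": "string", "description": "Disposition status variable", "default": "DSDECOD"},
    "completed_value": {"type": "string", "default": "COMPLETED"},
    "date_var": {"type": "string", "default": "DSSTDTC"}
  },
  "additionalProperties": false
}
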