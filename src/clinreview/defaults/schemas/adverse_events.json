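{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Adverse events chapter",
  "description": "Treatment-emergent AE incidence at worst severity, SOC/PT treemap data, and the AE listing.",
  "type": "object",
  "required": ["dataset"],
  "properties": {
    "dataset": {"type": "string", "description": "Adverse event domain code (AE-like)"},
    "exposure_dataset": {"type": "string", "description": "Exposure domain for the treatment-emergent window"},
    "treatment_emergent": {"type": "boolean", "default": true},
    "lag_days": {"type": "integer", "minimum": 0, "default": 30},
    "soc_var": {"type": "string", "default": "AEBODSYS"},
    "pt_var": {"type": "string", "default": "AEDECOD"},
    "severity_var": {"type": "string", "default": "AESEV"}
  },
  "additionalProperties": false
}
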