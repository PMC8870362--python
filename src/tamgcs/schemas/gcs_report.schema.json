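{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "GCS report",
  "type": "object",
  "required": [
    "aggregate",
    "gcs_per_class",
    "ns_per_class",
    "noise_flags",
    "radius_used",
    "tolerance_used",
    "normalized"
  ],
  "properties": {
    "aggregate": {"type": "number", "minimum": 0, "maximum": 1},
    "gcs_per_class": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "ns_per_class": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "noise_flags": {"type": "array", "items": {"type": "boolean"}},
    "radius_used": {"type": "number", "exclusiveMinimum": 0},
    "tolerance_used": {"type": "number", "exclusiveMinimum": 0},
    "normalized": {"type": "boolean"}
  }
}
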