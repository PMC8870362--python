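{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "GCS cut report",
  "type": "object",
  "required": [
    "profile",
    "scored_layers",
    "cut_index",
    "params_before",
    "params_after",
    "error_before",
    "error_after",
    "train_config",
    "gcs_config"
  ],
  "properties": {
    "profile": {"type": "array", "items": {"type": "number"}},
    "scored_layers": {"type": "array", "items": {"type": "integer"}},
    "cut_index": {"type": "integer", "minimum": 0},
    "params_before": {"type": "integer", "minimum": 0},
    "params_after": {"type": "integer", "minimum": 0},
    "error_before": {"type": "number", "minimum": 0, "maximum": 1},
    "error_after": {"type": "number", "minimum": 0, "maximum": 1},
    "train_config": {"type": "object"},
    "gcs_config": {"type": "object"}
  }
}
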