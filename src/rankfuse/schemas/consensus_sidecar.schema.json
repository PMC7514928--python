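{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rankfuse consensus report sidecar",
  "type": "object",
  "required": ["version", "metrics"],
  "properties": {
    "version": {"type": "string"},
    "input_sha256": {"type": ["string", "null"]},
    "seed": {"type": ["integer", "null"]},
    "metrics": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["objective", "score", "tiebreak_applied", "ranks"],
        "properties": {
          "objective": {"type": "integer", "minimum": 0},
          "score": {"type": "integer", "minimum": 0},
          "optimum_count": {"type": ["integer", "null"], "minimum": 1},
          "tiebreak_applied": {"type": "boolean"},
          "ranks": {"type": "array", "items": {"type": "integer", "minimum": 1}}
        }
      }
    },
    "coefficients": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "coefficient": {"type": "number"},
          "lower_bound": {"type": "number"},
          "upper_bound": {"type": "number"}
        }
      }
    }
  }
}
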