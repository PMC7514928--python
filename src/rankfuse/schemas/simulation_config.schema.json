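{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rankfuse simulation config",
  "description": "JSON mirror of rankfuse.simulate.SimulationConfig",
  "type": "object",
  "properties": {
    "K": {"type": "integer", "minimum": 2},
    "M": {"type": "integer", "minimum": 1},
    "n": {"type": "integer", "minimum": 1},
    "class_priors": {
      "type": "array",
      "items": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "accuracy": {"type": "number", "minimum": 0},
    "dependence": {"type": "number", "minimum": 0, "maximum": 1},
    "seed": {"type": "integer"},
    "model": {"enum": ["mallows", "score"]},
    "positive_class": {"type": "integer", "minimum": 0}
  },
  "additionalProperties": false
}
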