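{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "retromark single-pattern report",
  "type": "object",
  "required": ["labels", "counts", "mode", "alpha", "tests", "scenario", "warnings"],
  "properties": {
    "labels": {
      "type": "object",
      "required": ["a", "b", "c"],
      "properties": {
        "a": {"type": "string"},
        "b": {"type": "string"},
        "c": {"type": "string"}
      }
    },
    "counts": {
      "type": "object",
      "required": ["ab", "ac", "bc"],
      "properties": {
        "ab": {"type": ["integer", "null"]},
        "ac": {"type": ["integer", "null"]},
        "bc": {"type": ["integer", "null"]}
      }
    },
    "mode": {"type": "string", "enum": ["multi_directional", "one_directional"]},
    "reference_lineage": {"type": ["string", "null"]},
    "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["test_type", "p_value"],
        "properties": {
          "test_type": {"type": "string"},
          "p_value": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "critical_005": {"type": ["integer", "null"]},
          "critical_001": {"type": ["integer", "null"]}
        }
      }
    },
    "scenario": {
      "type": "string",
      "enum": [
        "tree",
        "polytomy",
        "hybridization",
        "tree_with_hybridization_signal",
        "undetermined_one_directional"
      ]
    },
    "scenario_sentence": {"type": "string"},
    "supported_pair": {
      "type": ["array", "null"],
      "items": {"type": "string"},
      "minItems": 2,
      "maxItems": 2
    },
    "hybrid_lineage": {"type": ["string", "null"]},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "drift_time": {
      "type": "object",
      "required": ["tau_hat", "ci_low", "ci_high", "conf_level", "p1_hat"],
      "properties": {
        "tau_hat": {"type": ["number", "null"]},
        "ci_low": {"type": "number"},
        "ci_high": {"type": ["number", "null"]},
        "conf_level": {"type": "number"},
        "p1_hat": {"type": "number"},
        "rate_ratio": {"type": "number"}
      }
    },
    "id": {"type": "string"}
  }
}
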