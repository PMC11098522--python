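{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "medfly-sit model parameters",
  "type": "object",
  "required": ["life", "rem", "sterile"],
  "properties": {
    "life": {
      "type": "object",
      "required": ["bW", "bWW", "bWS", "bSW", "nuA", "muA", "r", "muM", "muF", "muFWW", "muFWS", "muFSW", "K"],
      "properties": {
        "bW": {"type": "number", "exclusiveMinimum": 0},
        "bWW": {"type": "number", "minimum": 0},
        "bWS": {"type": "number", "minimum": 0},
        "bSW": {"type": "number", "minimum": 0},
        "nuA": {"type": "number", "exclusiveMinimum": 0},
        "muA": {"type": "number", "exclusiveMinimum": 0},
        "r": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "muM": {"type": "number", "exclusiveMinimum": 0},
        "muF": {"type": "number", "exclusiveMinimum": 0},
        "muFWW": {"type": "number", "exclusiveMinimum": 0},
        "muFWS": {"type": "number", "exclusiveMinimum": 0},
        "muFSW": {"type": "number", "exclusiveMinimum": 0},
        "K": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "rem": {
      "type": "object",
      "required": ["delta", "deltaS"],
      "properties": {
        "delta": {"type": "number", "minimum": 0},
        "deltaS": {"type": "number", "minimum": 0}
      }
    },
    "sterile": {
      "type": "object",
      "required": ["muS", "gamma", "eps"],
      "properties": {
        "muS": {"type": "number", "exclusiveMinimum": 0},
        "gamma": {"type": "number", "minimum": 0},
        "eps": {"type": "number", "minimum": 0, "exclusiveMaximum": 1}
      }
    }
  }
}
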