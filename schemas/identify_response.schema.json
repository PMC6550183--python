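{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "IdentifyResponse",
  "type": "object",
  "required": ["version", "predictions"],
  "properties": {
    "version": {"type": "integer"},
    "predictions": {
      "type": "array",
      "maxItems": 5,
      "items": {
        "type": "object",
        "required": ["ndc", "confidence"],
        "properties": {
          "ndc": {"type": "string"},
          "confidence": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
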