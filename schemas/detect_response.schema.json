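{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "DetectResponse",
  "type": "object",
  "required": ["version", "detections"],
  "properties": {
    "version": {"type": "integer"},
    "detections": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["box", "score"],
        "properties": {
          "box": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0},
            "minItems": 4,
            "maxItems": 4,
            "description": "half-open [r0, c0, r1, c1] in source-image pixels"
          },
          "score": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
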