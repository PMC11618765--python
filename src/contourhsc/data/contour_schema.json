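{
  "$comment": "JSON contour dialect, schema_version 1",
  "schema_version": 1,
  "type": "object",
  "required": ["name", "slices"],
  "properties": {
    "schema_version": {"type": "integer"},
    "name": {"type": "string"},
    "slice_thickness": {"type": "number", "exclusiveMinimum": 0},
    "slices": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["z", "points"],
        "properties": {
          "z": {"type": "number"},
          "points": {
            "type": "array",
            "minItems": 3,
            "items": {
              "type": "array",
              "minItems": 3,
              "maxItems": 3,
              "items": {"type": "number"}
            }
          }
        }
      }
    }
  }
}
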