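{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "atlasfuse fusion report",
  "type": "object",
  "required": ["config", "atlases", "fused_volume_mm3"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["k_over_s", "quadrature_nodes", "margin_mm"],
      "properties": {
        "k_over_s": {"type": "number", "minimum": 0},
        "quadrature_nodes": {"type": "integer", "minimum": 32},
        "margin_mm": {"type": "number", "minimum": 0}
      }
    },
    "atlases": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["atlas_id", "ncc", "roi_voxel_count", "weight"],
        "properties": {
          "atlas_id": {"type": "string"},
          "ncc": {"type": "number", "minimum": -1, "maximum": 1},
          "roi_voxel_count": {"type": "integer", "minimum": 2},
          "weight": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "fused_volume_mm3": {"type": "number", "minimum": 0}
  }
}
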