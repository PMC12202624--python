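{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "reefcover pipeline configuration",
  "description": "YAML/JSON configuration accepted by `reefcover run-all --config` and PipelineConfig.from_dict. All covers and SDs are percentage points on the 0-100 scale.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "seed": {"type": "integer", "minimum": 0},
    "out_dir": {"type": "string"},
    "expert_method": {"enum": ["expert_visual", "expert_detailed"]},
    "min_bin_images": {"type": "integer", "minimum": 1},
    "generator": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_reefs": {"type": "integer", "minimum": 1},
        "sites_per_reef": {"type": "integer", "minimum": 1},
        "images_per_site": {"type": "integer", "minimum": 1},
        "category_mean_cover": {
          "type": "object",
          "additionalProperties": {"type": "number", "minimum": 0},
          "description": "Total-image basis; must sum to 100 +/- 0.01"
        },
        "between_site_sd": {"type": "number", "minimum": 0},
        "within_site_sd": {"type": "number", "minimum": 0},
        "expert_noise_sd": {"type": "number", "minimum": 0},
        "ai_bias": {"type": "object", "additionalProperties": {"type": "number"}},
        "citizen_bias": {"type": "object", "additionalProperties": {"type": "number"}},
        "ai_noise_sd": {"type": "number", "minimum": 0},
        "citizen_noise_sd": {"type": "number", "minimum": 0},
        "analyst_effect_sd": {"type": "number", "minimum": 0},
        "n_citizen_analysts": {"type": "integer", "minimum": 1},
        "analyses_per_image": {
          "type": "array", "items": {"type": "integer", "minimum": 1},
          "minItems": 2, "maxItems": 2
        },
        "cell_noise_sd": {"type": "number", "minimum": 0},
        "seed": {"type": "integer", "minimum": 0}
      }
    },
    "sim": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_values": {"type": "array", "items": {"type": "integer", "minimum": 1}},
        "m_values": {"type": "array", "items": {"type": "integer", "minimum": 1}},
        "runs": {"type": "integer", "minimum": 1},
        "threshold": {"type": "number", "exclusiveMinimum": 0},
        "target_fraction": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "seed": {"type": "integer", "minimum": 0},
        "sample_images_with_replacement": {"type": "boolean"}
      }
    },
    "power": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "effect": {"type": "number", "exclusiveMinimum": 0},
        "power": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "sides": {"enum": ["two", "one"]},
        "min_images_per_site": {"type": "integer", "minimum": 2}
      }
    }
  }
}
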