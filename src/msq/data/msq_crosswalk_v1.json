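{
  "version": "crosswalk-1.0",
  "entries": [
    {"target_instrument": "cms", "target_component": "rom", "source_item_ids": [1, 2, 3, 4, 5], "transform": "linear_rescale", "target_range": [0, 40], "target_items": 1},
    {"target_instrument": "cms", "target_component": "strength", "source_item_ids": [6], "transform": "weight_to_cms_points", "target_range": [0, 25], "target_items": 1},
    {"target_instrument": "cms", "target_component": "pain", "source_item_ids": [7, 8, 9, 10, 11, 12], "transform": "linear_rescale", "target_range": [0, 15], "target_items": 1},
    {"target_instrument": "cms", "target_component": "adl", "source_item_ids": [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27], "transform": "linear_rescale", "target_range": [0, 20], "target_items": 1},
    {"target_instrument": "spadi", "target_component": "pain", "source_item_ids": [7, 8, 9, 10, 11, 12], "transform": "invert_then_rescale", "target_range": [0, 100], "target_items": 5},
    {"target_instrument": "spadi", "target_component": "disability", "source_item_ids": [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27], "transform": "invert_then_rescale", "target_range": [0, 100], "target_items": 8},
    {"target_instrument": "dash", "target_component": "pain_symptoms", "source_item_ids": [7, 8, 9, 10, 11, 12], "transform": "invert_then_rescale", "target_range": [1, 5], "target_items": 6},
    {"target_instrument": "dash", "target_component": "function", "source_item_ids": [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27], "transform": "invert_then_rescale", "target_range": [1, 5], "target_items": 21},
    {"target_instrument": "dash", "target_component": "social_emotional", "source_item_ids": [28, 29, 30], "transform": "invert_then_rescale", "target_range": [1, 5], "target_items": 3}
  ]
}
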