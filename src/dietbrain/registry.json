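{
  "description": "Default 15-component pregnancy diet-quality score registry. Adherence to Dutch dietary guidelines for pregnant individuals; each component scores in [0,1], total in [0,15].",
  "components": [
    {"name": "vegetables", "kind": "adequacy", "cutoff": 200.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "fruit", "kind": "adequacy", "cutoff": 200.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "whole_grains", "kind": "adequacy", "cutoff": 90.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "legumes", "kind": "adequacy", "cutoff": 135.0, "unit": "g/wk", "direction": "higher-is-better"},
    {"name": "nuts", "kind": "adequacy", "cutoff": 15.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "dairy", "kind": "adequacy", "cutoff": 300.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "fish", "kind": "adequacy", "cutoff": 100.0, "unit": "g/wk", "direction": "higher-is-better"},
    {"name": "tea", "kind": "adequacy", "cutoff": 450.0, "unit": "g/d", "direction": "higher-is-better"},
    {"name": "grain_quality_ratio", "kind": "ratio", "cutoff": 1.0, "unit": "fraction", "direction": "higher-is-better"},
    {"name": "soft_fat_ratio", "kind": "ratio", "cutoff": 1.0, "unit": "fraction", "direction": "higher-is-better"},
    {"name": "red_meat", "kind": "moderation", "cutoff": 375.0, "unit": "g/wk", "direction": "lower-is-better"},
    {"name": "sugary_beverages", "kind": "moderation", "cutoff": 150.0, "unit": "g/d", "direction": "lower-is-better"},
    {"name": "alcohol_any", "kind": "binary", "cutoff": null, "unit": "yes/no", "direction": "lower-is-better"},
    {"name": "salt", "kind": "moderation", "cutoff": 6.0, "unit": "g/d", "direction": "lower-is-better"},
    {"name": "folic_acid", "kind": "categorical", "cutoff": null, "unit": "category", "direction": "higher-is-better"}
  ]
}
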