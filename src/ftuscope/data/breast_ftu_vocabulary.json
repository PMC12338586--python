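{
  "organ": "breast",
  "terms": [
    {
      "category_path": ["glandular", "non-tumoral"],
      "color": [64, 160, 64],
      "id": 1,
      "name": "normal duct"
    },
    {
      "category_path": ["glandular", "non-tumoral"],
      "color": [120, 190, 120],
      "id": 2,
      "name": "normal lobule"
    },
    {
      "category_path": ["glandular", "precursor"],
      "color": [200, 200, 90],
      "id": 3,
      "name": "UDH"
    },
    {
      "category_path": ["glandular", "precursor"],
      "color": [220, 180, 70],
      "id": 4,
      "name": "ADH"
    },
    {
      "category_path": ["glandular", "tumoral", "in-situ"],
      "color": [240, 150, 60],
      "id": 5,
      "name": "DCIS"
    },
    {
      "category_path": ["glandular", "tumoral", "in-situ"],
      "color": [230, 120, 60],
      "id": 6,
      "name": "LCIS"
    },
    {
      "category_path": ["glandular", "tumoral", "invasive"],
      "color": [220, 90, 70],
      "id": 7,
      "name": "cribriform"
    },
    {
      "category_path": ["glandular", "tumoral", "invasive"],
      "color": [180, 40, 40],
      "id": 8,
      "name": "solid"
    },
    {
      "category_path": ["stromal", "nerve"],
      "color": [90, 120, 200],
      "id": 9,
      "name": "nerve"
    },
    {
      "category_path": ["stromal", "vascular"],
      "color": [60, 90, 220],
      "id": 10,
      "name": "vascular"
    },
    {
      "category_path": ["stromal", "inflammation"],
      "color": [130, 80, 180],
      "id": 11,
      "name": "inflammation"
    },
    {
      "category_path": ["artifact"],
      "color": [128, 128, 128],
      "id": 12,
      "name": "artifact"
    }
  ],
  "version": "1.0"
}
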