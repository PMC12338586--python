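{
  "organ": "prostate",
  "terms": [
    {
      "category_path": ["glandular", "non-tumoral"],
      "color": [64, 160, 64],
      "id": 1,
      "name": "normal gland"
    },
    {
      "category_path": ["glandular", "non-tumoral"],
      "color": [120, 190, 120],
      "id": 2,
      "name": "atrophic gland"
    },
    {
      "category_path": ["glandular", "precursor"],
      "color": [220, 200, 80],
      "id": 3,
      "name": "PIN"
    },
    {
      "category_path": ["glandular", "tumoral", "GP3"],
      "color": [240, 170, 60],
      "id": 4,
      "name": "Gleason pattern 3"
    },
    {
      "category_path": ["glandular", "tumoral", "GP4", "cribriform"],
      "color": [230, 110, 50],
      "id": 5,
      "name": "Gleason pattern 4 cribriform"
    },
    {
      "category_path": ["glandular", "tumoral", "GP4", "poorly formed"],
      "color": [220, 90, 70],
      "id": 6,
      "name": "Gleason pattern 4 poorly formed"
    },
    {
      "category_path": ["glandular", "tumoral", "GP4", "fused"],
      "color": [210, 70, 90],
      "id": 7,
      "name": "Gleason pattern 4 fused"
    },
    {
      "category_path": ["glandular", "tumoral", "GP4", "glomeruloid"],
      "color": [200, 60, 110],
      "id": 8,
      "name": "Gleason pattern 4 glomeruloid"
    },
    {
      "category_path": ["glandular", "tumoral", "GP5", "solid nests"],
      "color": [180, 40, 40],
      "id": 9,
      "name": "Gleason pattern 5 solid nests",
      "provisional": true
    },
    {
      "category_path": ["glandular", "tumoral", "GP5", "solid sheets"],
      "color": [160, 30, 30],
      "id": 10,
      "name": "Gleason pattern 5 solid sheets",
      "provisional": true
    },
    {
      "category_path": ["glandular", "tumoral", "GP5", "cords"],
      "color": [140, 20, 40],
      "id": 11,
      "name": "Gleason pattern 5 cords",
      "provisional": true
    },
    {
      "category_path": ["glandular", "tumoral", "GP5", "single cells"],
      "color": [120, 10, 50],
      "id": 12,
      "name": "Gleason pattern 5 single cells",
      "provisional": true
    },
    {
      "category_path": ["glandular", "tumoral", "GP5", "comedonecrosis"],
      "color": [100, 10, 60],
      "id": 13,
      "name": "Gleason pattern 5 comedonecrosis",
      "provisional": true
    },
    {
      "category_path": ["stromal", "nerve"],
      "color": [90, 120, 200],
      "id": 14,
      "name": "nerve"
    },
    {
      "category_path": ["stromal", "vascular"],
      "color": [60, 90, 220],
      "id": 15,
      "name": "vascular"
    },
    {
      "category_path": ["stromal", "inflammation"],
      "color": [130, 80, 180],
      "id": 16,
      "name": "inflammation"
    },
    {
      "category_path": ["artifact"],
      "color": [128, 128, 128],
      "id": 17,
      "name": "artifact"
    }
  ],
  "version": "1.0"
}
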