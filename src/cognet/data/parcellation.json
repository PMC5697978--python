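{
  "description": "Synthetic bilateral parcellation dictionary covering every region used by the five shipped cognitive networks, plus filler white-matter and CSF compartments so that tissue-group volumetry is meaningful. Labels are editable; real studies substitute their own label scheme.",
  "regions": {
    "medial_prefrontal_cortex": {"labels": {"L": 1, "R": 2}, "tissue": "GM", "weight": 1.0},
    "cingulate_cortex": {"labels": {"L": 3, "R": 4}, "tissue": "GM", "weight": 1.0},
    "precuneus": {"labels": {"L": 5, "R": 6}, "tissue": "GM", "weight": 1.0},
    "lateral_parietal_cortex": {"labels": {"L": 7, "R": 8}, "tissue": "GM", "weight": 1.0},
    "thalamus": {"labels": {"L": 9, "R": 10}, "tissue": "GM", "weight": 2.0},
    "superior_parietal_lobule": {"labels": {"L": 11, "R": 12}, "tissue": "GM", "weight": 1.0},
    "middle_frontal_gyrus": {"labels": {"L": 13, "R": 14}, "tissue": "GM", "weight": 1.0},
    "superior_frontal_gyrus": {"labels": {"L": 15, "R": 16}, "tissue": "GM", "weight": 1.0},
    "angular_gyrus": {"labels": {"L": 17, "R": 18}, "tissue": "GM", "weight": 1.0},
    "supramarginal_gyrus": {"labels": {"L": 19, "R": 20}, "tissue": "GM", "weight": 1.0},
    "inferior_temporal_gyrus": {"labels": {"L": 21, "R": 22}, "tissue": "GM", "weight": 1.0},
    "medial_occipitotemporal_gyrus": {"labels": {"L": 23, "R": 24}, "tissue": "GM", "weight": 1.0},
    "middle_temporal_gyrus": {"labels": {"L": 25, "R": 26}, "tissue": "GM", "weight": 1.0},
    "temporal_pole": {"labels": {"L": 27, "R": 28}, "tissue": "GM", "weight": 1.0},
    "inferior_frontal_gyrus": {"labels": {"L": 29, "R": 30}, "tissue": "GM", "weight": 1.0},
    "fusiform_gyrus": {"labels": {"L": 31, "R": 32}, "tissue": "GM", "weight": 1.0},
    "hippocampal_formation": {"labels": {"L": 33, "R": 34}, "tissue": "GM", "weight": 1.0},
    "fornix": {"labels": {"L": 35, "R": 36}, "tissue": "WM", "weight": 0.5},
    "deep_white_matter": {"labels": {"L": 37, "R": 38}, "tissue": "WM", "weight": 8.0},
    "periventricular_white_matter": {"labels": {"L": 39, "R": 40}, "tissue": "WM", "weight": 2.0},
    "lateral_ventricle": {"labels": {"L": 41, "R": 42}, "tissue": "CSF", "weight": 2.0},
    "third_ventricle": {"labels": {"L": 43, "R": 44}, "tissue": "CSF", "weight": 0.5},
    "subarachnoid_csf": {"labels": {"L": 45, "R": 46}, "tissue": "CSF", "weight": 2.0}
  }
}
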