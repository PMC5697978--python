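{
  "description": "Five cognitive resting-state networks. Each region name is bilateral and expands to left/right nodes. The default-mode network treats the entire cingulate cortex as one region, giving 4 bilateral regions (8 nodes, 28 links). The attention network is shipped with its full 6-region listing (12 nodes, 66 links); see docs/methods.md for the known link-count discrepancy.",
  "networks": [
    {
      "name": "default_mode",
      "regions": [
        "medial_prefrontal_cortex",
        "cingulate_cortex",
        "precuneus",
        "lateral_parietal_cortex"
      ]
    },
    {
      "name": "attention",
      "regions": [
        "thalamus",
        "superior_parietal_lobule",
        "middle_frontal_gyrus",
        "superior_frontal_gyrus",
        "angular_gyrus",
        "supramarginal_gyrus"
      ]
    },
    {
      "name": "verbal_memory",
      "regions": [
        "inferior_temporal_gyrus",
        "medial_occipitotemporal_gyrus",
        "middle_temporal_gyrus",
        "temporal_pole",
        "angular_gyrus",
        "inferior_frontal_gyrus"
      ]
    },
    {
      "name": "memory",
      "regions": [
        "angular_gyrus",
        "fusiform_gyrus",
        "superior_parietal_lobule",
        "supramarginal_gyrus",
        "hippocampal_formation",
        "superior_frontal_gyrus"
      ]
    },
    {
      "name": "visuospatial_working_memory",
      "regions": [
        "cingulate_cortex",
        "superior_frontal_gyrus",
        "fornix",
        "superior_parietal_lobule",
        "supramarginal_gyrus"
      ]
    }
  ]
}
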