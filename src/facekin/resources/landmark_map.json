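{
  "version": 1,
  "description": "Mapping from 478-point face-mesh ids to clinical anthropometric landmarks. Entries with more than one mesh id are located at the arithmetic mean of those mesh points. Side tags refer to the participant's anatomical side.",
  "landmarks": {
    "pogonion":                 {"ids": [199],      "side": "mid"},
    "labrale_superius":         {"ids": [0],        "side": "mid"},
    "labrale_inferius":         {"ids": [17],       "side": "mid"},
    "stomion_superius":         {"ids": [13],       "side": "mid"},
    "stomion_inferius":         {"ids": [14],       "side": "mid"},
    "mid_fissure_upper_right":  {"ids": [81],       "side": "right"},
    "mid_fissure_upper_left":   {"ids": [311],      "side": "left"},
    "mid_fissure_lower_right":  {"ids": [178],      "side": "right"},
    "mid_fissure_lower_left":   {"ids": [402],      "side": "left"},
    "cheilion_right":           {"ids": [61],       "side": "right"},
    "cheilion_left":            {"ids": [291],      "side": "left"},
    "gonion_right":             {"ids": [172],      "side": "right"},
    "gonion_left":              {"ids": [397],      "side": "left"},
    "subnasale":                {"ids": [2],        "side": "mid"},
    "tragion_right":            {"ids": [93],       "side": "right"},
    "tragion_left":             {"ids": [323],      "side": "left"},
    "zygion_right":             {"ids": [227],      "side": "right"},
    "zygion_left":              {"ids": [447],      "side": "left"},
    "sellion":                  {"ids": [168],      "side": "mid"},
    "glabella":                 {"ids": [9],        "side": "mid"},
    "inner_canthus_right":      {"ids": [133],      "side": "right"},
    "inner_canthus_left":       {"ids": [362],      "side": "left"},
    "frontotemporale_right":    {"ids": [68, 71],   "side": "right"},
    "frontotemporale_left":     {"ids": [301, 298], "side": "left"}
  }
}
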