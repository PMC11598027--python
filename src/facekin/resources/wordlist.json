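{
  "version": 1,
  "description": "The 20 probe words of the mandibular and labial-facial assessment stages, their movement-similarity classes, and the two movement groups. Word order is canonical and used for deterministic tie-breaking.",
  "words": ["Ba", "Map", "Ham", "Pam", "Eye", "Pie", "Umm", "Bob", "Pup", "Papa",
            "Bee", "Peep", "Feet", "Boy", "Bush", "Moon", "Phone", "Fish", "Wash", "Show"],
  "classes": {
    "1": ["Ba", "Map", "Ham", "Pam"],
    "2": ["Eye", "Pie"],
    "3": ["Umm", "Bob", "Pup"],
    "4": ["Bee", "Peep", "Feet"],
    "5": ["Boy", "Bush", "Moon", "Phone", "Fish", "Wash", "Show"]
  },
  "excluded_at_class_level": ["Papa"],
  "groups": {
    "mandibular": ["Ba", "Map", "Ham", "Pam", "Eye", "Pie", "Umm", "Bob", "Pup", "Papa"],
    "labial_facial": ["Bee", "Peep", "Feet", "Boy", "Bush", "Moon", "Phone", "Fish", "Wash", "Show"]
  }
}
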