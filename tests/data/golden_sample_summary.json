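{
  "ambiguous_pairs": [],
  "class_counts": {
    "Ambiguous mass shift": 20,
    "Artefact": 9,
    "Post-translational": 32
  },
  "mass_shifts": {
    "+103.0684": 103.0684,
    "+15.9949": 15.994915,
    "Acetyl": 42.010565,
    "Cation:K": 37.955882,
    "Phospho": 79.966331
  },
  "shared": {
    "cells": [
      [
        "+103.0684",
        "+103.0684",
        6
      ],
      [
        "+103.0684",
        "Phospho",
        1
      ],
      [
        "+15.9949",
        "+15.9949",
        14
      ],
      [
        "Acetyl",
        "Acetyl",
        12
      ],
      [
        "Cation:K",
        "Cation:K",
        9
      ],
      [
        "Phospho",
        "Phospho",
        20
      ]
    ],
    "labels": [
      "+103.0684",
      "+15.9949",
      "Acetyl",
      "Cation:K",
      "Phospho"
    ]
  },
  "site_counts": {
    "+103.0684": 6,
    "+15.9949": 14,
    "Acetyl": 12,
    "Cation:K": 9,
    "Phospho": 20
  },
  "types": [
    {
      "count": 6,
      "label": "+103.0684",
      "mass_shift": 103.0684
    },
    {
      "count": 14,
      "label": "+15.9949",
      "mass_shift": 15.994915
    },
    {
      "count": 12,
      "label": "Acetyl",
      "mass_shift": 42.010565
    },
    {
      "count": 9,
      "label": "Cation:K",
      "mass_shift": 37.955882
    },
    {
      "count": 20,
      "label": "Phospho",
      "mass_shift": 79.966331
    }
  ]
}
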