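{
  "schema_version": 1,
  "provenance": "initial expert-elicited rule base",
  "attributes": [
    {
      "name": "ARTUL",
      "labels": [
        "S",
        "N",
        "B"
      ],
      "ref_values": [
        4.0,
        8.0,
        12.0
      ]
    },
    {
      "name": "RTT",
      "labels": [
        "S",
        "N",
        "L"
      ],
      "ref_values": [
        5.0,
        10.0,
        15.0
      ]
    },
    {
      "name": "MAMS",
      "labels": [
        "S",
        "N",
        "H"
      ],
      "ref_values": [
        5.0,
        8.0,
        11.0
      ]
    }
  ],
  "attribute_weights": [
    1.0,
    1.0,
    1.0
  ],
  "grade_labels": [
    "I",
    "II",
    "III",
    "IV"
  ],
  "grade_utilities": [
    1.0,
    2.0,
    3.0,
    4.0
  ],
  "rules": [
    {
      "antecedent": [
        "S",
        "S",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        1.0,
        0.0,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "S",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.9,
        0.1,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "S",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.8,
        0.2,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "N",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.9,
        0.1,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "N",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.8,
        0.2,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "N",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.7,
        0.3,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "L",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.6,
        0.3,
        0.1,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "L",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.5,
        0.4,
        0.1,
        0.0
      ]
    },
    {
      "antecedent": [
        "S",
        "L",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.9,
        0.1,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "S",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.8,
        0.2,
        0.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "S",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.4,
        0.5,
        0.1,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "S",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.3,
        0.4,
        0.3,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "N",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.2,
        0.6,
        0.2,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "N",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.1,
        0.2,
        0.7,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "N",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.3,
        0.7,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "L",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.1,
        0.9,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "L",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        1.0,
        0.0
      ]
    },
    {
      "antecedent": [
        "N",
        "L",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.9,
        0.1
      ]
    },
    {
      "antecedent": [
        "B",
        "S",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.3,
        0.6,
        0.1
      ]
    },
    {
      "antecedent": [
        "B",
        "S",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.2,
        0.7,
        0.1
      ]
    },
    {
      "antecedent": [
        "B",
        "S",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.1,
        0.8,
        0.1
      ]
    },
    {
      "antecedent": [
        "B",
        "N",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.7,
        0.3
      ]
    },
    {
      "antecedent": [
        "B",
        "N",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.3,
        0.7
      ]
    },
    {
      "antecedent": [
        "B",
        "N",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.1,
        0.9
      ]
    },
    {
      "antecedent": [
        "B",
        "L",
        "S"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.2,
        0.8
      ]
    },
    {
      "antecedent": [
        "B",
        "L",
        "N"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.1,
        0.9
      ]
    },
    {
      "antecedent": [
        "B",
        "L",
        "H"
      ],
      "theta": 1.0,
      "beliefs": [
        0.0,
        0.0,
        0.0,
        1.0
      ]
    }
  ]
}
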