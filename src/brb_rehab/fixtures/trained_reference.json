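{
  "schema_version": 1,
  "provenance": "reference trained parameters",
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
        0.835,
        0.15,
        0.013,
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
        0.814,
        0.176,
        0.01,
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
        0.723,
        0.237,
        0.03,
        0.01
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
        0.812,
        0.117,
        0.064,
        0.007
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
        0.837,
        0.105,
        0.047,
        0.011
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
        0.643,
        0.348,
        0.008,
        0.001
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
        0.489,
        0.377,
        0.103,
        0.031
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
        0.466,
        0.279,
        0.228,
        0.027
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
        0.027,
        0.813,
        0.132,
        0.028
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
        0.774,
        0.196,
        0.03,
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
        0.496,
        0.386,
        0.107,
        0.011
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
        0.319,
        0.376,
        0.245,
        0.06
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
        0.197,
        0.631,
        0.123,
        0.049
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
        0.089,
        0.217,
        0.597,
        0.097
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
        0.013,
        0.321,
        0.564,
        0.102
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
        0.003,
        0.064,
        0.877,
        0.056
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
        0.032,
        0.005,
        0.899,
        0.064
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
        0.001,
        0.006,
        0.9,
        0.093
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
        0.01,
        0.28,
        0.632,
        0.078
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
        0.002,
        0.121,
        0.796,
        0.081
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
        0.006,
        0.012,
        0.843,
        0.139
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
        0.004,
        0.053,
        0.698,
        0.245
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
        0.003,
        0.027,
        0.325,
        0.645
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
        0.003,
        0.064,
        0.182,
        0.751
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
        0.006,
        0.009,
        0.311,
        0.674
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
        0.001,
        0.003,
        0.082,
        0.914
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
        0.007,
        0.021,
        0.036,
        0.936
      ]
    }
  ]
}
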