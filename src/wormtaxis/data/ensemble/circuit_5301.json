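{
  "chem": [
    {
      "post": "AIYL",
      "pre": "ASEL",
      "w": 15.0
    },
    {
      "post": "AIYR",
      "pre": "ASEL",
      "w": 15.0
    },
    {
      "post": "AIYL",
      "pre": "ASER",
      "w": -15.0
    },
    {
      "post": "AIYR",
      "pre": "ASER",
      "w": -15.0
    },
    {
      "post": "AIZL",
      "pre": "AIYL",
      "w": 15.0
    },
    {
      "post": "AIZR",
      "pre": "AIYR",
      "w": 15.0
    },
    {
      "post": "SMBDL",
      "pre": "AIZL",
      "w": -15.0
    },
    {
      "post": "SMBVL",
      "pre": "AIZL",
      "w": -15.0
    },
    {
      "post": "SMBDR",
      "pre": "AIZR",
      "w": -14.313735582553244
    },
    {
      "post": "SMBVR",
      "pre": "AIZR",
      "w": -14.313735582553244
    }
  ],
  "gaps": [
    {
      "a": "AIYL",
      "b": "AIYR",
      "g": 0.15009855575981168
    },
    {
      "a": "AIZL",
      "b": "AIZR",
      "g": 1.1759669515632407
    }
  ],
  "neurons": {
    "AIYL": {
      "tau": 1.5,
      "theta": -0.07403160281199739,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIYR": {
      "tau": 1.5,
      "theta": -0.1366973222845509,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZL": {
      "tau": 1.5,
      "theta": -6.72156212260769,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZR": {
      "tau": 1.5,
      "theta": -7.133550883275,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "SMBDL": {
      "tau": 1.5,
      "theta": 5.418175164964044,
      "w_osc": 10.0,
      "w_self": 8.805664627046841
    },
    "SMBDR": {
      "tau": 1.5,
      "theta": 5.973630846293084,
      "w_osc": 10.0,
      "w_self": 8.75429801841436
    },
    "SMBVL": {
      "tau": 1.5,
      "theta": 5.418175164964044,
      "w_osc": 10.0,
      "w_self": 8.805664627046841
    },
    "SMBVR": {
      "tau": 1.5,
      "theta": 5.973630846293084,
      "w_osc": 10.0,
      "w_self": 8.75429801841436
    }
  },
  "provenance": {
    "genotype": [
      -0.8034411728239481,
      -0.45316462583990835,
      1.0,
      1.0,
      -1.0,
      -1.0,
      -0.004935440187466496,
      -0.009113154818970052,
      -0.9799868592320251,
      1.0,
      1.0,
      -0.4481041415071794,
      -0.47557005888500004,
      -0.8432044064582346,
      -1.0,
      -0.954249038836883,
      0.3612116776642694,
      0.39824205641953875,
      0.5870443084697894,
      0.5836198678942908
    ],
    "objective": {
      "alphas": [
        -0.35,
        -0.25,
        -0.15,
        -0.08,
        -0.03
      ],
      "dt": 0.02,
      "duration": 800.0,
      "headings": [
        0.3,
        1.4,
        2.4,
        -0.8,
        -1.9,
        -2.9
      ],
      "pirouette_rate": 0.033
    },
    "parameter_map": {
      "constants": {
        "tau": 1.5,
        "w_nmj": 1.0,
        "w_osc": 10.0
      },
      "slots": [
        {
          "high": 4.2,
          "kind": "sensory_N",
          "low": 0.1,
          "name": "N",
          "targets": [
            "ASEL",
            "ASER"
          ]
        },
        {
          "high": 4.2,
          "kind": "sensory_M",
          "low": 0.1,
          "name": "M",
          "targets": [
            "ASEL",
            "ASER"
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_ASEL_AIYL",
          "targets": [
            [
              "ASEL",
              "AIYL"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_ASEL_AIYR",
          "targets": [
            [
              "ASEL",
              "AIYR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_ASER_AIYL",
          "targets": [
            [
              "ASER",
              "AIYL"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_ASER_AIYR",
          "targets": [
            [
              "ASER",
              "AIYR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_AIYL",
          "targets": [
            "AIYL"
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_AIYR",
          "targets": [
            "AIYR"
          ]
        },
        {
          "high": 15.0,
          "kind": "gap",
          "low": 0.0,
          "name": "g_AIY",
          "targets": [
            [
              "AIYL",
              "AIYR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_AIYL_AIZL",
          "targets": [
            [
              "AIYL",
              "AIZL"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_AIYR_AIZR",
          "targets": [
            [
              "AIYR",
              "AIZR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_AIZL",
          "targets": [
            "AIZL"
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_AIZR",
          "targets": [
            "AIZR"
          ]
        },
        {
          "high": 15.0,
          "kind": "gap",
          "low": 0.0,
          "name": "g_AIZ",
          "targets": [
            [
              "AIZL",
              "AIZR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_AIZL_SMBL",
          "targets": [
            [
              "AIZL",
              "SMBDL"
            ],
            [
              "AIZL",
              "SMBVL"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "chem",
          "low": -15.0,
          "name": "w_AIZR_SMBR",
          "targets": [
            [
              "AIZR",
              "SMBDR"
            ],
            [
              "AIZR",
              "SMBVR"
            ]
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_SMBL",
          "targets": [
            "SMBDL",
            "SMBVL"
          ]
        },
        {
          "high": 15.0,
          "kind": "theta",
          "low": -15.0,
          "name": "theta_SMBR",
          "targets": [
            "SMBDR",
            "SMBVR"
          ]
        },
        {
          "high": 15.0,
          "kind": "w_self",
          "low": -15.0,
          "name": "wself_SMBL",
          "targets": [
            "SMBDL",
            "SMBVL"
          ]
        },
        {
          "high": 15.0,
          "kind": "w_self",
          "low": -15.0,
          "name": "wself_SMBR",
          "targets": [
            "SMBDR",
            "SMBVR"
          ]
        }
      ],
      "version": "1"
    },
    "perturbation_sigma": 0.02,
    "pipeline": "perturbed multi-round Nelder-Mead refinement of a common-random-number chemotaxis-index objective",
    "retest": {
      "ci_conical": 0.11178380283442006,
      "ci_gaussian": 0.11982634454036345,
      "dt": 0.01,
      "duration": 1000.0,
      "n_assays": 25,
      "reliability_conical": 0.0,
      "reliability_gaussian": 0.0
    },
    "seed": 5301
  },
  "schema_version": "1",
  "sensory": {
    "ASEL": {
      "M": 1.221012517028188,
      "N": 0.5029455957109065,
      "polarity": "ON"
    },
    "ASER": {
      "M": 1.221012517028188,
      "N": 0.5029455957109065,
      "polarity": "OFF"
    }
  },
  "w_nmj": 1.0
}
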