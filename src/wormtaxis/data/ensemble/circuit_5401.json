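{
  "chem": [
    {
      "post": "AIYL",
      "pre": "ASEL",
      "w": 10.2255448410811
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
      "w": -14.98591305976199
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
      "w": -15.0
    },
    {
      "post": "SMBVR",
      "pre": "AIZR",
      "w": -15.0
    }
  ],
  "gaps": [
    {
      "a": "AIYL",
      "b": "AIYR",
      "g": 0.0
    },
    {
      "a": "AIZL",
      "b": "AIZR",
      "g": 4.879734733333596
    }
  ],
  "neurons": {
    "AIYL": {
      "tau": 1.5,
      "theta": -0.0007065816227580513,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIYR": {
      "tau": 1.5,
      "theta": 0.001576102807552715,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZL": {
      "tau": 1.5,
      "theta": -6.802130168575863,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZR": {
      "tau": 1.5,
      "theta": -6.33909940126898,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "SMBDL": {
      "tau": 1.5,
      "theta": 5.192742770741653,
      "w_osc": 10.0,
      "w_self": 10.26989404467232
    },
    "SMBDR": {
      "tau": 1.5,
      "theta": 8.62291957899544,
      "w_osc": 10.0,
      "w_self": 8.135667206592085
    },
    "SMBVL": {
      "tau": 1.5,
      "theta": 5.192742770741653,
      "w_osc": 10.0,
      "w_self": 10.26989404467232
    },
    "SMBVR": {
      "tau": 1.5,
      "theta": 8.62291957899544,
      "w_osc": 10.0,
      "w_self": 8.135667206592085
    }
  },
  "provenance": {
    "genotype": [
      -0.8300611370757145,
      -0.5295760754426958,
      0.6817029894054066,
      1.0,
      -1.0,
      -0.9990608706507993,
      -4.7105441517238274e-05,
      0.00010507352050341561,
      -1.0,
      1.0,
      1.0,
      -0.4534753445717242,
      -0.42260662675126537,
      -0.3493687022221873,
      -1.0,
      -1.0,
      0.3461828513827768,
      0.5748613052663626,
      0.6846596029781546,
      0.5423778137728058
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
    "perturbation_sigma": 0.0,
    "pipeline": "perturbed multi-round Nelder-Mead refinement of a common-random-number chemotaxis-index objective",
    "retest": {
      "ci_conical": 0.21380664968148408,
      "ci_gaussian": 0.201598578806637,
      "dt": 0.01,
      "duration": 1000.0,
      "n_assays": 25,
      "reliability_conical": 0.04,
      "reliability_gaussian": 0.0
    },
    "seed": 5401
  },
  "schema_version": "1",
  "sensory": {
    "ASEL": {
      "M": 1.0643690453424737,
      "N": 0.4483746689947853,
      "polarity": "ON"
    },
    "ASER": {
      "M": 1.0643690453424737,
      "N": 0.4483746689947853,
      "polarity": "OFF"
    }
  },
  "w_nmj": 1.0
}
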