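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
      "w": -14.30886442270356
    },
    {
      "post": "SMBVR",
      "pre": "AIZR",
      "w": -14.30886442270356
    }
  ],
  "gaps": [
    {
      "a": "AIYL",
      "b": "AIYR",
      "g": 0.38230592891193793
    },
    {
      "a": "AIZL",
      "b": "AIZR",
      "g": 1.3862672119682595
    }
  ],
  "neurons": {
    "AIYL": {
      "tau": 1.5,
      "theta": -0.0010618117060481325,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIYR": {
      "tau": 1.5,
      "theta": 0.002937379683608299,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZL": {
      "tau": 1.5,
      "theta": -6.822445854432429,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZR": {
      "tau": 1.5,
      "theta": -6.87878609953489,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "SMBDL": {
      "tau": 1.5,
      "theta": 5.478365852023352,
      "w_osc": 10.0,
      "w_self": 9.406803974372291
    },
    "SMBDR": {
      "tau": 1.5,
      "theta": 6.249002921283033,
      "w_osc": 10.0,
      "w_self": 8.567454730266576
    },
    "SMBVL": {
      "tau": 1.5,
      "theta": 5.478365852023352,
      "w_osc": 10.0,
      "w_self": 9.406803974372291
    },
    "SMBVR": {
      "tau": 1.5,
      "theta": 6.249002921283033,
      "w_osc": 10.0,
      "w_self": 8.567454730266576
    }
  },
  "provenance": {
    "genotype": [
      -0.8230578989964635,
      -0.4426697571394164,
      1.0,
      1.0,
      -1.0,
      -1.0,
      -7.078744706986181e-05,
      0.00019582531224055148,
      -0.9490258761450749,
      1.0,
      1.0,
      -0.4548297236288285,
      -0.45858573996899266,
      -0.8151643717375654,
      -1.0,
      -0.9539242948469041,
      0.3652243901348901,
      0.4166001947522023,
      0.6271202649581527,
      0.5711636486844386
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
      "ci_conical": 0.2110317841998824,
      "ci_gaussian": 0.22881050959041893,
      "dt": 0.01,
      "duration": 1000.0,
      "n_assays": 25,
      "reliability_conical": 0.12,
      "reliability_gaussian": 0.0
    },
    "seed": 5402
  },
  "schema_version": "1",
  "sensory": {
    "ASEL": {
      "M": 1.2425269978641964,
      "N": 0.46273130705724985,
      "polarity": "ON"
    },
    "ASER": {
      "M": 1.2425269978641964,
      "N": 0.46273130705724985,
      "polarity": "OFF"
    }
  },
  "w_nmj": 1.0
}
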