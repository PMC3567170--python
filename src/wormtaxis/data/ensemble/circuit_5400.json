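{
  "chem": [
    {
      "post": "AIYL",
      "pre": "ASEL",
      "w": 6.277785322737046
    },
    {
      "post": "AIYR",
      "pre": "ASEL",
      "w": 6.682122521862368
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
      "g": 4.816252927596047
    }
  ],
  "neurons": {
    "AIYL": {
      "tau": 1.5,
      "theta": -0.0006294072165395903,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIYR": {
      "tau": 1.5,
      "theta": 0.0018197205736534272,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZL": {
      "tau": 1.5,
      "theta": -6.772712867522582,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZR": {
      "tau": 1.5,
      "theta": -6.245029485911511,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "SMBDL": {
      "tau": 1.5,
      "theta": 5.042812949279281,
      "w_osc": 10.0,
      "w_self": 10.446553056351483
    },
    "SMBDR": {
      "tau": 1.5,
      "theta": 6.82610746065054,
      "w_osc": 10.0,
      "w_self": 10.09482388241863
    },
    "SMBVL": {
      "tau": 1.5,
      "theta": 5.042812949279281,
      "w_osc": 10.0,
      "w_self": 10.446553056351483
    },
    "SMBVR": {
      "tau": 1.5,
      "theta": 6.82610746065054,
      "w_osc": 10.0,
      "w_self": 10.09482388241863
    }
  },
  "provenance": {
    "genotype": [
      -0.873550865765554,
      -0.6396823104430686,
      0.41851902151580306,
      0.4454748347908246,
      -1.0,
      -1.0,
      -4.19604811025787e-05,
      0.00012131470491008478,
      -1.0,
      1.0,
      1.0,
      -0.4515141911681721,
      -0.4163352990607673,
      -0.35783294298719376,
      -1.0,
      -1.0,
      0.33618752995195217,
      0.4550738307100358,
      0.6964368704234323,
      0.6729882588279086
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
      "ci_conical": 0.18749463298712812,
      "ci_gaussian": 0.29279178454822735,
      "dt": 0.01,
      "duration": 1000.0,
      "n_assays": 25,
      "reliability_conical": 0.12,
      "reliability_gaussian": 0.04
    },
    "seed": 5400
  },
  "schema_version": "1",
  "sensory": {
    "ASEL": {
      "M": 0.8386512635917095,
      "N": 0.35922072518061443,
      "polarity": "ON"
    },
    "ASER": {
      "M": 0.8386512635917095,
      "N": 0.35922072518061443,
      "polarity": "OFF"
    }
  },
  "w_nmj": 1.0
}
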