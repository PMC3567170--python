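{
  "chem": [
    {
      "post": "AIYL",
      "pre": "ASEL",
      "w": 10.170715591243372
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
      "w": -14.993554799860211
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
      "g": 4.93063227390704
    }
  ],
  "neurons": {
    "AIYL": {
      "tau": 1.5,
      "theta": 0.059949655518156675,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIYR": {
      "tau": 1.5,
      "theta": 0.09499619933260561,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZL": {
      "tau": 1.5,
      "theta": -7.170702290560274,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "AIZR": {
      "tau": 1.5,
      "theta": -6.396054796408677,
      "w_osc": 0.0,
      "w_self": 0.0
    },
    "SMBDL": {
      "tau": 1.5,
      "theta": 5.0880496382865275,
      "w_osc": 10.0,
      "w_self": 10.026241415143396
    },
    "SMBDR": {
      "tau": 1.5,
      "theta": 8.6096496675607,
      "w_osc": 10.0,
      "w_self": 8.67758935327199
    },
    "SMBVL": {
      "tau": 1.5,
      "theta": 5.0880496382865275,
      "w_osc": 10.0,
      "w_self": 10.026241415143396
    },
    "SMBVR": {
      "tau": 1.5,
      "theta": 8.6096496675607,
      "w_osc": 10.0,
      "w_self": 8.67758935327199
    }
  },
  "provenance": {
    "genotype": [
      -0.8201901234925046,
      -0.4811992717626411,
      0.6780477060828917,
      1.0,
      -1.0,
      -0.9995703199906808,
      0.003996643701210478,
      0.006333079955506976,
      -1.0,
      1.0,
      1.0,
      -0.47804681937068494,
      -0.4264036530939118,
      -0.34258236347906135,
      -1.0,
      -1.0,
      0.33920330921910175,
      0.5739766445040467,
      0.6684160943428932,
      0.5785059568847994
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
      "ci_conical": 0.12889566246914413,
      "ci_gaussian": 0.13656439140714563,
      "dt": 0.01,
      "duration": 1000.0,
      "n_assays": 25,
      "reliability_conical": 0.08,
      "reliability_gaussian": 0.0
    },
    "seed": 5200
  },
  "schema_version": "1",
  "sensory": {
    "ASEL": {
      "M": 1.163541492886586,
      "N": 0.46861024684036556,
      "polarity": "ON"
    },
    "ASER": {
      "M": 1.163541492886586,
      "N": 0.46861024684036556,
      "polarity": "OFF"
    }
  },
  "w_nmj": 1.0
}
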