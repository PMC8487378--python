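{
  "$defs": {
    "FitReport": {
      "properties": {
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "iterations": {
          "title": "Iterations",
          "type": "integer"
        },
        "k": {
          "title": "K",
          "type": "integer"
        },
        "lam_hat": {
          "title": "Lam Hat",
          "type": "number"
        },
        "loglik": {
          "title": "Loglik",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "p_hat": {
          "title": "P Hat",
          "type": "number"
        }
      },
      "required": [
        "k",
        "n",
        "lam_hat",
        "p_hat",
        "converged",
        "iterations",
        "loglik"
      ],
      "title": "FitReport",
      "type": "object"
    },
    "GofReport": {
      "properties": {
        "alpha": {
          "title": "Alpha",
          "type": "number"
        },
        "bin_ends": {
          "items": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Bin Ends",
          "type": "array"
        },
        "critical": {
          "title": "Critical",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        },
        "expected_probs": {
          "items": {
            "type": "number"
          },
          "title": "Expected Probs",
          "type": "array"
        },
        "observed": {
          "items": {
            "type": "integer"
          },
          "title": "Observed",
          "type": "array"
        },
        "params": {
          "$ref": "#/$defs/ParamsReport"
        },
        "reject": {
          "title": "Reject",
          "type": "boolean"
        },
        "sample_size": {
          "title": "Sample Size",
          "type": "integer"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "params",
        "sample_size",
        "bin_ends",
        "observed",
        "expected_probs",
        "statistic",
        "df",
        "alpha",
        "critical",
        "reject"
      ],
      "title": "GofReport",
      "type": "object"
    },
    "ParamsReport": {
      "properties": {
        "k": {
          "title": "K",
          "type": "integer"
        },
        "lam": {
          "title": "Lam",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "p": {
          "title": "P",
          "type": "number"
        }
      },
      "required": [
        "k",
        "lam",
        "n",
        "p"
      ],
      "title": "ParamsReport",
      "type": "object"
    }
  },
  "properties": {
    "dataset": {
      "title": "Dataset",
      "type": "string"
    },
    "fit": {
      "$ref": "#/$defs/FitReport"
    },
    "gof": {
      "$ref": "#/$defs/GofReport"
    }
  },
  "required": [
    "dataset",
    "fit",
    "gof"
  ],
  "title": "DemoReport",
  "type": "object"
}
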