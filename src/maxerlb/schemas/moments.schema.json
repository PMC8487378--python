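{
  "$defs": {
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
    "mean": {
      "title": "Mean",
      "type": "number"
    },
    "params": {
      "$ref": "#/$defs/ParamsReport"
    },
    "variance": {
      "title": "Variance",
      "type": "number"
    }
  },
  "required": [
    "params",
    "mean",
    "variance"
  ],
  "title": "MomentsReport",
  "type": "object"
}
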