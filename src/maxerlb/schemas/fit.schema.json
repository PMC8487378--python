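{
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
}
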