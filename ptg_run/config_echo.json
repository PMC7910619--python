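{
  "config": {
    "layout": {
      "kind": "grid",
      "sides": [
        3,
        3
      ]
    },
    "hyper": {},
    "mcmc": {
      "n_sweeps": 40,
      "burn_in": 20
    },
    "fine_tune": {
      "n_iter": 3
    },
    "seed": 0
  },
  "seed": 0
}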