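{
  "items": [
    {
      "item": "item_0",
      "node_id": 21,
      "coords": [
        1.0,
        -0.5
      ]
    },
    {
      "item": "item_1",
      "node_id": 18,
      "coords": [
        0.5,
        0.5
      ]
    },
    {
      "item": "item_2",
      "node_id": 2,
      "coords": [
        -1.0,
        0.0
      ]
    },
    {
      "item": "item_3",
      "node_id": 20,
      "coords": [
        1.0,
        -1.0
      ]
    },
    {
      "item": "item_4",
      "node_id": 5,
      "coords": [
        -0.5,
        -1.0
      ]
    },
    {
      "item": "item_5",
      "node_id": 0,
      "coords": [
        -1.0,
        -1.0
      ]
    },
    {
      "item": "item_6",
      "node_id": 16,
      "coords": [
        0.5,
        -0.5
      ]
    },
    {
      "item": "item_7",
      "node_id": 22,
      "coords": [
        1.0,
        0.0
      ]
    },
    {
      "item": "item_8",
      "node_id": 4,
      "coords": [
        -1.0,
        1.0
      ]
    },
    {
      "item": "item_9",
      "node_id": 8,
      "coords": [
        -0.5,
        0.5
      ]
    },
    {
      "item": "item_10",
      "node_id": 10,
      "coords": [
        0.0,
        -1.0
      ]
    },
    {
      "item": "item_11",
      "node_id": 13,
      "coords": [
        0.0,
        0.5
      ]
    }
  ],
  "provenance": {
    "log_joint": -46.26726143699476,
    "n_iter": 3,
    "seed": 0,
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
    "coarse_K": 9,
    "fine_K": 25
  }
}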