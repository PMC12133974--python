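{
  "model": "seirs",
  "blocks": {
    "latent": {"kind": "erlang", "k": 3, "mean": 3.0},
    "infectious": {"kind": "erlang", "k": 4, "mean": 5.0},
    "immune": {"kind": "exponential", "rate": 0.02}
  },
  "params": {
    "beta": 0.002,
    "Lambda": 5.0,
    "mu": 0.05
  },
  "initial_state": {
    "S": 99.0,
    "E": [0.0, 0.0, 0.0],
    "I": [1.0, 0.0, 0.0, 0.0],
    "R": [0.0]
  }
}
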