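{
  "model": "predprey",
  "blocks": {
    "maturation": {"kind": "exponential", "rate": 1.0},
    "adult": {"kind": "exponential", "rate": 0.1}
  },
  "params": {
    "r": 1.0,
    "K": 100.0,
    "a": 2.0,
    "h": 50.0,
    "chi": 0.5,
    "eta": 0.0
  },
  "initial_state": {
    "N": 100.0,
    "immature": [0.0],
    "mature": [1.0]
  }
}
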