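{
  "description": "Synthetic 2-agent scenario, both fully fused: a single donation. Expected values derived by hand from the assessment rules (donation increments r_i and r_G, counts n_pos; ctr becomes 1).",
  "benefit": 1.0,
  "cost": 0.7,
  "fusion": [1.0, 1.0],
  "rules": [[1, 1, 0], [1, 1, 0]],
  "init": {"rep": [0, 0], "group_rep": 0},
  "steps": [{"donor": 0, "recipient": 1, "ostracised": false}],
  "expected": [
    {"rep": [0, 0], "group_rep": 0, "payoff": [0.0, 0.0],
     "n_pos": [0, 0], "n_neu": [0, 0], "n_neg": [0, 0],
     "ctr": [null, null]},
    {"rep": [1, 0], "group_rep": 1, "payoff": [-0.7, 1.0],
     "n_pos": [1, 0], "n_neu": [0, 0], "n_neg": [0, 0],
     "ctr": [1.0, null]}
  ]
}
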