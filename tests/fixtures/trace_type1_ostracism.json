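{
  "description": "Synthetic 3-agent scenario exercising the type-1 ostracism exception (personal penalty, group untouched, counts n_neu), a fused donation by a half-fused agent, and an illegitimate defection. Expected values derived by hand from the standing assessment rules.",
  "benefit": 1.0,
  "cost": 0.7,
  "fusion": [1.0, 1.0, 0.5],
  "rules": [[1, 1, 0], [0, 1, 0], [1, 1, 0]],
  "init": {"rep": [1, -1, 0], "group_rep": 0,
           "n_pos": [1, 0, 0], "n_neg": [0, 1, 0]},
  "steps": [
    {"donor": 0, "recipient": 1, "ostracised": true},
    {"donor": 2, "recipient": 1, "ostracised": false},
    {"donor": 1, "recipient": 0, "ostracised": false}
  ],
  "expected": [
    {"rep": [1, -1, 0], "group_rep": 0, "payoff": [0.0, 0.0, 0.0],
     "n_pos": [1, 0, 0], "n_neu": [0, 0, 0], "n_neg": [0, 1, 0],
     "ctr": [1.0, 0.0, null]},
    {"rep": [0, -1, 0], "group_rep": 0, "payoff": [0.0, 0.0, 0.0],
     "n_pos": [1, 0, 0], "n_neu": [1, 0, 0], "n_neg": [0, 1, 0],
     "ctr": [1.0, 0.0, null]},
    {"rep": [0, -1, 1], "group_rep": 1, "payoff": [0.0, 1.0, -0.7],
     "n_pos": [1, 0, 1], "n_neu": [1, 0, 0], "n_neg": [0, 1, 0],
     "ctr": [1.0, 0.0, 1.0]},
    {"rep": [0, -2, 1], "group_rep": 0, "payoff": [0.0, 1.0, -0.7],
     "n_pos": [1, 0, 1], "n_neu": [1, 0, 0], "n_neg": [0, 2, 0],
     "ctr": [1.0, 0.0, 1.0]}
  ]
}
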