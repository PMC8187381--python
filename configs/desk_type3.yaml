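# Type-3 ostracism, in-group mixing tied to fusion, desk scale.
n_agents: 100
games_per_gen: 5000
generations: 2000
ostracism_type: 3
s_policy: fusion
seed: 1
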