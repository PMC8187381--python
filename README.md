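# fusionsim

Agent-based simulation of how **identity fusion** — the degree to which an
individual's identity overlaps with a group's — can co-evolve with
cooperation in a population interacting through **indirect reciprocity**.

The package is for researchers in social and cultural evolution who want a
fast, fully reproducible implementation of this model family: donation-game
cooperation under the standing norm, a shared group reputation that fused
agents partially adopt as their own, and hypocrisy-triggered ostracism as
the mechanism that protects the group identity from exploitation.

## The model in brief

`N = 100` agents repeatedly play the one-shot donation game (`m = 5000`
games per generation): a donor pays `c = 0.7` to give a recipient `b = 1`.
Each agent carries heritable action-rule bits `(s, u, d)` — donate on
similarity, upward, or downward self-comparison of reputations — and a
heritable fusion level `f ∈ {0, ¼, ½, ¾, 1}`. A fused observer perceives
agent `j` through the blend

```
r^j = (1 − f_j) · r_j + f_j · r_G
```

of `j`'s personal reputation and the shared group reputation, both integers
in `[−5, 5]` maintained under the *standing* norm (legitimate defection
against lower-standing partners is free). Fused agents also track a group
contribution ratio `ctr_i = (n_pos + n_neu) / (n_pos + n_neu + n_neg)` and,
with probability equal to their own fusion, check whether an equally-or-more
fused partner contributes less than themselves (`f_j ≥ f_i` and
`ctr_j < ctr_i`) — a perceived *hypocrite*. Detected hypocrites can be
ostracised at the interaction stage (type-1), at the roulette-wheel
reproduction stage (type-2), or both (type-3); perception (`e_p`) and
execution (`e_x`) errors, a fusion threshold `T` for who may ostracise, and
a differential donation cost `c_T` for those agents are all configurable.

Headline metrics are cumulative: *average cooperation* (donations over all
games so far) and *average fusion* (mean fusion over all generation-agent
pairs). See `docs/methods.md` for the full specification, the random draw
order, and the rationale for the five-point fusion scale.

## Worked example

```python
from fusionsim import ModelParams, run_experiment

params = ModelParams(ostracism_type=3, s_policy="fusion",
                     generations=2000, seed=1)
exp = run_experiment(params, n_seeds=3)
print(f"average cooperation: {exp.avg_cooperation:.3f}")
print(f"average fusion:      {exp.avg_fusion:.3f}")

base = run_experiment(params.replace(ostracism_type=0), n_seeds=3)
print(f"baseline (no ostracism) cooperation: {base.avg_cooperation:.3f}")
print(f"baseline (no ostracism) fusion:      {base.avg_fusion:.3f}")
```

prints

```
average cooperation: 0.973
average fusion:      0.992
baseline (no ostracism) cooperation: 0.359
baseline (no ostracism) fusion:      0.547
```

With type-3 ostracism and in-group mixing tied to fusion (`S_i = f_i`),
cooperation and fusion lock in together above 0.97 within 2,000
generations. Removing ostracism flips the outcome: "shirkers" — defectors
sitting at full fusion — hide behind the saturated group reputation,
cooperation collapses to ≈ 0.36, and fusion drifts near the mutation mean
instead of fixating.

The same machinery is scriptable from the shell:

```
fusionsim run --seed 1 --generations 2000       # one run + trajectory CSV
fusionsim sweep --figure 5 --scale desk --out sweeps/   # error-rate sweep
fusionsim plot --table sweeps/fig5_errors_desk.csv
```

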