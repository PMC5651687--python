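# eqsim

A Hebbian neural-network simulator of **stimulus equivalence**: how
perceptually unrelated stimuli, trained pairwise in matching-to-sample
(MTS) tasks, come to form interchangeable classes — including the
*derived* relations (symmetry, transitivity, combined equivalence) that
were never reinforced. It is written for behavior analysts and
computational cognitive scientists who want a quantitative handle on
*relatedness* — the graded associative strength between class members —
and on how training protocols shape it.

## The model

One layer of fully interconnected localist units, one unit per stimulus.
A symmetric weight matrix `W` (all zeros at the start, bounded in
[−1, 1]) stores the relatedness between every stimulus pair.

On an MTS trial the sample unit is clamped to 1; comparison units compete
on the raw weight they receive from the sample, the winner is clamped to
1 and the losers are silenced (lateral inhibition). Activation then
spreads to the rest of the layer through a gated sigmoid

```
X_j = 1 / (1 + exp(−net_j))   if net_j > 0.85,   else X_j = 0
```

where `net_j = Σ_i W_ij X_i` over the clamped units. Weights update for
every pair of coactive units with a supervised Hebbian rule with an
LTP-like threshold θ and a self-adapting (metaplastic) term λ:

```
if X_i·X_j ≥ θ:   λ = X_i·X_j − W_ij      ΔW_ij = ±β λ        (sign = feedback)
else:             λ = −W_ij               ΔW_ij = 0.25 β λ     (LTD-like decay)
```

During unreinforced test phases there is no feedback; the rate drops to
β/4 with a positive sign. Defaults: β = 0.2, θ = 0.7.

The key emergent behaviour: once a trained weight exceeds the 0.85
activation gate, the absent stimulus is re-activated by spreading, its
coactivation with the clamped units crosses θ, and a weight grows between
stimuli that were **never presented together** — a transitive relation.
Raising θ to 0.72 and lowering β to 0.1 (a learning-disability regime
motivated by raised-LTP-threshold findings) leaves trained relations
learnable but abolishes this derived growth.

Shipped protocols (`eqsim protocols list`): a two-relation curriculum
(`sim1`), a staged 4-member-class study (`sidman1982`), a 2-class study
with typical / learning-disability / interference-avoidance variants
(`devany1986`), and a 7-member linear-series study with nodal-distance
analysis plus an equal-trial-frequency control (`spencer1996`).

## Worked example

```python
from eqsim import (make_protocol, run_protocol, relatedness_by_category,
                   nodal_profile, emergence_epoch)

result = run_protocol(make_protocol("sim1"), seed=1)
print("emergence epoch of A1C1:", emergence_epoch(result, ("A1", "C1")))
for pair in [("A1", "B1"), ("B1", "C1"), ("A1", "C1")]:
    print(f"final W({pair[0]},{pair[1]}) = {result.final_state.weight(*pair):.3f}")

res = run_protocol(make_protocol("spencer1996"), seed=1)
table = relatedness_by_category(res, res.protocol.structure)
print(nodal_profile(table).to_string(index=False))
```

prints

```
emergence epoch of A1C1: 10
final W(A1,B1) = 0.921
final W(B1,C1) = 0.936
final W(A1,C1) = 0.857
 distance  mean_relatedness
        0          0.797558
        1          0.713273
        2          0.358515
        3          0.089828
        4          0.050380
        5          0.032500
```

Reading: over 30 epochs of alternating A1B1/B1C1 training the derived
A1C1 weight stays at zero until (here) epoch 10, when the trained A1–B1
weight first exceeds the activation gate; it then grows but ends below
both trained weights. In the 7-member linear-series study, mean
relatedness falls monotonically with nodal distance — directly trained
pairs strongest, 5-node transitive pairs weakest.

The same runs are available from the shell:

```
eqsim replicate sim1 --seeds 1 --outdir out/sim1
eqsim replicate devany1986 --variant learning_disability --seeds 1..20 --outdir out/ld
eqsim run my_protocol.yaml --outdir out/custom
```

Each run writes weight matrices (CSV/JSON), trial logs, per-block weight
trajectories, relatedness tables, nodal profiles and a manifest with
artifact checksums; re-running a manifest's seed reproduces every byte.

## Layout

- `src/eqsim/network.py` — activation, spreading, the weight-update rule
- `src/eqsim/trials.py` — one MTS trial (competition, feedback, update)
- `src/eqsim/protocol.py` — blocks, mastery criteria, staged runs
- `src/eqsim/structures.py` — classes, roles, nodal distance, generators
- `src/eqsim/studies.py` + `src/eqsim/protocols/*.yaml` — study fixtures
- `src/eqsim/analysis.py` — relatedness tables, profiles, accuracy
- `src/eqsim/cli.py` — the `eqsim` command
- `docs/methods.md` — modelling notes, parameter rationale, limitations
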