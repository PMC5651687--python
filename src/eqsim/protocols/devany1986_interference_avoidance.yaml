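# Interference-avoidance training under the learning-disability parameter
# regime: AB is trained alone for 45 trials per class (its weight reaching
# ~0.99 = 1 - 0.9^45) before 30 mixed AB/AC trials.  No test block: the
# question this variant answers is whether transitive BC develops during
# training itself.
name: devany1986_interference_avoidance
seed: 0
structure:
  roles: [A, B, C]
  n_classes: 2
  trained_relations: [AB, AC]
parameters:
  beta: 0.1
  theta: 0.72
stages:
  - {name: A1B1-solo, phase: train, trials: {A1B1: 45}, criterion: null, shuffle: false}
  - {name: A2B2-solo, phase: train, trials: {A2B2: 45}, criterion: null, shuffle: false}
  - {name: AB-AC-mixed, phase: train, trials: {AB: 15, AC: 15}, criterion: null, shuffle: true}
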