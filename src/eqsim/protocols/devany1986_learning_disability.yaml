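# Same staged protocol as devany1986, with the learning-disability
# parameter regime: raised coactivation (LTP) threshold theta 0.7 -> 0.72
# and lowered learning rate beta 0.2 -> 0.1.
name: devany1986_learning_disability
seed: 0
structure:
  roles: [A, B, C]
  n_classes: 2
  trained_relations: [AB, AC]
parameters:
  beta: 0.1
  theta: 0.72
stages:
  - {name: A1B1, phase: train, trials: {A1B1: 10}, criterion: 9/10, shuffle: false}
  - {name: A2B2, phase: train, trials: {A2B2: 10}, criterion: 9/10, shuffle: false}
  - {name: AB-mixed, phase: train, trials: {A1B1: 5, A2B2: 5}, criterion: 9/10}
  - {name: A1C1, phase: train, trials: {A1C1: 10}, criterion: 9/10, shuffle: false}
  - {name: A2C2, phase: train, trials: {A2C2: 10}, criterion: 9/10, shuffle: false}
  - {name: AC-mixed, phase: train, trials: {A1C1: 5, A2C2: 5}, criterion: 9/10}
  - {name: all-mixed, phase: train, trials: {A1B1: 2, A2B2: 2, A1C1: 2, A2C2: 2}, criterion: 7/8}
  - {name: maintenance, phase: test, trials: {A1B1: 2, A2B2: 2, A1C1: 2, A2C2: 2}, criterion: 8/8}
  - {name: test, phase: test, trials: {B1C1: 1, C1B1: 1, B2C2: 1, C2B2: 1}, criterion: null}
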