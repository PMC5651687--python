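# Two 3-member classes, trained AB and AC (one-to-many from node A),
# two comparison options per trial.  Single-relation stages at 9/10,
# mixed block at 7/8 with each relation twice, unreinforced maintenance
# at 2/2 per relation, then a test block presenting each transitive
# relation (BC, CB per class) once.  Typical-development parameters.
name: devany1986
seed: 0
structure:
  roles: [A, B, C]
  n_classes: 2
  trained_relations: [AB, AC]
parameters:
  beta: 0.2
  theta: 0.7
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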