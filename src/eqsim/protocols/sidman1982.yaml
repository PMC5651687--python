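# Three 4-member classes (A: spoken names; B, C, D: printed symbols).
# Staged introduction of the nine trained relations (AB, AC, DC per class)
# with the original mastery criteria, then one unreinforced test block
# presenting every baseline and derived relation once.
name: sidman1982
seed: 0
structure:
  roles: [A, B, C, D]
  n_classes: 3
  trained_relations: [AB, AC, DC]
parameters:
  beta: 0.2
  theta: 0.7
stages:
  - {name: AB-1, phase: train, trials: {A1B1: 10, A2B2: 10}, criterion: 19/20}
  - {name: AB-2, phase: train, trials: {A1B1: 10, A3B3: 10}, criterion: 19/20}
  - {name: AB-3, phase: train, trials: {A2B2: 10, A3B3: 10}, criterion: 19/20}
  - {name: AB-4, phase: train, trials: {A1B1: 10, A2B2: 10, A3B3: 10}, criterion: 29/30}
  - {name: AC-1, phase: train, trials: {A1C1: 10, A2C2: 10}, criterion: 19/20}
  - {name: AC-2, phase: train, trials: {A1C1: 10, A3C3: 10}, criterion: 19/20}
  - {name: AC-3, phase: train, trials: {A2C2: 10, A3C3: 10}, criterion: 19/20}
  - {name: AC-4, phase: train, trials: {A1C1: 10, A2C2: 10, A3C3: 10}, criterion: 29/30}
  - {name: AB-AC, phase: train, trials: {AB: 15, AC: 15}, criterion: 29/30}
  - {name: DC-1, phase: train, trials: {D1C1: 10, D2C2: 10}, criterion: 19/20}
  - {name: DC-2, phase: train, trials: {D1C1: 10, D3C3: 10}, criterion: 19/20}
  - {name: DC-3, phase: train, trials: {D2C2: 10, D3C3: 10}, criterion: 19/20}
  - {name: DC-4, phase: train, trials: {D1C1: 10, D2C2: 10, D3C3: 10}, criterion: 29/30}
  - {name: AB-AC-DC, phase: train, trials: {AB: 15, AC: 15, DC: 15}, criterion: 44/45}
  - name: test
    phase: test
    trials: {AB: 3, AC: 3, DC: 3, DB: 3, BD: 3, AD: 3, BC: 3, CB: 3, CD: 3}
    criterion: null
    shuffle: true
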