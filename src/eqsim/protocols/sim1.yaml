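# Three-member class (A-B-C) trained AB then BC, one trial each per epoch,
# 30 epochs, no mastery criterion.  Classes 2 and 3 supply the distractor
# comparison units (B2, B3, C2, C3) and are never themselves trained.
name: sim1
seed: 0
structure:
  roles: [A, B, C]
  n_classes: 3
  trained_relations: [AB, BC]
parameters:
  beta: 0.2
  theta: 0.7
stages:
  - name: AB-BC-epochs
    phase: train
    trials: {A1B1: 1, B1C1: 1}
    criterion: null
    shuffle: false
    blocks: 30
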