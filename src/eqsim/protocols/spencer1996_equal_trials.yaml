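# Equal-frequency control for the linear-series structure: 65 reinforced
# trials of each of the 18 trained relations (AB..FG in each of the three
# classes), presented as 65 epochs with every relation once per epoch,
# interleaved-shuffled within the epoch.  Training only — the published
# control relatedness is read from the weights the training itself
# produces (unreinforced test trials would otherwise clamp never-related
# pairs together and lift their weights off zero).
name: spencer1996_equal_trials
seed: 0
structure:
  roles: [A, B, C, D, E, F, G]
  n_classes: 3
  trained_relations: [AB, BC, CD, DE, EF, FG]
parameters:
  beta: 0.2
  theta: 0.7
stages:
  - name: equal-trials
    phase: train
    trials: {AB: 3, BC: 3, CD: 3, DE: 3, EF: 3, FG: 3}
    criterion: null
    shuffle: true
    blocks: 65
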