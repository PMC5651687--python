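# Three 7-member classes under linear series training (AB..FG), staged
# with maintenance trials of earlier relations.  Counts are per relation
# set across the three classes (each stage totals 48 trials), split as
# evenly as possible between classes.  Criterion: at least 90% correct
# per block.  Stage 7 is unreinforced baseline maintenance (18 trials,
# 90%); the test block presents all 126 baseline, symmetry, transitivity
# and combined relations once per class.
name: spencer1996
seed: 0
structure:
  roles: [A, B, C, D, E, F, G]
  n_classes: 3
  trained_relations: [AB, BC, CD, DE, EF, FG]
parameters:
  beta: 0.2
  theta: 0.7
stages:
  - {name: stage1-AB, phase: train, trials: {AB: 48}, criterion: 44/48}
  - {name: stage2-BC, phase: train, trials: {AB: 24, BC: 24}, criterion: 44/48}
  - {name: stage3-CD, phase: train, trials: {AB: 12, BC: 12, CD: 24}, criterion: 44/48}
  - {name: stage4-DE, phase: train, trials: {AB: 8, BC: 8, CD: 8, DE: 24}, criterion: 44/48}
  - {name: stage5-EF, phase: train, trials: {AB: 6, BC: 6, CD: 6, DE: 6, EF: 24}, criterion: 44/48}
  - {name: stage6-FG, phase: train, trials: {AB: 3, BC: 3, CD: 3, DE: 6, EF: 9, FG: 24}, criterion: 44/48}
  - {name: stage7-maintenance, phase: test, trials: {AB: 3, BC: 3, CD: 3, DE: 3, EF: 3, FG: 3}, criterion: 17/18}
  - name: test
    phase: test
    criterion: null
    trials: {
      AB: 3, BC: 3, CD: 3, DE: 3, EF: 3, FG: 3,
      BA: 3, CB: 3, DC: 3, ED: 3, FE: 3, GF: 3,
      AC: 3, AD: 3, AE: 3, AF: 3, AG: 3, BD: 3, BE: 3, BF: 3,
      BG: 3, CE: 3, CF: 3, CG: 3, DF: 3, DG: 3, EG: 3,
      CA: 3, DA: 3, EA: 3, FA: 3, GA: 3, DB: 3, EB: 3, FB: 3,
      GB: 3, EC: 3, FC: 3, GC: 3, FD: 3, GD: 3, GE: 3,
    }
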