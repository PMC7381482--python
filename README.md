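# lesionlab

Simulated neural damage in recurrent connectionist models of cognition.

Connectionist cognitive neuropsychology lesions a trained network —
severing connections, adding weight noise, ablating units, scaling
weights, or perturbing activations — and reads the resulting behavioural
impairment against patient data.  Whether those five implementations of
damage are interchangeable, and how much post-lesion behaviour depends on
the training set rather than the architecture, are live methodological
questions.  `lesionlab` packages two classic testbeds for exploring them:

1. **A recurrent hub-and-spoke auto-associator of semantic knowledge.**
   216 visible units (40 name + 64 visual + 112 verbal spokes)
   bidirectionally connected to a 64-unit recurrent hub, trained to
   auto-associate 48 binary items (six categories of eight: birds,
   mammals, fruits vs tools, vehicles, household objects).  Picture
   naming clamps the visual units for 2 cycles, settles 5 more, and reads
   the most active name unit above 0.5.  Damaged networks develop
   *category-specific* deficits — which domain suffers depends jointly on
   the form of damage and the statistics of the training patterns.
2. **A simple recurrent network of routine action selection.**  An
   Elman network that prepares coffee (37 steps) and tea (20 steps) in a
   simulated kitchen, trained by backpropagation through time on six
   action sequences plus 250+ single-step background actions.  Damaged
   networks produce everyday-slip and action-disorganisation style
   errors: subtask omissions, intrusions, perseverations, displacements
   and within-subtask disorganisation, classified automatically against a
   subtask grammar.

Five damage operators apply to both models with seed-exact replay:
connection severing (each weight zeroed with probability *q*), weight
perturbation (added zero-mean noise of half-range *r* or SD *σ*), unit
ablation (all outgoing connections of a unit removed with probability
*p*), weight scaling (all weights × *s* ∈ (0, 1]), and context
activation noise (per-step N(0, σ²)).  Bias weights are always exempt.

The headline behavioural statistic of the semantic study is the signed
**area between curves**: with naming accuracy measured per domain across
a severity grid, the per-network area is the mean over levels of
(artefact − animal) accuracy; positive values mean an artefact advantage
(animals harmed more).  For the action study the analyses are **survival
curves** (proportion of episodes error-free through each step), the
subtask/action error taxonomy, crux vs non-crux error rates and the
weight-scaling failure-onset factor per task.

## Worked example

```bash
python examples/04_action_selection.py
```

trains the action network (a couple of minutes) and prints:

```
intact coffee episode: 37 steps, correct = True
intact tea episode:    20 steps

context noise sigma=0.10, 200 coffee episodes: 171 erroneous
  within_subtask  365
  perseveration   231
  omission        124
(omission is coffee's dominant goal-level error — typically the cream
step, captured by the tea routine, which has no cream; abandoned
restarts and stray actions count as perseverations and within-subtask
errors)
```

The intact network reproduces the full 37-step coffee and 20-step tea
routines.  With Gaussian noise (SD 0.10) on the context units most
episodes go wrong.  The dominant goal-level error in coffee making is
omission: the network, having added sugar, is captured by the very
similar tea routine (which has no cream step) and skips straight to
drinking; no subtask ever intrudes into coffee.  The wander around those
captures — abandoned restarts of completed subtasks and stray actions —
is what the perseveration and within-subtask counts record.  The other examples generate calibrated pattern sets
(`01_pattern_sets.py`), train and name with the hub network
(`02_train_and_name.py`), reproduce the severing/perturbation
dissociation (`03_semantic_dissociation.py`), and compare all damage
kinds plus the scaling thresholds (`05_damage_equivalence.py`).

A thin CLI wraps the same library calls:

```bash
lesionlab generate-patterns --profile P2-like --seed 1 --out ps.csv
lesionlab run-semantic --scale desk --master-seed 0 --output-dir runs/sem
lesionlab run-action   --scale desk --master-seed 0 --output-dir runs/act
lesionlab report --run-dir runs/sem
```

The `desk` preset reduces replicate counts only (5 hub networks × 5
lesions per severity level; 3 action networks × 100 episodes per cell);
severity grids are never thinned.

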