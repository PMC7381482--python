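# Methods

This note documents the models, the synthetic data, the damage operators
and the analysis choices implemented in `lesionlab`, together with the
numerical decisions a user may want to audit.

## 1. The hub-and-spoke semantic network

### Architecture and dynamics

The semantic model is a recurrent auto-associator with 216 visible units
split into three modality-specific "spokes" — 40 name units, 64 visual
units, 112 verbal units — bidirectionally and fully connected to a hidden
"hub" of 64 units, which also carries full recurrent hub-to-hub
connections.  Every unit receives a fixed, untrainable bias of −2.0 from a
permanently active bias unit, so an unconnected unit rests at
σ(−2) ≈ 0.119.  Activation is the logistic sigmoid and updates are
synchronous: on each cycle every unit recomputes its activation from the
previous cycle's activations.

Processing an item clamps one spoke to the item's pattern for 2 cycles,
then lets all units run free for 5 more cycles (7 cycles total).  Picture
naming clamps the visual block; the response is the most active name unit
at cycle 7 if it exceeds 0.5 (ties break to the lowest index), otherwise
"no response".  The hub size (64) is configurable; it matches the hidden
width of the feed-forward comparison network.

### Training

Networks train for 1000 epochs with learning rate 0.001 and weight decay
0.001.  Each epoch presents all 48 items three times — name, verbal and
visual clamped — in shuffled order, updating after every presentation.
Gradients come from backpropagation through time over the 7-cycle unroll,
with cross-entropy targets applied to all visible units on each of the 5
free cycles.  Applying targets on every free cycle (rather than only the
final ones) is what lets default training reach the working criterion —
every unit within 0.20 of its target, naming at ceiling — within the
stated 1000 epochs.  Weight decay enters the update as
Δw = −lr·(∂E/∂w + λw); applying the decay term unscaled by the learning
rate destroys all learning (weights contract by ~13% per epoch), so the
conventional scaled form is used.  Initial weights are uniform in ±0.5;
biases are never updated.

Trained networks show weight distributions closely matching the published
description of this model family: near-symmetric about zero, with a slight
positive majority in the visible→hidden and hidden→hidden matrices
(≈0.53) and a slight negative majority hidden→visible (≈0.44–0.46).

### The feed-forward comparison network

A 216→64→216 feed-forward auto-associator (single forward pass, no
recurrence, same fixed bias) is provided for the attractor-free
comparison.  It trains by plain backpropagation on the auto-association
target and accepts all weight-space lesion operators.

## 2. Synthetic pattern sets

Each pattern set holds 48 items × 216 binary units: six categories of
eight exemplars — birds, mammals, fruits (the "animal"/living domain) and
tools, vehicles, household objects (artefacts).

### Template structure

The 176 stochastic feature slots (64 visual + 112 verbal) are organised in
four kinds of block:

* a 24-slot **global** block (probability weight 0.9) of concrete-object
  generalities shared by all 48 items — this holds cross-domain
  correlations near zero instead of strongly negative;
* per domain, a 16-slot **domain-shared** block (weight 0.8, echoing the
  original template's 80% presence probability for shared animal
  features);
* per category, a 19-slot **own** block (weight 1.0);
* **sibling** overlap on the other categories of the same domain.  Animal
  categories overlap strongly (0.45, and a still higher bird↔mammal
  overlap), artefact categories weakly (0.15).  This asymmetry mirrors the
  feature-norm structure both reference pattern sets encode: living
  things share many properties and are mutually confusable, artefacts are
  distinctive.

The two domains occupy disjoint visual and verbal slots, so cross-domain
correlation is ~0 (slightly negative), within-domain correlation is
strong, and within-category correlation stronger still.

Each category's probability vector is then **calibrated**: the whole
vector is scaled (with clipping at 1) until the closed-form expected
active-feature count — including the one active name unit — exactly equals
the reference count.  The `P1-like` profile uses the per-category counts
of the pattern set distributed with the open-source release of the model
(birds 42.250 … household 22.500) and a bird↔mammal overlap of 0.75; the
`P2-like` profile uses the template-generated counts (birds 35.875 …
household 24.625) and a weaker bird↔mammal overlap of 0.55, reflecting the
reported weaker bird/mammal correlations of that set.
`boost_domain_norms` re-runs the same calibration to move one domain's
expected counts (e.g. raising P2-like animal norms to P1-like levels).

### Name assignment

48 items cannot be one-hot in a 40-unit name block.  The paired-localist
scheme keeps the block localist: eight within-category item pairs share a
name unit (four categories contribute one pair, two contribute two; pairs
and the category allocation are drawn with the set's seed).  Naming is
scored against the item's assigned unit, so shared-name siblings are not
confusable with each other by construction.

### What the generator does and does not emulate

It reproduces the reference sets' dimensions, per-category feature
counts, domain structure and correlation ordering
(within-category ≥ within-domain ≥ cross-domain ≈ 0).  It does not
reproduce the exact feature-by-feature probability table of the original
template, item-level semantics, or the empirical feature-frequency
distribution of elicitation norms (e.g. heavy-tailed feature
distinctiveness).  Conclusions from passing tests therefore concern the
statistical regime — relative norms and confusability of the domains —
not any particular stimulus set.

## 3. Damage operators

All five operators leave bias weights untouched and never touch more than
their stated target:

* **sever(q)** — each non-bias weight is zeroed independently with
  probability q (multiplication by Bernoulli(1−q)); a single pooled
  random stream covers all targeted matrices in declared order.
* **perturb_weights(r)** — independent zero-mean noise added to every
  targeted weight; uniform U(−r, +r) for the semantic grids, Gaussian
  N(0, r²) for the recurrent weights of the action network (matching each
  case study's published procedure).
* **ablate_units(p)** — each unit of the hub/context layer loses all its
  *outgoing* connections with probability p (exactly equivalent to
  severing those connections); incoming weights are retained.
* **scale_weights(s)** — deterministic multiplication of all non-bias
  weights by s ∈ (0, 1]; equivalent to lowering activation-function gain.
* **activation_noise(σ)** — a per-step injector adding N(0, σ²) to the
  context activations of a sequence-generating run; weights untouched.

Stochastic operators take explicit seeds; a `LesionRecord` (kind,
severity, seed, target) replays any lesion bit-exactly.  Experiment code
derives per-lesion seeds from a master seed by SHA-256 hashing of
(master, stage, counter), so no stage reads global RNG state.

## 4. Case study 1: damage grids and analyses

The published severity ladders are used exactly: severing 2.5%–50% in
2.5% steps (20 levels); uniform weight noise half-range 0.05–1.00 in 0.05
steps (20); unit ablation probability 0.00–1.00 in 0.05 steps (21);
weight scaling 0.75 down to 0.55 in 0.01 steps (21).  At full scale, 20
networks are trained per pattern set and each is lesioned 10 times per
level; the desk preset keeps all severity levels and reduces replicates
to 5 networks × 5 lesions per level (runs in minutes on one CPU).  Weight
scaling is deterministic, so one lesion per level suffices.

The **area between curves** summarising a domain dissociation is the mean
over severity levels of (artefact − animal) naming accuracy, computed per
network — equivalent to the trapezoid area normalised by the severity
span, and comparable across damage kinds with different severity units.
Positive areas mean an artefact advantage.  The 95% CI is a Student-t
interval over per-network areas; the original work does not name its CI
method, and at n = 20 t and percentile-bootstrap intervals are close.

**Attractors** are the hub states after the same 2+5 visual-clamp
protocol used for naming (the source work does not state the clamping
used for attractor extraction); attractor density is the mean pairwise
Euclidean distance within each domain, compared by a standard two-way
ANOVA (domain × pattern set) over per-network means.  **Weight
summaries** report min/max/mean/proportion-positive per matrix with
t-intervals over networks.  **Output error** is the Euclidean distance
between the settled visible vector and the target, over all 216 units and
over the 40 name units separately.

## 5. Case study 2: beverage world, SRN and error taxonomy

### Environment and corpus

The simulated kitchen contains a cup, spoon, coffee packet, sugar packet,
sugar bowl (with removable lid), cream carton and teabag.  The agent
fixates one object and holds at most one; actions are discrete (7 fixate
actions plus pick-up, put-down, tear-open, pull-open, pull-off, pour,
scoop, dip, stir, sip, say-done).  Effects are deterministic;
inapplicable actions leave the world unchanged and are flagged anomalous.
`fixate_sugar` lands on whichever sugar source the scenario provides
(packet or bowl), so sequence variability driven by the environment
enters exactly at that fixation, as in the source model.

The corpus holds six target sequences: four coffee realisations (37
steps: add grounds; add sugar — from packet or bowl — and add cream in
either order; drink) and two tea realisations (20 steps: steep; add
sugar from packet or bowl; drink).  Every ingredient-addition subtask
ends with a stir and the next begins by putting the spoon down, which
places the subtask boundaries at coffee steps 10/11, 21/22, 32/33 and tea
steps 10/11, 15/16.  Each subtask contains exactly one crux action (the
goal-fulfilling pour/dip/sip); everything else is preparation or
clean-up.  A deterministic enumeration of world states additionally
yields 250+ single-step background state→action pairs (each distinct
input maps to one canonical affordance-driven action, so background
training is conflict-free).

Two design choices depart from pure emergence and are worth flagging.
First, a transient instruction cue (coffee/tea, plus an order bit for
coffee) is present in the input on the first step only; the network must
carry it in context thereafter.  Without a cue, a deterministic network
given identical initial input could not produce both tasks, and the
original model's random initial context is replaced here by a fixed
context (0.5) for exact reproducibility.  Second, the sugar/cream order
is part of the cue rather than spontaneous, which is what makes "the
network reproduces all six sequences" a well-defined deterministic check.

### Network and training

The SRN maps [fixated-object features ‖ held-object features ‖
instruction] (27 inputs) through 50 sigmoid hidden units (with a context
copy of the previous hidden state) to a softmax over the 18 actions.
Training is full-batch backpropagation through time (momentum 0.9,
learning rate 0.5 on step-averaged gradients): the four coffee sequences
form one batch, the two tea sequences another, the background pairs a
single-step batch.  The published epoch count (20,000) is kept as a cap;
training stops early once the total cross-entropy falls below 1.0 *and*
free-running episodes reproduce all six sequences exactly (checked every
100 epochs; typically ~2,000 epochs).  At test time the argmax action is
executed in the environment and the environment's next state becomes the
next input; episodes are capped at 60 steps.

### Error classification

Produced action strings are classified deterministically:

1. **Parse** into non-overlapping complete subtask tokens (both tasks'
   inventories pooled), maximising covered actions; ties prefer earlier
   segment starts, then lexicographic token names.  The dynamic-programme
   parser is verified against exhaustive enumeration on short episodes.
2. **Fragments**: residual runs are scanned leftmost-longest for
   contiguous substrings (≥ 3 actions) of any token.  A fragment
   containing its token's crux action fulfils that goal (truncated but
   effective routine); a crux-less fragment of an already-fulfilled goal
   is a perseveration; any other crux-less fragment is a broken subtask
   attempt (within-subtask error).  Actions in no fragment are
   disorganised "independent" actions, each a within-subtask error.
3. **Goal comparison** against the task's valid goal orders yields
   omissions (expected goal never fulfilled), intrusions (foreign goal),
   perseverations (re-fulfilled goal) and displacements (expected goals
   in an order matching no valid realisation, counted by LCS deficit).

Action-level errors (omission vs sequence vs other) come from a minimal
edit alignment against the nearest valid realisation: deletions are
omissions; insertions/substitutions whose action occurs in the target are
sequence errors; edits introducing foreign actions are "other".

Survival curves report, per step k, the fraction of episodes whose first
divergence from the *nearest* valid realisation (so legitimate
sugar/cream order variation is never an error) occurs after step k.
Because every subtask opens with actions shared across continuations
(putting the held object down), a boundary capture surfaces within the
first two steps of the next subtask; boundary windows in the tests are
therefore (b, b+2] for each boundary b.

### Damage sweep defaults

The published mild settings anchor each ladder: activation noise σ = 0.10,
Gaussian recurrent-weight noise SD = 0.05, severing 5% of recurrent
connections, removing 5% of context units; ladders are geometric above
these anchors.  Stochastic lesions are redrawn per episode (each trial is
an independent instance of the damaged network — with a single fixed
lesion a deterministic network would produce one trajectory per scenario).
Weight scaling is deterministic, so the failure-onset search runs one
episode per (network, scenario, cue, factor) on a descending grid.

## 6. Reproduced phenomena and known limitations

With the default synthetic conditions the package reproduces, at desk
scale: hub training to criterion with ceiling naming and near-symmetric
weight distributions; the perturbation-induced animal-naming deficit for
both profiles, larger under P1-like training, with mean areas close to
the reference magnitudes; the ordering of the severing effect between the
profiles (P1-like areas more artefact-favouring than P2-like, whose mean
is negative); intact SRN cohorts reproducing all six sequences;
noise-driven failures clustering at subtask boundaries; coffee's
dominance of subtask omissions over intrusions at mild damage;
within-subtask disorganisation predominating at severe damage; rising
independent-action proportions with severity; omission as the modal
action-level error under near-onset weight scaling — all of these
equivalently across the four stochastic damage kinds.

Known limitations, stated plainly:

* **Severing/scaling sign conventions of the hub study.**  Both
  profiles' severing areas sit ~0.02 above the reference values, so the
  P1-like severing interval is mildly positive rather than containing
  zero and the P2-like interval straddles zero rather than lying wholly
  below it; weight scaling favours animals under both profiles rather
  than splitting by profile.  The cause is diagnosable: any training
  variant that reaches the ≤0.20 error criterion here drives the hub
  nearly binary (mean |h − 0.5| ≈ 0.48 across cross-entropy and
  sum-squared objectives and a wide weight-decay range), which
  orthogonalises item codes; richer animal items then recruit more hub
  units and sit farther apart, muting the confusability cost that the
  richness/confusability trade-off needs.  For the same reason the
  within-domain attractor-density ordering comes out reversed (animal
  attractors sparser, not denser).  The corresponding tests assert the
  reference directions and are expected to fail under the shipped
  conditions; they are retained as a faithful record of the target
  phenomena.
* **Action-domain scope.**  Three reference claims are not robust
  properties of this implementation across training seeds, and their
  tests fail under the shipped conditions.  Mild damage produces more
  within-subtask than subtask-level error counts: mild erroneous episodes
  contain complete subtasks plus short abandoned restarts, which the
  residual-action count scores as within-subtask errors.  Tea's error
  profile flips between intrusion- and omission-dominant across training
  seeds (the reference tea is strongly intrusion-prone).  And the
  weight-scaling failure-onset factors for coffee and tea are
  statistically indistinguishable here (per-network onsets ≈ 0.72–0.90
  for both tasks) rather than widely separated (0.88 vs 0.49 in the
  reference).  All three trace to the two tasks sharing more surface
  structure in this corpus than in the reference environment.
* Quantities that depend on the exact original training sets (absolute
  CI endpoints, attractor distances, table-level error magnitudes) are
  reproduced in direction and rough magnitude, not digit-for-digit.
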