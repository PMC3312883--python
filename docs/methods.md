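# Methods

## The labeling network

Each prediction is local: the label of residue *i* is predicted from a
window of `w` residues centered on *i* (positions beyond the sequence ends
are filled with a dedicated padding symbol that has its own learned
embedding column and an all-zero profile row).  Per window position the
network concatenates a learned `d`-dimensional embedding of the residue
symbol and/or its scaled 20-dimensional profile row; the resulting
`w·(d+20)`-vector feeds a fully connected hidden layer with a hard-tanh
transfer (saturating at ±1, identity in between), a task-specific linear
output layer, and a softmax.  We restrict the trunk to one hidden layer;
the code accepts a list of layer sizes should deeper trunks be wanted.

Key numerical choices:

* **Profile scaling.**  Raw integer log-odds are mapped through the
  logistic `1/(1+e^(−x))`, which is strictly monotone, bounded in (0,1),
  and sends 0 to 0.5.  Proteins without a profile fall back to their
  residues' BLOSUM62 columns, mirroring what PSI-BLAST itself reports when
  a query has no homologs.
* **Initialization.**  Every weight matrix is i.i.d. uniform on `[−r, r]`
  with `r = 1/√fan‑in` (embedding columns use `r = 1/√d`).  Centered-uniform
  initialization keeps the hard-tanh units in their identity region at the
  start, so early training is well-conditioned.
* **Loss and optimization.**  Negative log-likelihood, minimized by plain
  SGD with a constant learning rate (default 0.005; the synthetic
  experiments use 0.05 because their fixtures are far smaller and cleaner
  than real profile data), one sampled window per update.  Posteriors are
  floored at 1e-12 inside the log.  Softmax subtracts the row max before
  exponentiation.
* **Gradients.**  Backpropagation is hand-derived and exact; a
  finite-difference checker (`network.gradient_check`, central differences,
  `eps = 1e-6`, relative deviation `|a−n| / max(1,|a|,|n|)`) audits every
  parameter, including the embedding columns of the window's tokens.  The
  hard-tanh derivative is taken as 0 at the saturation boundaries; random
  inputs land on a kink with probability zero.

Defaults: `w = 13`, `d = 15`, 300 hidden units.  The unit and acceptance
tests use much smaller nets (`w` 3–7, `d` 2–8, 10–30 hidden units) because
the properties under test are size-independent and the suite must run in
minutes on one CPU.

## Multitask training

All registered tasks share the embedding table and the hidden layer; each
task owns only its output layer.  An *iteration* is a fixed budget of SGD
updates — by default the total number of labeled training windows, capped
at 100 000 — followed by a validation evaluation.  Each update draws a task
uniformly at random (equal task weighting), then one of its labeled
windows.  Unlabeled positions ('.') never enter the update stream and never
count in accuracy denominators.

One fifth of each task's proteins (protein-level, seeded) is held out for
validation.  Training stops when the validation error improves by less than
`5·10⁻⁵` — for multitask runs, the unweighted mean of per-task validation
errors, since the aggregate drives a single shared parameter set — or at
the iteration cap (default 150).  A zero or negative improvement also
stops: the rule is "improved by less than the tolerance", so a flat
learning curve converges rather than running to the cap.

When task sizes are very unbalanced, the large-flagged tasks can be
pre-trained jointly first (`pretrain=True`); when the full phase starts,
the never-trained output layers of the remaining tasks are freshly
re-initialized (provenance-tagged `"fresh"` vs `"pretrained"`), while the
shared layers keep their pre-trained state.  Whether an implementation
should retain or reset those output layers is genuinely open; we reset,
since they were never updated against data and their initial values would
otherwise be entangled with the pre-training RNG stream.

Because uniform task sampling splits the update budget across tasks, the
canned comparison experiment gives the joint run `n_tasks ×` the per-
iteration budget of each single-task run — one pass-equivalent per task —
so the stopping rule compares equally trained models.

## The natural-protein task

A separate scoring network (embedding → window concatenation → hidden
layer → single scalar; no profiles, no softmax) is trained on unlabeled
sequences to rank genuine windows above middle-corrupted ones with the
margin cost `max(0, margin − s⁺ + s⁻)`, margin fixed at 1.  The corrupted
middle is drawn uniformly from the 20 canonical letters and may equal the
original; such pairs cost exactly the margin and act as regularizers.  The
corpus is split 70/30 into training and validation sequences; the held-out
ranking loss is evaluated against a negative set corrupted *once* per run,
so successive evaluations are comparable and the 5·10⁻⁵ stopping rule is
meaningful (re-corrupting each iteration injects noise orders of magnitude
above the tolerance).  The product of training is the embedding table,
exported as plain text (repr-formatted float64, bitwise round-trip) and
importable as the initialization of any supervised regime.

## Viterbi post-processing

Per-residue argmax labeling ignores label grammar.  The decoder maximizes
`log init(y₁) + Σ log P(yₜ | posteriorₜ) + Σ log T(yₜ₋₁, yₜ)` over whole
label paths, where the bigram transition matrix `T` and the initial
distribution are add-pseudocount (default 1) maximum-likelihood estimates
from the training-fold labelings — transitions are *not* trained jointly
with the network; post-processing is kept strictly separate.  Bigrams never
span an unlabeled position.  All scores are in log space; forbidden
transitions use the sentinel −1e30 rather than −inf so arithmetic stays
finite, and any path avoiding sentinels beats any path through one.  Ties
break toward the lower label index.  If every path is forbidden, the
decoder falls back to per-position argmax with a warning.  Transition
models are estimated per task; whether a shared or task-specific grammar is
preferable is open, but per-task estimation is the minimal faithful reading
of "post-processing".

## Synthetic fixtures: what they emulate, and what they do not

`generate_multitask_fixture` draws, per protein, a hidden first-order
Markov state path (default 4 states, self-transition 0.7–0.75); residues
are emitted uniformly from state-specific groups of the 20 letters, and
every task's labels are a per-task permutation recoding of the same hidden
path, optionally corrupted at a known rate ε (resampling uniformly among
the other labels).  This reproduces the essential structure that motivates
multitask learning — tasks whose labels are mutually informative because
they reflect one underlying local structure — and gives closed-form ground
truth: with injective recodings and ε = 0, between-task label mutual
information equals the label entropy, and with noise ε no predictor can
exceed `1 − ε` expected held-out accuracy (the Bayes ceiling the tests
guard against).

`generate_natural_corpus` emits sequences whose per-position *group*
follows a sticky Markov chain while the letter within a group is uniform —
same-group letters are exactly exchangeable, so a successful embedding must
place them together.  Group usage is non-uniform (linear 4:3:2:1 weights),
as residue frequencies in real databases are; with exactly uniform
marginals the ranking task's only signal is the middle-vs-context
interaction, which the freshly initialized (near-linear) network cannot
express, and SGD can sit at the symmetric saddle indefinitely.  The k-NN
co-membership chance rate with g equal groups is `(20/g − 1)/19` per
neighbor.

`generate_pssm` emits integer log-odds peaked (+5) on the emitting group's
letters with ±1 uniform noise, range-compatible with the logistic scaling.

What the fixtures deliberately do **not** emulate: real secondary-structure
segment length distributions, amino-acid composition biases of specific
structural states, evolutionary correlation between profile columns, or
any 3D-structure-derived labeling.  Passing tests therefore demonstrate
the correctness and the qualitative behavior of the machinery (multitask
transfer, embedding recovery, decoder repairs), not benchmark-level
accuracy on real proteins, which additionally requires large labeled sets
and genuine PSI-BLAST profiles.

## Problem sizes

The test and reproduction runs use desk-scale sizes chosen once: 30
proteins of length 40–80 across 3 tasks for the multitask comparison (5
seeds), 80 sequences of length 60–100 for embedding recovery (3 seeds), 20
noisy proteins for the Bayes-ceiling guard, windows 5–7, 20–30 hidden
units.  At these sizes each experiment takes seconds to ~10 s on one CPU
and the directional effects are large (multitask +0.07–0.1 Q over single
task; embedding co-membership ≥ 4× chance).

## Degenerate inputs and conventions

* Sequences are uppercased; out-of-dictionary characters become `X`.
* Accessibility thresholds are strict (`> 15 Å²` absolute, `> 0.15`
  relative); boundary values are labeled buried.  An all-zero protein in
  relative mode is all-buried with a logged warning.
* Per-residue arrays are 0-based internally; every report and file is
  1-based.
* Zero denominators in precision/recall yield 0 with a flag; a degenerate
  pooled rate in the Z-test yields p = 1 with a warning.
* Non-finite gradients skip the SGD step and increment a counter.
* Checkpoints are `.npz` containers with a JSON metadata entry; save →
  load → forward is exact.  All computation is single-threaded float64;
  identical seeds give bitwise-identical models, predictions and files.

## Known limitations

* No GPU, no minibatching, no learning-rate schedules — deliberate, to
  keep every update auditable.
* The Viterbi layer is a fixed post-processor, not a jointly trained CRF.
* `knn_overlap` requires `k` explicitly; there is no sensible default.
* The natural-protein scoring head is one hidden layer; deeper heads were
  not explored.
* Real-data performance depends on genuine PSI-BLAST profiles, which the
  package consumes from files but does not compute.
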