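# Methods

## Problem setting

Cognitive-workload classifiers trained on epoched fNIRS data degrade sharply
when evaluated on subjects, sessions, or even experiment *blocks* that were
not seen during training.  An epoch is a windowed trial `x ∈ R^{T×F}` of
hemoglobin-concentration changes (ΔHbO/ΔHbR, possibly with separate
intensity/phase optical types) with a class label `y` (e.g. an n-back level)
and a position in the hierarchy subject → session → block → trial.  This
package implements (i) an MLP-Mixer classifier adapted to such time series,
(ii) a family of kernel discrepancies that align the classifier's features
across blocks, sessions, and subjects during training, and (iii) the
evaluation machinery — split scenarios, a Wasserstein shift diagnostic,
paired tests, and a channel-masking importance scan — needed to study the
effect of the hierarchy on generalization.

## Classifier

The mixer maps each timestep's feature vector (all probe groups
concatenated, width `G·D = F`) through a shared fully-connected encoder to a
C-dimensional token, producing a token sequence along time.  `N` mixer
layers then alternate

* a temporal-mixing MLP acting along the T axis, and
* a channel-mixing MLP acting along the C axis,

each of the form `w2·GELU(w1·x + b1) + b2` (exact Gaussian-CDF GELU), with
pre-layer-normalization and a residual connection; the output is
global-average-pooled over time into the pooled feature vector `φ(x) ∈ R^C`,
followed by a linear head.  Defaults for the two-probe configuration are
`T=150, D=4, C=16, N=4`, temporal hidden width 64, channel hidden width 32;
for single-probe-group montages `D` is the full per-timestep feature count.
Dropout, when enabled, is applied to each MLP-block output.  Parameter and
multiply-accumulate counts are computed in closed form counting linear-map
multiplies only (no layer-norm/GELU/bias operations) and are verified
against an explicit per-layer enumeration in the tests; they serve internal
consistency checks, not comparisons with external profiling tools whose
counting conventions differ.

The network, its losses, and the Adam training loop run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`nirsda.autodiff`): the models here are a few tens of thousands of
parameters, for which dense numpy linear algebra on one CPU is entirely
adequate, and the engine keeps the package's training path fully
self-contained and bit-reproducible.

## Discrepancy losses

All alignment operates on the pooled pre-head features `φ(x)` under a
multi-bandwidth Gaussian kernel.  Bandwidths default to the median
heuristic on the pooled pairwise distances of the current batch with
multipliers (0.5, 1, 2), resolved **once per training step** from detached
feature values and shared by every term in that step — resolving per term
on small aligned class subsets creates a shrinking-bandwidth feedback loop
that destabilizes training.

* **MMD** — the biased V-statistic estimator (self-pairs included),
  `1/n_s² ΣΣ k(s,s') + 1/n_t² ΣΣ k(t,t') − 2/(n_s n_t) ΣΣ k(s,t)`.
  A `cross_term="printed"` option preserves a non-scale-consistent
  `2/(n_s² n_t²)` variant for comparison; it is not used in training.
* **Class-aware discrepancy** `D_{c1c2} = e1 + e2 − 2 e3`, with `e1`/`e2`
  the indicator-masked within-domain kernel means over class `c1`/`c2`
  pairs and `e3` the cross-domain mean over `(c1, c2)` pairs.  Empty class
  masks raise a dedicated error (the normalizing denominators vanish).
* **Contrastive domain discrepancy (CDD)** — mean of the intra-class terms
  minus mean of the inter-class terms.  Class terms absent from either
  domain are skipped and the normalizers reduced to the number of computed
  terms, since small mini-batches routinely miss classes.  Ground-truth
  labels are used on both sides: both "domains" come from the training set,
  so no target-label estimation is needed.
* **Block-wise discrepancy** — the class-conditional MMD between two blocks
  of the same subject and session, averaged over domain pairs and shared
  classes at the batch level.  A missing class yields a skip signal
  (distinct from an error); violated subject/session/block key constraints
  raise.

The training objective is `l = l_ce + α (D_cdd + D_bwise)`.  Under
subject-mode adaptation no within-subject pairs exist and the block-wise
term is identically zero.  During training the CDD is evaluated **within
each domain pair** and averaged across pairs (the two halves of a pair share
a subject in block/session mode); a pooled cross-subject variant is
available via `cdd_scope="pooled"`.  In designs whose blocks are
single-condition, a domain pair shares exactly one class, and the
within-pair CDD coincides with the block-wise MMD — the objective then
doubles the alignment weight, a structural property of the loss worth
knowing when choosing α.

## Paired sampling

`partition_domains` groups training epochs by the mode's key projection
(subject / subject+session / subject+session+block).  Each training step
draws `n_domain_pairs` valid pairs uniformly (block mode: same subject and
session, different blocks, at least one shared class), then up to
`samples_per_class_per_side` epochs per shared class per side, without
replacement within the batch.  Cross-entropy is computed on both halves.
The whole batch stream is a deterministic function of the seed.

## Training protocol

Adam with default moments; training stops when the validation criterion has
not improved for `patience` consecutive epochs (default 50), restoring the
best-epoch parameters.  Two selection criteria are available: the full
validation objective (`selection="loss"`, the default) and validation
accuracy (`selection="accuracy"`).  Under strong subject shift the
validation loss of a well-generalizing model can rise through
miscalibration while its accuracy still improves; the bundled benchmark
studies therefore select by validation accuracy, with the same criterion for
every training arm.  When no validation split is supplied, one is carved at
the subject level (no subject straddles the split).  Grid search enumerates
learning rate × dropout (and optionally α) over supplied folds, selecting by
mean validation accuracy with ties broken toward the smaller learning rate,
dropout, then α.

## Synthetic corpus generator

The generator emulates three published block-design layouts — a 26-subject,
3-session n-back study (9 blocks/session of 20 trials, condition order
0-2-3-2-3-0-3-0-2, 36 channels × HbO/HbR → 72 features, 2 s @ 10 Hz), a
30-subject finger/foot-tapping study (3 sessions × 25 trials per task type
in randomized order, 20 channels → 40 features, 10 s @ 13.33 Hz stored as
T=134), and a 68-subject single-session n-back study (16 blocks of 40
trials, 2 probes × HbO/HbR × intensity/phase → 8 features, 15 s @ 10 Hz) —
plus arbitrary custom designs.

Signal model per epoch:

* **Task response**: a boxcar convolved with a canonical hemodynamic
  response (gamma rise with mode 6 s, width 3 s; a delayed gamma undershoot
  starting at the peak, ratio 1/6 — placing the undershoot's onset at the
  peak makes the unit peak normalization exact), truncated to the epoch
  window and peak-normalized within the window so that per-class gains set
  the within-epoch signal size directly regardless of window length.  Each
  trial restarts its response; with all nuisance switched off, same-class
  epochs are exactly identical everywhere (a tested invariant).
* **Class coding**: monotone per-class amplitude gains (default 0.5 → 1.5
  across the ordered class set) applied to the HbO columns of the
  `informative_channel_fraction` lowest-index channels; HbR columns receive
  the negated response scaled by 1/3.
* **Subject effects**: multiplicative response gain `1 + N(0, 0.25)` and an
  additive baseline offset `N(0, 0.4)`.
* **Session effects**: per-feature additive offsets `N(0, 0.5)` emulating
  sensor re-placement between sittings.
* **Block effects**: per-feature additive offsets `N(0, 0.6)` (regional
  baseline and coupling drift within a sitting), a linear ramp across the
  block, and a small multiplicative gain jitter (SD 0.15).  Block offsets
  are per-channel deliberately: a globally uniform offset is removable by
  trivial normalization and carries no structure for alignment to exploit.
* **Noise**: AR(1) noise along time (coefficient 0.6, stationary SD 0.35)
  plus a 0.1 Hz sinusoidal systemic oscillation (amplitude 0.3, random
  phase per block, phase-continuous across the trials of a block).

All draws flow from one seed through two spawned streams per subject (one
for domain effects, one for data), so `sample_domain_effects` returns
exactly the effect tables the corpus generator applies, and corpora are
byte-identical across runs.  Effect magnitudes were calibrated once —
against the requirement that split-by-trial accuracy exceed split-by-block
accuracy by ≥5 points under the default classifier — and then frozen.

What the generator does *not* emulate: motion-artifact spikes, heartbeat
and respiration bands, optode-specific noise spectra, spatial correlation
between neighboring channels, label noise, or any physiologically validated
forward model.  Tests passing on this corpus demonstrate that the losses,
sampler, and evaluation machinery behave as designed under controlled
hierarchical shift — not that the method attains any particular accuracy on
real recordings.

## Evaluation

* **Split scenarios**: trial, block, session, subject.  The splitting unit
  is atomic (no epoch of a held-out unit leaks into training); units rotate
  through a seeded permutation across folds; defaults reproduce the
  published fold compositions (e.g. 26 subjects over 10 folds → 18 train /
  5 validation / 3 test).  The session scenario holds one session of every
  subject out, rotating per fold.
* **Wasserstein diagnostic**: mean exact optimal-transport cost (Euclidean
  ground metric, uniform weights) between seeded mini-batch pairs of train
  and test features; with equal batch sizes this is an assignment problem
  solved exactly.  Both sides are scaled by the training features'
  per-dimension SD by default so diagnostics from differently-scaled
  encoders are comparable.
* **Paired t-test**: classical paired t on fold-wise score differences,
  df = k−1; zero-variance differences raise a degenerate-case signal.
* **Channel-masking scan**: one channel group at a time is zeroed across
  all its feature columns; the 95% confidence band is the t-interval on the
  mean of the per-mask accuracies (the "over masks" reading; an alternative
  would be over folds per mask), and masks falling below the lower bound
  are critical.

## Benchmark problem sizes

The bundled studies run on a 12-subject corpus of the three-session
n-back design with ~25k-parameter mixers, 20 optimization steps per epoch,
at most 60 epochs with patience 20, and 5 seeds — sizes chosen so the full
study suite completes in minutes on a single CPU while preserving the
qualitative phenomena (the split-scenario ordering, the benefit of
block-wise adaptation on held-out subjects, and planted-channel recovery).
`scripts/acceptance.py` re-runs these studies from scratch and writes the
resulting numbers as JSON.

## Known limitations

* The discrepancy terms are O(n²) in the mini-batch; linear-time MMD
  approximations are out of scope.
* Adversarial (gradient-reversal) adaptation is not implemented.
* Real-data ingestion is limited to the package's HDF5+CSV container; raw
  optics preprocessing (Beer–Lambert conversion, filtering) and SNIRF
  import are out of scope.
* The generator's class signal is amplitude-coded; tasks distinguished by
  spatial topography alone (e.g. left- vs right-hemisphere activation) are
  not modeled.
* With `selection="loss"` under strong shift, early stopping can select
  substantially before the accuracy optimum; this is inherent to
  loss-based selection with miscalibrated models, not a defect of the
  stopping rule's implementation.
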