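# Methods

`metaclm` implements semi-quantitative potent-compound design as
conditional sequence translation: given a weakly potent *source
compound* (SC) and a desired potency difference ΔPot (pKi units), a
chemical language model (CLM) generates candidate *target compounds*
(TCs) — structural analogues expected to realise that difference,

    (SC, ΔPot) → TC.

A model-agnostic meta-learning (MAML) stage turns the pre-trained CLM
into an initialisation that adapts quickly to a new activity class from
little fine-tuning data (Meta-CLM). This note records the models, the
parameter choices that matter, and the limits of what the synthetic
benchmarks show.

## Data model and curation

Raw activity records are (SMILES, target, assay metadata, pKi) rows.
Curation keeps direct-interaction records (relationship type "D") at
the top assay confidence score (9) whose measurement type is an
equilibrium constant (Ki); structures that RDKit cannot parse are
dropped with a warning. Replicate measurements of one compound against
one target are aggregated as the geometric mean of Ki — equivalently
the arithmetic mean of pKi — provided all values lie within one order
of magnitude on the Ki scale. "One order of magnitude" is implemented
as max−min ≤ 1.0 pKi units, boundary inclusive: a 10-fold Ki ratio is
exactly one log unit and there is no natural strict/non-strict
preference. Wider-spread compounds are discarded. Identity and
deduplication use RDKit canonical SMILES throughout, including
generated-candidate matching; tautomer and stereochemistry
normalisation are deliberately off.

## Analogue series (CCR)

A compound is decomposed by cutting k ∈ 1..5 acyclic single bonds
between heavy atoms (never ring bonds). A cut set is a valid
core/substituent decomposition when exactly one fragment — the core —
carries all k attachment points, each other fragment carries exactly
one, and the core has at least twice the combined substituent
heavy-atom count. All size-filtered decompositions are retained (the
alternative — keeping one maximal core — is equally defensible; keeping
all is the more conservative reading of "series identification").
Attachment points are renumbered 1..k by the canonical atom rank of the
unlabelled core so that cores are comparable across compounds;
reassembly (`molzip` on matched attachment labels) must reproduce the
parent molecule, which is asserted in tests.

Compounds sharing an identical numbered canonical core form an analogue
series. All member pairs yield triples (SC, TC, ΔPot); |ΔPot| ≥ 2.0
(at least a 100-fold Ki change) marks an activity-cliff pair (AC_CCR),
the rest are CCR pairs. Pre-training uses both orientations of every
pair (signed ΔPot); fine-tuning uses only the orientation with the more
potent compound as TC. Identical (SC, TC) pairs arising from different
cores are pooled once per class.

## Tokenisation

SMILES strings are tokenised losslessly into bracket atoms, the
two-character halogens Cl/Br, and single characters. Potency
differences are binned over the fixed global range −6.62..6.52 pKi at
width 0.01 — exactly 1314 bins, one condition token each, half-open
with the top edge closing the last bin. The condition token is
appended to the encoder input after the SC tokens (a single fixed slot;
the alternative prefix position would work equally, but one position
had to be chosen). Out-of-range differences raise by default; an
opt-in clamp truncates to the range boundary, since the printed range
is a property of a training corpus, not a law of chemistry.

## Base model

The CLM is a pre-norm encoder–decoder transformer with multi-head
self-/cross-attention, a ReLU feed-forward block, sinusoidal positions,
and a softmax over the full vocabulary, trained with teacher forcing,
token-level cross-entropy (padding masked) and Adam. It is built on a
small in-package reverse-mode autodiff engine over NumPy arrays
(`metaclm.autodiff`); every operator's vector–Jacobian product is
checked against central finite differences in the test suite. The
reference configuration is encoding dimension 256, batch size 64,
learning rate 0.001, up to 1000 epochs, with a per-epoch loss record
and min-loss checkpoint selection (earliest epoch on ties). The
desk-scale preset (dimension 32–64, one layer, two heads, float32)
keeps the full algorithm and shrinks only capacity so that every stage
runs in minutes on one CPU.

Candidate generation draws n = 50 sequences per (SC, ΔPot) by
multinomial sampling at temperature 1.0 (greedy and temperature knobs
exist); the decode budget is 1.5× the longest training target. Decoded
strings are validity-checked with RDKit and canonicalised; invalid
strings are kept with a flag rather than silently dropped, so the
requested sample count is always accounted for.

## Meta-learning

Each activity class with at least 300 analogue-pair triples is one
task, split 80/20 into support and query sets by seed. Per meta-epoch
and task the shared parameters θ are adapted on the support set by
`inner_steps` SGD steps at `inner_lr` (the inner loop), the adapted
model's query loss is evaluated, and θ is updated by Adam on the sum of
query losses across tasks (the outer loop). The meta-gradient is
first-order MAML: the query-loss gradient at the adapted parameters.
With `inner_lr = 0` this reduces exactly to multi-task training on the
summed query loss, which is one of the verified invariants.

Three numerical choices matter at desk scale and were settled during
method development:

- **Outer-optimiser warmup and epsilon.** Meta-training starts from a
  trained model. Adam's first updates move every parameter by
  ≈ lr·sign(gradient) regardless of gradient magnitude, which knocks a
  converged model off its optimum before the second-moment statistics
  exist. The outer Adam therefore uses linear learning-rate warmup
  (default 20 updates) and ε = 1e-4.
- **Inner learning rate.** The library default is `inner_lr = 0.01`
  (the canonical one-step formulation). The bundled experiments use
  0.001: at desk scale, larger inner steps drive the MAML objective to
  trade unadapted competence for one-step adaptability so aggressively
  that the tiny fine-tuning sets of the low-data evaluation cannot
  restore basic sequence validity. At 0.001 meta-training improves
  both the post-adaptation query loss and the plain family loss.
- **Batching.** By default an epoch performs one outer update with
  every task's full support and query sets (the textbook loop, used by
  the unit tests). The experiment configuration opts into task
  batches of 2 and support/query minibatches of 48 so that an epoch
  performs several outer updates — a single full-batch update per
  epoch gives the optimiser too few steps within a desk-scale budget.

Fine-tuning takes a class's activity-cliff triples (TC more potent),
draws a seed-frozen subset of the requested fraction — nested, so the
10% subset is contained in the 25% subset — and trains at learning rate
0.0001 for up to 200 epochs (experiments use 40), returning the
min-loss checkpoint. The same routine fine-tunes the meta-trained
initialisation (Meta-CLM arm) and the plain pre-trained one (CLM arm);
the two arms differ only in their starting parameters, which is the
comparison of interest.

## Evaluation

A class's AC_CCR triples are divided into fine-tuning and test
instances by a per-pair Bernoulli(0.2) draw — 80/20 in expectation —
redrawn until the two sides share no core structure (bounded retries,
then an error naming the colliding cores). A fixed-size 20% split
would require the test side to consist of exactly whole cores summing
to the target size, a subset-sum condition that is often infeasible on
small classes; the Bernoulli form keeps the stated ratio and the
retry-until-disjoint semantics. CCR triples sharing a core with the
fine-tuning set are excluded; the remainder joins the test side.

Unique test compounds are categorised at 1 μM: sources (SCs) have
pKi ≤ 6, known target compounds (KTCs) pKi > 6. For each SC occurring
in a test SC–KTC pair, 50 candidates are sampled, conditioned on the
largest ΔPot among that SC's test pairs (the most ambitious instruction
the test set supports for that template; the conditioning value for
evaluation is otherwise a free choice). A pair is reproduced when the
KTC's canonical structure appears among the SC's valid candidates;
class reproducibility is the percentage of unique KTCs reproduced.
Valid candidates matching no test compound are counted as novel. Arms
are compared with two-sided Welch t-tests on per-run reproducibility
and on the pooled KTC-pKi and SC–KTC ΔpKi distributions, starred at
p ≤ 0.05 / 0.01 / 0.001 / 0.0001 (boundary inclusive).

## Synthetic activity classes

The generator emulates curated activity classes with controllable
analogue structure. Sixteen drug-like scaffold cores (9–10 heavy
atoms, one marked substitution site) are combined with 26 monovalent
substituents (1–4 heavy atoms); potency follows an additive model
pKi = 5.0 + effect(substituent) + N(0, 0.1²). Substituent effects are
evenly spaced over [0, E] with E = 2/(1 − √cliff_rate) (≥ 3), so the
expected fraction of analogue pairs crossing the 100-fold cliff
threshold matches the target cliff rate (default 0.2) and achievable
potency differences span at least three log units. Scaffold-defining
groups are deliberately disjoint from the substituent pool — otherwise
two core+substituent assemblies can collide into one molecule with two
designed potencies.

Meta-learning families draw per-class effects as
`scale·shared + (1−scale)·own + N(0, sd)` with the shared component
fixed by the family seed and each class's own component by (seed,
class index): `scale = 1` gives related tasks perturbed by
`class_effect_sd` (experiments use 0.5 — strongly related but clearly
distinct structure–activity maps), `scale = 0` gives unrelated tasks
with the same marginal spread (the negative control).

## Desk-scale experiment sizes

The bundled two-arm comparison uses 8 training classes (two 14-membered
series each, ≈ 340–380 pooled directed triples — above the 300-pair
inclusion threshold even when a rare replicate-spread discard removes a
compound) and 3 held-out classes per seed, each consisting of 24
two-compound series on distinct scaffold cores. A two-compound series
pairs a weak template with its far-more-potent analogue, so every
series contributes exactly one ≥100-fold activity-cliff pair: this
probes the activity-cliff prediction setting directly and makes
core-disjoint fine-tuning/test partitions structurally attainable
(whole cores can land on one side of the Bernoulli split).

The model is the dimension-32 desk preset; pre-training runs 10 epochs
at learning rate 0.002 — deliberately short of convergence, so that the
meta-training stage (24 epochs) has headroom: the comparison is between
a pre-trained model and the same model after the additional
meta-learning stage, and the unrelated-task negative control receives
the same additional compute, which separates task-structure transfer
from a mere extra-training effect. Fine-tuning runs 40 epochs at the
10% fraction (one to three cliff triples); decomposition depth is one
site (the synthetic series vary a single site). One pipeline run takes
roughly 100 s on one CPU; the shipped comparison uses five seeds for
the related-task family and three for the negative control. At this
scale the advantage of the meta arm manifests as weak dominance:
frequent exact ties between the arms, interspersed with strict wins
for the meta arm, and no observed losses across the piloted seeds —
individual seed differences are within sampling noise, and only the
across-seed mean ordering is claimed.

## What the synthetic benchmarks do and do not show

Passing tests demonstrate that the machinery is correct and that the
meta-learning arm extracts transferable structure when it exists: the
additive potency model makes (SC, ΔPot) → TC learnable by construction,
sequence lengths are short, and chemical diversity is far below any
curated corpus. They do not show that the desk-scale models rival
GPU-scale training on public activity data, nor do synthetic
reproducibility percentages correspond to values obtainable on real
activity classes; only their direction and ordering across arms carry
meaning. Known limitations: first-order meta-gradients only (no
second-order option — the autodiff engine does not build
grad-of-grad graphs); no stereochemistry or tautomer normalisation in
matching; multinomial sampling is the only decoding scheme exercised
beyond greedy; and the CCR enumeration is exhaustive over cut sets,
which is exponential in the per-molecule acyclic-bond count and
intended for lead-like molecule sizes.
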