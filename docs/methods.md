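# Methods

## Model

funcascade predicts multi-label protein function by evidence-weighted
voting over annotated reference proteins. For a function scheme with K
categories (default: the 24 FunCat top categories) and reference
annotations held as a binary K×n indicator matrix D, each branch computes a
K-vector of scores as D·w, where w holds one nonnegative evidence weight
per reference protein:

* **similarity** — w are alignment bit scores of the query's homologues
  (absence of any hit is the "no homologue" condition, not a zero score);
* **interaction** — w are combined confidence scores of the query's
  annotated network neighbours, used exactly as supplied (the vote's
  ranking is invariant to the weight scale, so no rescaling of, e.g.,
  0–1000 combined scores is applied);
* **PseAAC** — w are cosine similarities between the query's and each
  reference's pseudo amino acid composition descriptor; this branch is
  defined for every query that has a sequence.

The cascade tries the branches in that fixed order and uses the first with
any evidence. The underlying assumption is guilt-by-association: homologues
share function more reliably than interaction partners, which in turn share
function more reliably than proteins that merely look compositionally
alike; falling through the cascade therefore trades accuracy for coverage,
and total coverage is 100% of queries whenever the reference set is
non-empty.

Scores are converted to predictions by sorting categories in descending
score order; the category ranked k-th is the k-th-order prediction. Ties
are broken by ascending category number — an arbitrary but deterministic
rule, chosen so that reports are identical across runs and platforms.
The vote is deliberately implemented as the plain sum over all references
(an optional `top_k` restricts the PseAAC vote to the k nearest references
for users who prefer strict nearest-neighbour semantics; the default uses
all).

## PseAAC encoding

A sequence X₁…X_N is encoded as 20 amino-acid frequencies plus, for each of
m property scales, λ lag-correlation factors
C_i = (1/(N−i)) Σ_k (F(X_k) − F(X_{k+i}))², i = 1..λ.
Defaults: λ = 50, sequence-order weight ϖ = 0.15, and the five factor-score
scales packaged in `data/property_factors.tsv` (polarity, secondary
structure, molecular volume, codon diversity, electrostatic charge), giving
20 + 5·50 = 270 dimensions. The packaged constants are published factor
scores and are used bit-exact; the mean-0/mean-square-1 normalisation
F(X) = (L(X) − mean L) / sqrt(mean (L − mean L)²) is applied only to
user-supplied raw scales.

Numerical conventions, each chosen once and fixed:

* **Shared denominator.** With several property scales the correlation
  blocks of all scales share one denominator, Σf + ϖ·ΣΣC, so the full
  vector is a point on the probability simplex (entries ≥ 0, sum = 1).
  This gives a single well-defined composition block and a crisp testable
  invariant. A per-scale variant (each block normalised by its own Chou
  denominator) is available via `shared_denominator=False`.
* **Short sequences.** For N ≤ λ the correlation depth is effectively
  N−1 and the remaining entries are zero, keeping the dimensionality — and
  hence cosine comparability — constant across proteins.
* **Non-standard residues** (B, J, O, U, X, Z) carry no property value:
  they are skipped by the composition counts and break correlation windows
  like sequence gaps, so no pair spanning them contributes. Silent coercion
  to some standard residue would quietly corrupt the feature space.
* **Degenerate inputs.** Sequences without two standard residues cannot
  yield correlation factors; all-identical property scales cannot be
  normalised. Both raise dedicated errors rather than returning NaNs.

## Evaluation harness

Order-k accuracy is ACC_k = (1/n) Σᵢ U_{k,i}, with U_{k,i} = 1 iff the
k-th-ranked category of protein i is truly annotated. Because every
prediction is a full permutation, Σ_k ACC_k equals the mean true-label
count per protein for any predictor — the suite uses this conservation law
as a self-check on the harness.

Both protocols remove a held-out protein from the reference universe of
*all* branches (annotation column, self-hits, edges). In k-fold evaluation
the entire test fold is excluded at once, so test proteins — unannotated by
construction — cannot vouch for each other through similarity hits or
edges. Fold assignment is unstratified uniform random (near-equal folds,
sizes differing by at most one), fully derived from one integer seed; the
reported spread across repeats is the sample standard deviation (ddof = 1),
the conventional choice for a handful of repeats.

"False-wrong" extraction lists proteins whose 1st-order call is not
currently annotated while the 2nd-order call is; under incomplete
annotation these top calls are candidate novel functions rather than plain
errors, and the report groups them by producing branch.

## Synthetic data generator

The generator produces datasets with the statistical structure the cascade
exploits, without modelling real biology:

* **Labels via profiles.** Proteins draw a label *profile* (a functional
  module's label set) rather than independent categories. Profile
  membership weights follow the per-category protein counts of the mouse
  FunCat reference annotation, so a few categories dominate; the mean
  label-set size defaults to 3.1 (the reference annotation's labels-per-
  protein ratio). Correlated label sets are both realistic (annotations
  co-occur in modules) and necessary: with independently sampled labels
  under a skew this strong, "shares ≥ 1 label" is almost uninformative and
  no network, however clean, would let a weighted vote recover functions.
  10% of proteins get one label swapped at random (count-preserving noise).
* **Homology clusters.** A configurable fraction of proteins is grouped
  into clusters that share a profile and exchange mutual similarity hits
  whose scores increase with label overlap (the absolute score scale is
  irrelevant to ranking).
* **Interaction network.** `gba_strength` g is the probability that an
  edge joins a label-sharing pair. Edges are drawn from an exact mixture of
  uniform pair pools — same-module pairs, uniform random pairs, and
  non-sharing pairs — with the mixing rate solved against the realized
  random-pair sharing rate ρ so that P(edge shares) = g holds exactly.
  Consequently g = 1 wires whole modules together (perfect
  guilt-by-association) and g = ρ reproduces uniform random pairing in
  distribution (the null network). Edge weights are drawn independently of
  the labels so a null network carries no annotation signal at all.
* **Orphans and sequences.** A fraction of proteins receives neither hits
  nor edges and is reachable only through the PseAAC branch. All sequences
  are sampled from label-dependent residue-usage tilts — enough signal for
  compositional discrimination, with no pretence of protein grammar, domain
  structure, or realistic network topology.

What passing tests on this generator do and do not show: they demonstrate
that each branch recovers exactly the structure it assumes (homology
transfer, network GBA, compositional similarity) and that the harness
measures it honestly; they do not certify accuracy on real proteomes,
where evidence quality, annotation incompleteness and sequence biases are
far messier than the generator's idealised clusters and modules.

A note on the null comparison: with g = ρ the interaction branch's
first-order accuracy is compared against the top-category-frequency
baseline. The branch's vote is an argmax over the category frequencies of
a *finite* neighbour sample, which can only lose accuracy relative to the
exact-frequency baseline; the acceptance test therefore runs a dense null
network (mean degree 48) to keep that finite-sample penalty small and
checks both directions asymmetrically — no excess above the baseline
beyond Monte-Carlo error, and at most a small shortfall below it.

## Problem sizes and defaults

Behavioural checks run leave-one-out at n = 500 proteins (single seed for
the perfect-GBA and strong-homology conditions, 20 seeds at n = 300 for
the null comparison) and repeated ten-fold at n = 150–600; these sizes give
stable accuracy estimates while keeping the full suite fast on one core.
Generator defaults — 8 edges per protein, gba_strength 0.9, homology
fraction 0.4, orphan fraction 0.05, 40 profiles, sequence lengths 80–300 —
are fixed study-like conditions, not tuning knobs; the acceptance script
runs them unchanged.

## Known limitations

* The cascade is strictly sequential; no blending of score vectors across
  branches is attempted (a deliberate non-goal).
* Alignment and interaction evidence are consumed from files; the toolkit
  neither runs aligners nor estimates interaction confidences.
* Only flat schemes are supported — no hierarchical sub-categories, no GO.
* Scores are ranks, not probabilities; no calibration is provided.
* The ID map between annotation and network namespaces is applied as
  given; proteins without a mapping simply lack interaction evidence.
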