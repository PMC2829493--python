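# Methods

This note records the models implemented in `cheops`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.

## Operon prediction from gene proximity

Gene positions are summarised by their centres x_i = (start + end)/2; the
working assumption is that centres of genes in one operon are
approximately independent draws from a normal distribution with an
operon-specific mean and a shared variance — reasonable because genes are
short relative to a replicon. Predicting operons is then a 1-D
model-selection problem: choose the number of clusters k and a contiguous
assignment of genes to clusters.

For fixed k, the assignment minimises the pooled within-operon sum of
squares W_k = Σ_l Σ_{i∈l} (x_i − x̄_l)²; across k, the corrected Akaike
information criterion AICc(k) = 2 ln W_k + 2nk/(n − k + 1) is minimised,
where n is the number of genes in the candidate segment. The penalty term
grows quickly as k approaches n, guarding against over-splitting on the
short gene sets typical of this problem.

Biology constrains the search in four ways:

* **Candidate segments.** Only genes on the same strand with no
  intervening opposite-strand che gene can share an operon, so each
  replicon is first cut into maximal same-strand runs. Non-che genes are
  invisible to this step.
* **Merge constraint** (`merge_distance`, default 3,500 bp): adjacent
  genes with an intergenic gap at or below it are fused before the
  search. The default is the largest intra-operon gap in the *E. coli*
  chemotaxis operon.
* **Split constraint** (`split_distance`, default 100,000 bp): adjacent
  genes further apart are never co-clustered. The default sits below the
  closest inter-operon spacing in *R. sphaeroides*; on corpora whose
  inter-operon gaps clear the whole 50–200 kb range the assignment is
  invariant to this parameter, which the test suite checks.
* **Separation requirement**: in an admissible partition the largest
  within-operon gap is smaller than the smallest between-operon gap of
  the same segment. Inadmissible partitions are discarded *before* the
  AICc argmin (the alternative — filtering after — could leave a segment
  with no answer).

Numerical choices: natural logarithm in the AICc; W_k = 0 (every cluster
a singleton or degenerate) maps to −∞ so that a fully split segment wins
whenever nothing forces a merge — isolated genes become single-gene
operons, which is the biologically expected reading. AICc ties resolve
toward smaller k (parsimony); W_k ties resolve toward the partition whose
largest within-cluster gap is smallest, then earliest split points.
Distances are intergenic gaps by default (`distance_mode="centre"` is
available). The search enumerates admissible split placements exactly;
che segments hold at most tens of genes, so exhaustion is cheaper and
more transparent than dynamic programming. Sums of squares are computed
directly per block (prefix-sum shortcuts lose the exact zero on
singleton blocks, which the −∞ sentinel depends on). Circular replicons
are treated as linear in file order, so an origin-spanning operon would
be missed — a known limitation.

## Functional-order scores

For a candidate gene order (a permutation of {A, B, R, W, Y}), each
operon is scored by ordering its *distinct* gene types by permutation
rank and summing (rank difference − 1) over consecutive present pairs;
genes missing before the first or after the last present gene are free.
Copy number and within-operon gene order never matter. Corpus scores sum
over all operons of all species; at corpus level a linear order and its
reverse always tie. The circular variant scores each operon as the
minimum linear score over all rotations of a cyclic order, so a step
"around the end" of the cycle is not skipped. Cyclic orders are
canonicalised by rotating the alphabetically smallest gene to the front;
mirror-image cycles are deliberately kept distinct, since a cycle and its
reversal describe different gene orders.

## Pathway models

CheB, CheR, CheW and CheY are all functionally linked to CheA; each
linkage is a putative interaction (PI), recorded at operon granularity
("there is at least one PI of this type between these operons") and
classed as within- or across-operon. Assembly assumptions: every Che
protein belongs to some functioning pathway; pathways prefer to stay
distinct; within-operon PIs are preferred to across-operon ones; a
pathway uses as few operons as possible; and across-operon partners are
chosen by how often the two compressed operon types co-occur within
species across the whole corpus.

A species with a single CheA homologue connects that CheA to every other
Che protein. Otherwise, per CheA-encoding operon: within-operon PIs
first; if the pathway is incomplete, partners are sought tier by tier —
(a) one exactly complementary operon (type set equal to the deficit),
(b) several jointly complementary operons without surplus genes, (c) any
non-CheA operon contributing missing types, (d) another CheA-encoding
operon. Within a tier, candidates without existing cross-operon edges
are preferred, then higher co-occurrence, then lexicographic type and
operon id — every tie-break is total, so predictions are deterministic.
Finally, left-over operons with no edges are attached to the CheA operon
they co-occur with most.

That last step deliberately skips operons whose core content is CheY
only. Wiring isolated cheY genes is precisely what the four models
disagree on, and attaching them unconditionally would make the base and
isolated-Y models indistinguishable: `ABRWY` leaves them unwired,
`ABRWY+Y'` connects still-unconnected CheYs to every CheA, and `ABRW+Y`
/ `ABRWY+Y` connect every CheY to every CheA (the former also keeps Y
out of the assembly steps entirely). A~B/A~R/A~W edges are identical
across the base-family models, giving the containment
ABRWY ⊆ ABRWY+Y' ⊆ ABRWY+Y that the tests assert. CheV and CheZ never
participate in pathway models.

## Shuffled-operon nulls

The null preserves everything about a species except the allocation of
genes to operons: gene-type tokens are permuted uniformly within the
species and refilled into the fixed operon-size slots, keeping operon
count, sizes, coordinates, strands and the per-species type multiset.
Replicates (default 100) re-run the full downstream analysis — including
rebuilding the co-occurrence table from the shuffled corpus — and report
per-cell means and standard errors (sd/√n_reps); observed-vs-null
displays use mean ± 2·SE bands. Note the SE band localises the *null
mean*; calibration of a single observed corpus against the null is
checked at the scale of the replicate standard deviation, the spread an
individual draw actually has. Homogeneity of observed and shuffled count
tables is tested with the standard two-sample chi-square statistic
(no continuity correction; categories with zero combined margin are
dropped with a warning).

## Synthetic corpora

The generator emulates the statistical shape of a large multi-species
che-gene survey: operon compositions are drawn from a frequency table
whose default is heavily CheY-skewed (≈50% single-gene Y operons, then
W, complete ABRWY, R, ABWY, …), operons per species follow
1 + Poisson(5.89) (mean 6.89), gene lengths are type-specific (≈3 bp per
residue of the corresponding query protein, e.g. CheA ≈ 1,962 bp), intra-
operon gaps are uniform on 20–3,000 bp and inter-operon gaps on
250–400 kb. Species are resampled until all five core genes are present,
matching the conditioning of real analysis sets. Because intra-gaps stay
below the merge threshold and inter-gaps above every split threshold the
robustness sweep uses, planted assignments always satisfy the
clusterability conditions — exact recovery is a designed property, and
recovery tests are not luck. An adversarial configuration
(`adversarial=True`, intra-gaps up to the split distance) removes that
guarantee so the AICc search itself, not the hard constraints, is
exercised. The generator does not simulate sequence content, paralogue
evolution, horizontal transfer, overlapping genes or non-che genes;
passing tests therefore demonstrate correctness of the machinery under
the stated geometric conditions, not performance on real annotation
noise (mis-called strands, missed homologues, SDRR/CheY ambiguity).

## Problem sizes and determinism

Tests and examples run on corpora of 8–200 synthetic species with ~7
operons each and null ensembles of up to 100 replicates — sizes chosen
so every claim is recomputed from scratch in seconds while keeping the
per-species statistics in the regime the defaults describe. All
randomness flows through seeded `numpy` generators; replicate r of a
null ensemble uses the stream seeded by (base_seed, r), and the CLI
requires an explicit seed for any stochastic stage, making whole
pipeline runs byte-identical on re-execution.
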