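# Methods

This note documents the models, conventions and numerical choices
behind mitocomp, and what the synthetic test bed does and does not show
about real data.

## Genomes and coordinates

Internally all feature intervals are 0-based half-open; the GenBank
boundary uses that format's 1-based inclusive convention (handled by
Biopython). Features spanning the origin of a circular genome are
linearized by rotating the sequence at read time; the rotation offset is
recorded on the genome. Gene labels are normalized to one canonical
scheme (COX1–3, ND1–6, ND4L, ATP6/8, CYTB, trnX-ANTICODON, rrnL/rrnS,
D-loop) through a shipped alias table; unknown labels pass through with
feature class `other` and a logged warning. The ambiguity code N is
accepted; all other IUPAC ambiguity letters are rejected outright, so
downstream codon counting has a single well-defined policy (codons
containing N are skipped and tallied).

## Composition

Percentages are computed over counted A/C/G/T with N excluded from the
denominator. AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); a zero
denominator is reported as skew 0 with an explicit undefined flag.
Per-class rows concatenate each class's feature slices strand-oriented;
overlapping or duplicated features contribute independently, so class
sizes can exceed the unique genomic span and class proportions can sum
above 100% — this matches how published per-class tables count a
duplicated gene's bases twice. Printed-table comparisons round half-up
(ties away from zero); Python's built-in banker's rounding would
misreproduce printed values such as 63.66%.

## RSCU and the table dialect

RSCU(c) = k·n_c / Σ_F n for family F of size k; within a fully counted
family the values sum to k, and a single-codon family always has
RSCU 1. Which codons form a family is a deliberate degree of freedom:

- `table5-mito` partitions by the invertebrate mitochondrial code
  (AUA→Met, UGA→Trp, AGA/AGG→Ser) — the biologically consistent choice.
- `table8-standard` (default) partitions by the *standard* code while
  excluding the true mitochondrial stops UAA/UAG from the counts. This
  reverse-engineered dialect is what several published mollusc
  codon-usage tables actually use: the printed values are only
  reproducible with AUA inside a 3-codon Ile family, AGA/AGG inside a
  6-codon Arg family, and UGA sitting alone in the zeroed stop family
  (hence RSCU(UGA) = 3.00 and RSCU(UGG) = 1.00 exactly). Those two rows
  are flagged as dialect artifacts in reports rather than treated as
  biology.

Both partitions are exposed everywhere a partition is accepted.
Third-position degeneracy of a codon is the number of third-position
states encoding the same amino acid under the translation code (1, 2,
3 or 4); degenerate-site composition stratifies third-position base
counts by that class.

## Ka/Ks estimation

Both estimators consume a gap-free codon alignment built by aligning
the two proteins globally (BLOSUM62, gap open 10, extend 1 — a
configurable scoring object) and replacing residues with their source
codons; gap and N columns are dropped and counted.

**NG86.** Synonymous sites per codon are per-position fractions of
non-stop single-nucleotide changes that are synonymous (mutations to
stop codons excluded from numerator and denominator). Differences
between codon pairs are averaged with equal weight over all shortest
mutational pathways that avoid stop codons; a pair whose pathways are
all blocked is skipped and logged. Proportions are corrected with the
one-parameter distance d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields NA.

**YN00.** κ is estimated from codon positions that are nondegenerate or
fourfold degenerate *in both codons of a column* via the Kimura
two-parameter distance, the two classes combined weighted by site
counts (fallback κ = 2, flagged, when no class is estimable). Codon
equilibrium frequencies use F3×4 fitted to both sequences jointly. Site
counting weights every possible change by π(target)·κ^[ts]; the
synonymous fraction is normalized globally over the sequence rather
than codon-by-codon — under a GY94-style process with heterogeneous
per-codon total rates the global normalization is the choice that makes
dN/dS consistent for the generating ω (the per-codon variant
overestimates ω by ~16% at these AT-rich frequencies). Differences are
distributed over stop-free pathways weighted by the product of step
rates π(target)·κ^[ts]·ω^[nonsyn], symmetrized over the two comparison
directions so that swapping the sequences changes nothing. Proportions
are corrected with the two-parameter distance separately for synonymous
and nonsynonymous sites, and ω is iterated from 1.0 to relative
convergence 1e-6 (cap 100 iterations, clamped to [1e-4, 99]; a
non-converged result is returned flagged). Ka/Ks is NA whenever Ks is
zero or a distance is undefined — never 0/0 or infinity.

**Fisher validation.** The 2×2 table is {synonymous, nonsynonymous} ×
{differences, sites − differences} with real-valued counts rounded to
the nearest integer; the two-sided p sums all tables (fixed margins)
with probability ≤ the observed one. The construction of this table is
our documented choice; the computation itself is scipy's exact test,
cross-checked in the suite against exhaustive hypergeometric
enumeration.

For genome-level runs, duplicated genes contribute their first copy in
genome order (configurable through the gene list).

## Gene-order comparison

A *cluster* is a maximal run of genes contiguous and identically
ordered in both genomes, with genes private to one genome transparent
(skipped when testing contiguity). The transparency rule is essential:
published cluster notation elides the other genome's interleaved
private tRNAs, and without it those printed clusters are irrecoverable.
Duplicated labels are matched greedily left-to-right (k-th occurrence
to k-th occurrence) — a documented heuristic, backstopped by a replay
validator that re-checks every reported cluster by direct contiguity.
Reversed clusters additionally require each column to flip strand (the
signature of an inversion); annotations that keep everything on the
plus strand can relax this. Circular orders use wrap-around adjacency,
equivalent to brute force over rotations at these sizes (≤ ~50 genes).

**TDRL.** A single event duplicates a contiguous block (≤ `max_block`
genes) in tandem and then retains, per block position, the first copy,
the second, or both. `tdrl_candidates` searches all events exhaustively
(3^L retentions per block; a replay cap raises an error advising a
smaller window). Because sister genomes both descend from an unobserved
ancestor, some published order pairs are *not* one event apart in
either direction — e.g. k-m-m-l-n versus k-l-m-n: no single tandem
duplication of the latter can leave an l after the second m.
`tdrl_ancestral_candidates` therefore reconstructs a single ancestral
duplication (common prefix + block permutation + common suffix, each
descendant's middle decomposed into two block subsequences) whose two
independent random losses yield both observed orders; for the published
region it recovers the ancestral trnY–trnM–trnD arrangement with a
tandem trnM–trnD duplication.

## Synthetic data

The generators emulate an AT-rich bivalve-like mitogenome: 13 PCGs, 22
tRNAs, 2 rRNAs and one control region (tRNAs 66 bp, rRNAs 1200/850 bp,
control region 900 bp, PCGs 120 codons by default; non-coding sequence
drawn at 66% AT). Codon sequences are sampled from a published
codon-count profile (start ATG, stop TAA, no internal stops).

Codon evolution is a GY94-style continuous-time process: rate from
codon i to j is π_j·κ^[transition]·ω^[nonsynonymous] for single-position
changes, zero otherwise and zero into stops, scaled so that t is the
expected number of substitutions per codon at equilibrium. Each codon
is simulated exactly (event-by-event) along two independent branches of
length t/2 — a symmetric star design matching pairwise-estimator
assumptions — and the true synonymous/nonsynonymous event counts are
recorded. `divergence_for_ks` converts a target synonymous divergence
(e.g. Ks ≈ 0.3, the regime used for calibration) into t from the
model's synonymous event rate and synonymous site content. Default
codon frequencies are F3×4 fitted to the published *R. philippinarum*
counts; uniform frequencies are available. All generators take explicit
integer seeds and use private Mersenne Twister instances, so outputs
are bit-identical across platforms.

What the synthetic bed does *not* emulate: indels (the alignment stage
is exercised with hand-built gap cases instead), among-site rate
variation, strand-asymmetric mutation, tRNA/rRNA secondary structure,
and real annotation noise. Passing recovery tests therefore shows the
estimators are correct under their own model assumptions at realistic
divergences, not that real annotations are error-free.

## Calibration results the suite verifies

At κ = 2, 1000 codons, synonymous divergence ≈ 0.3 and 100 replicates
per condition, mean YN00 ω̂ recovers ω ∈ {0.1, 0.3, 1.0} within ±15%
(observed biases were within ±6% at these settings); Ka ≈ Ks at ω = 1
within Monte-Carlo error; and forcing κ = 1 with uniform frequencies
reduces YN00 to within 5% of NG86 (the residual gap is the two- versus
one-parameter distance correction). Planted reversals and planted TDRL
events are recovered in 100% of 200 seeded cases each. These problem
sizes mirror the calibration regime above and keep the default suite
fast.

## Known limitations

- YN00 here is a faithful re-derivation, not a line-for-line port of
  any particular implementation; third-party tools differ in site
  normalization and κ pooling, so per-gene values can differ by a few
  percent on real data.
- The greedy duplicate matching in cluster detection can in principle
  mis-pair copies in pathological orders; every reported cluster is
  replay-validated, so such cases surface as missing (never wrong)
  clusters.
- Ancestral TDRL reconstruction assumes a single-copy ancestor block
  and one duplication; multi-event histories are out of scope.
- The printed codon-usage total for the PCG set (5189/4081 codons) is
  not consistent with the printed per-gene lengths (4804/4113 stop-
  excluded codons); `published.codon_total_discrepancy()` reports both
  sides, and nothing in this package resolves the conflict.
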