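# Methods

This note documents the models and algorithmic choices behind megamap: what
each stage assumes, which parameters matter, what the synthetic data do and
do not emulate, and where the design was genuinely open.

## Gamete model and two-point estimation

Each megagametophyte is one meiotic product. The simulator draws, per
chromosome of genetic length L cM, a Poisson(L/100) number of crossovers
with breakpoints uniform on the chromosome — a no-interference (Haldane)
process. The transmitted allele at a locus is the per-marker parental phase
XOR the segment parity. Genotyping error is an allele flip applied
independently per call (rate ε), matching the mechanism that inflates map
length: one flipped call creates one apparent recombinant in each flanking
interval. Missingness is applied after the flip, independently per call.
Crossover interference is exposed only through the process choice, not
asserted as biology: the species' true interference is unknown, so the
simplest correct gamete model is used and its consequences are documented
(below) rather than hidden.

Phase is unknown in real data, so the two-point recombinant count between
markers with k mismatches over n pairwise-complete gametes is
k' = min(k, n − k) (the phase minimizing recombination; k > n − k means
repulsion). r̂ = k'/n and the LOD against free recombination is
k'·log10(2r̂) + (n − k')·log10(2(1 − r̂)), with the r̂ = 0 limit n·log10 2.

## Binning, grouping, ordering, distances

*Binning* is exact: two markers share a bin iff their rows agree at every
sample, including the missing pattern. The representative is the member with
the fewest missing calls, ties broken lexicographically — under exactness
the choice is cosmetic, but the rule is stated so relaxed binning modes can
slot in. All downstream pairwise quantities use representative signatures
only.

*Grouping* forms connected components of the graph with an edge when
LOD ≥ 8 and r̂ ≤ 0.35 (both thresholds configurable). Transitive closure is
deliberate: a chain a–b–c belongs together even when a–c alone would not
qualify.

*Ordering* is RECORD: `n_counts` (default 16) random insertion sequences,
each inserted greedily at the position minimizing COUNT — the summed
adjacent recombinant counts — keeping the best final order. The *ripple*
pass slides a window (default 10 bins, step 1) and accepts permutations only
on strict COUNT decrease, iterating until a pass makes no change; COUNT is
integer and bounded below, so termination is guaranteed. A 10-bin window
cannot enumerate 10! permutations; for windows of more than 8 bins the
candidate set is all circular shifts, all adjacent transpositions and 5,000
seeded random permutations (exhaustive below that). This is a documented
policy, not a reconstruction of any particular mapping package's internals.
Orders are reported with the lexicographically lower terminal bin first to
fix the reversal ambiguity.

*Distances* are two-point Kosambi along the final order:
d = 25·ln((1+2r)/(1−2r)) cM. An adjacent r̂ of exactly 0.5 is rejected — it
means unlinked bins ended up adjacent, a grouping/ordering failure — except
in the subsampling inflation estimator, which clips r̂ at 0.499 so a rare
saturated estimate cannot abort a Monte-Carlo round.

Because gametes are simulated without interference but mapped with Kosambi
(which assumes moderate interference), recovered lengths are biased slightly
short: ≈1.2% per 1.25 cM interval at n = 800. Tests therefore assert
recovered lengths only within 15% of the true length, while marker *order*
is asserted tightly (Kendall τ ≥ 0.99 per linkage group, up to whole-LG
reversal).

## Family QC

Diploid-coded calls (haploid tissue genotyped under a diploid model so
contamination is visible) are collapsed: heterozygotes become missing, and
the per-sample heterozygous fraction — measured over non-missing calls
*before* collapse — estimates the per-call contamination rate. Samples are
excluded when heterozygosity exceeds 10% or missingness 20%; comparisons are
strict (a sample exactly at a threshold is retained).

Family assignment runs PCA on the mean-imputed sample-by-marker matrix and
average-linkage hierarchical clustering on the leading 3 components, picking
k ∈ 2..max_k by the largest mean silhouette, or k = 1 when no k reaches
0.45. Few components and a demanding floor are deliberate: between-family
divergence (different maternal genotypes fix different alleles) concentrates
in the top components, whereas within-family variation is segregation noise
spread over many dimensions. The silhouette floor is meaningful only when
markers come from many independently segregating chromosomes; with one or
two chromosomes, linkage itself creates genuine low-dimensional structure
and the clustering can legitimately subdivide a family. All knobs are
arguments.

Per family, markers are recoded to the haploid testcross form: informative
iff both alleles are observed in the family (the mother was heterozygous);
segregation distortion is a χ² goodness-of-fit against 1:1 on non-missing
calls (df = 1), flagged at p < α/(number of testable bins) (Bonferroni).

## Consensus merging

Component maps are ranked by marker count and weighted (weights normalized
at merge). For each linkage group and each maximum interval K ∈ 1..10, the
consensus positions x minimize Σᵢ wᵢ Σₘ |xₘ − (cᵢₘ + sᵢ)| with a free shift
sᵢ per component (the top-ranked component's shift pinned to 0), subject to
xₐ ≤ x_b for every pair (a before b) within K intervals in any component.
Conflicting orders make the constraint digraph cyclic; edges contributed by
the lowest-priority component in each cycle are deleted (deterministic
tie-break) until the graph is acyclic — the deletion policy is this
package's choice, since only the component ranking is externally specified.
The LP is solved with HiGHS via scipy; consensus positions are reported
relative to their minimum. Per-component RMSE is computed over shared
markers with the fitted shift applied, and the candidate with the lowest
mean RMSE (ties to smaller K) becomes the consensus. Kendall τ is the
tie-corrected tau-b throughout: bins at identical cM make ties routine.

Linkage-group identity across components is established before merging by
shared-scaffold majority vote against the largest component's labels.

## Inflation estimate

Per linkage group: 100 rounds, each subsampling 100 bins without
replacement, ordering with 10 RECORD counts (no ripple) and summing Kosambi
distances. Reported are the mean and sample SD (n−1) of the round lengths,
inflation per bin = (observed − mean estimated)/total bins, and the implied
error load: errors per sample = inflation per bin × total bins / 100
(crossover-equivalents), errors per bin = inflation per bin × n samples /
100. Linkage-group assignments are reused across rounds rather than
regrouped — cheaper, and the estimate is a within-LG quantity. Subsampled
bins keep their full signatures; there is no re-binning.

The estimator needs the subsample to be genuinely smaller than the LG (a
subsample equal to the whole LG reproduces the observed length by
construction), so inflation experiments use 150-bin LGs with the standard
100-bin subsample.

## Assembly evaluation

Classification against the consensus map per scaffold with mapped markers:
single-marker; consistent (one LG, cM span ≤ 5 — a span of exactly 5 cM
counts as co-located, since splits are defined by *exceeding* 5 cM);
intra-split (one LG, span > 5); inter-split-k (k LGs). Splits are localized
to the interval between the two nearest disagreeing markers in scaffold bp
order — the tightest localizable interval — categorized as within-gene
(both flanking markers inside one gene model), interior-region (5′ and 3′
markers co-map while an interior block maps elsewhere), or between-genes,
and intersected with N-gap spans to decide whether the split sits at a
contig join. Component cross-support distinguishes splits reproduced by an
independent component map (supported) from consensus merge artifacts
(co-located in every component that holds ≥2 of the markers) and
unverifiable cases. Scaffold-length contrasts use Welch's two-sided t-test.

Coordinate conventions, stated once and tested: marker loci and gene models
are 1-based inclusive (GFF3-style); contig and gap spans are 0-based
half-open (internal interval arithmetic and AGP export handle the shift).

## Synteny comparison

The sequence-homology search is external; its output enters as a TSV of
(query marker, query scaffold, target marker, identity%, reciprocal-best)
rows, filtered at identity strictly greater than the threshold (default
95). Homology per query LG is the majority target LG (mirroring how such
dot-plots are colored); the homologous fraction is the share of comparisons
on majority pairs, invariant to relabeling either map. Per homologous pair,
order agreement is tau-b over the matched positions; off-diagonal
comparisons are annotated with whether the query scaffold is a known split
scaffold.

## Population-genetic statistics

Hard filters mirror a capture-panel workflow: bi-allelic SNPs inside
extended probe regions (probe ± 100 bp), QD > 5, MQ > 50, DP within a
cohort-scaled range, then samples with > 25% missing calls dropped; every
rule's removals are counted in a ledger. Diploid genotypes are treated as 2n
alleles of unknown phase: per site with allele count m and alt frequency p,
the unbiased diversity contribution is 2p(1−p)·m/(m−1); π per site divides
the summed contributions by callable sites (the defensible denominator when
none is externally specified — configurable). Tajima's D follows the
standard constants a₁..e₂ evaluated at the site-wise mean allele count over
segregating sites, undefined at S = 0. ZnS is the mean squared correlation
of dosage vectors over pairs of segregating sites computed on
pairwise-complete samples — composite LD, which equals haplotype r² for
phased or haploid data.

Unmapped probes take the consensus coordinates of the physically closest
(|Δbp|) mapped probe on the same scaffold; ties resolve to the smaller cM,
then lexicographic probe id. Sliding windows are half-open [k, k+10) cM
stepping by 1, extending to the last window whose start does not exceed the
LG end so probes near the end fall in as many windows as interior ones;
empty windows are reported with a missing mean rather than dropped.

## Coalescent null

The neutral panel generator is a single-population Kingman coalescent:
waiting time Exp(k(k−1)/2) at k lineages (time in 2N generations), mutations
Poisson(θ/2 × branch length) per branch under infinite sites, one new site
per mutation at a uniform position. Calibration checks: E[pairwise
differences] = θ at n = 2; E[S] = θ·a₁(n); mean Tajima's D over ≥2,000
panels within [−0.15, 0.05] (D has a small finite-sample negative bias).
A 20,000-replicate calibration of E[S] at n = 20, θ = 5 sits within one
standard error of the expectation.

## What the synthetic data do not emulate

No sequence-level simulation (no reads, bases, or capture efficiency); no
crossover interference; error is a symmetric allele flip (no allele-specific
dropout); families share one marker panel; the diversity panel is a single
panmictic population with no structure, selection or recombination within
probes. Passing tests therefore demonstrate algorithmic correctness and the
direction/magnitude of method-level effects (inflation, chimera detection),
not robustness to every artifact of real capture data.

## Problem sizes and numerical choices

Test and acceptance runs use: order recovery 12 chromosomes × 80 bins at
n = 800 error-free; inflation 12 × 150 bins at n = 300 (error-free control
vs ε = 0.01); chimera detection 12 chromosomes × 250 markers at 0.2 cM
spacing, 500 drawn scaffolds with a truncated-geometric 1–11
markers-per-scaffold distribution and 10% planted inter-chimeras at n = 400
(the dense spacing keeps true scaffold spans ≈2 cM, far from the 5 cM split
threshold, so false positives measure method error rather than design
leakage); coalescent calibration 2,000 panels. Every stochastic stage takes
an explicit seed and is byte-reproducible; Monte-Carlo assertions use 3-SE
(or stated) bands. LP tolerances are HiGHS defaults; ordering tie-breaks are
first-best under a seeded sequence, making all outputs deterministic given
seeds.
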