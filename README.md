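# megamap

Haploid linkage mapping for conifer megagametophyte panels, and everything a
dense genetic map is good for afterwards: merging per-family component maps
into a consensus map, quantifying genotyping-error map inflation, flagging
chimeric assembly scaffolds, comparing maps between species, and anchoring
population-genetic scans to centiMorgan coordinates.

## Why haploid megagametophytes

In conifers the megagametophyte — the maternal nutritive tissue of the seed —
is haploid and derives from the same meiosis as the egg cell, so every seed
is a directly observable gamete of the mother tree. A panel of genotyped
megagametophytes is an open-pollinated testcross: each marker heterozygous in
the mother segregates 1:1, and recombination fractions can be read off as
simple mismatch counts. That makes ultra-dense maps feasible in species such
as Norway spruce (*Picea abies*), whose ~20 Gbp genome is assembled into
millions of short scaffolds: anchoring those scaffolds onto the 12 linkage
groups is one of the few ways to see chromosome-scale organization, and
scaffolds whose markers map to two different places expose mis-joins in the
assembly.

## The methods in brief

* **Two-point estimation.** For haploid markers with unknown phase, the
  recombinant count over n pairwise-complete gametes with k mismatches is
  k' = min(k, n − k); r̂ = k'/n, and the linkage LOD is
  `LOD = k'·log10(2r̂) + (n − k')·log10(2(1 − r̂))` (= n·log10 2 at r̂ = 0).
* **Binning and grouping.** Markers with identical segregation signatures are
  binned (they cannot be recombinationally separated); bins join a linkage
  group when LOD ≥ 8 and r̂ ≤ 0.35, by transitive closure.
* **Ordering.** RECORD: repeated greedy insertion minimizing COUNT, the total
  number of observed recombination events between adjacent bins, followed by
  a sliding-window "ripple" refinement that only accepts strict COUNT
  improvements.
* **Distances.** Kosambi map function, d = 25·ln((1+2r)/(1−2r)) cM.
* **Consensus.** Component maps are merged per linkage group by linear
  programming: minimize the weighted sum of absolute deviations from each
  (shifted) component, subject to ordinal constraints within a maximum
  interval K; the K ∈ 1..10 candidate with the lowest mean RMSE wins.
* **Inflation.** Each genotyping error inflates the map; re-estimating LG
  lengths from random 100-bin subsamples gives a density-independent
  baseline, and (observed − mean estimated)/bins is the inflation per bin.
* **Assembly evaluation.** A scaffold whose mapped markers sit on one LG
  within 5 cM is consistent; >5 cM apart is an intra-split and two or more
  LGs an inter-split — putative assembly errors, localized to the interval
  between the disagreeing markers and intersected with gene models and
  contig-join N-gaps.
* **Diversity scans.** Per probe region: segregating sites S, per-site π,
  Tajima's D, and Kelly's ZnS (mean pairwise r²), anchored to the consensus
  map and smoothed in 10 cM windows stepping by 1 cM.

A full synthetic-data layer (`megamap.simulate`) generates haploid families
with crossovers, genotyping error, missing data and diploid contamination,
artificial assemblies with planted chimeric scaffolds, and neutral coalescent
haplotype panels, so the entire pipeline is testable without external data.

## Worked example

```python
from megamap.simulate import evenly_spaced_true_map, simulate_haploid_family
from megamap.pipeline import build_component_map
from megamap.inflation import estimate_inflation

true_map = evenly_spaced_true_map(n_chromosomes=3, markers_per_chromosome=60,
                                  length_cM=100.0)
family = simulate_haploid_family(true_map, "fam1", n_samples=400,
                                 error_rate=0.01, seed=11)
component = build_component_map(family.genotypes, seed=12)
for lg_id, lg in component.maps.items():
    print(f"{lg_id}: {lg.n_bins} bins, {lg.length_cM:.1f} cM, COUNT={lg.count_score}")

report = estimate_inflation(component, n_rounds=100, n_bins=40, seed=13)
print(report[["lg_id", "observed_length_cM", "mean_estimated_length_cM",
              "inflation_per_bin_cM"]].round(2).to_string(index=False))
```

prints

```
LG01: 60 bins, 201.3 cM, COUNT=804
LG02: 60 bins, 212.7 cM, COUNT=849
LG03: 60 bins, 211.4 cM, COUNT=844
lg_id  observed_length_cM  mean_estimated_length_cM  inflation_per_bin_cM
 LG01              201.35                    160.03                  0.69
 LG02              212.68                    169.31                  0.72
 LG03              211.42                    166.38                  0.75
```

The three simulated 100 cM chromosomes come back as three linkage groups of
60 bins each, but at 1% genotyping error the observed map is roughly doubled
in length — exactly the inflation the subsampling estimate quantifies: about
0.7 cM of excess length per marker bin, which at this marker density implies
on the order of one genotyping error per bin (`implied_errors_per_bin` in the
full report). On error-free data the same estimate sits within Monte-Carlo
noise of zero.

A thin CLI mirrors the library: `megamap simulate | qc | map | consensus |
inflate | evaluate-assembly | compare-maps | popgen` exchange TSV/VCF files;
see `megamap --help`.

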