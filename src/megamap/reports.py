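"""Accounting report generators, plus the bundled Norway spruce summaries.

The generators are plain arithmetic over summary tables — column totals,
subsampling-inflation ratios, and the split-scaffold percentage identities
over the mapped / multi-marker denominators.  They run on any table with
the documented columns; the package bundles, as data, the published
per-LG summaries of the Norway spruce (Picea abies) ultra-dense haploid
consensus map so the accounting can be reproduced without external files.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files("megamap") / "data"


def load_component_map_sizes() -> pd.DataFrame:
    """Published per-LG component/consensus map sizes (markers, bins, cM)."""
    with resources.as_file(_DATA / "picea_abies_component_maps.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_inflation_summary() -> pd.DataFrame:
    """Published per-LG observed and subsample-estimated map lengths."""
    with resources.as_file(_DATA / "picea_abies_inflation.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_split_counts() -> dict:
    """Published split-scaffold and gene-model counts."""
    with resources.as_file(_DATA / "picea_abies_split_counts.json") as p:
        return json.loads(p.read_text())


def component_totals(sizes: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster totals of markers, bins and map length."""
    return (
        sizes.groupby("cluster")
        .agg(
            markers=("markers", "sum"),
            bins=("bins", "sum"),
            length_cM=("length_cM", "sum"),
            max_gap_cM=("max_gap_cM", "max"),
            n_lgs=("lg", "count"),
        )
        .reset_index()
    )


def inflation_accounting(
    inflation: pd.DataFrame, sizes: pd.DataFrame
) -> pd.DataFrame:
    """Inflation per marker bin from observed vs subsample-estimated lengths.

    inflation_per_bin = (observed - mean estimated) / bins for each LG, and
    for the per-cluster totals row (sums of each column).
    """
    merged = inflation.merge(
        sizes[["cluster", "lg", "bins"]], on=["cluster", "lg"], how="left"
    )
    merged["inflation_per_bin_cM"] = (
        merged["observed_length_cM"] - merged["mean_estimated_length_cM"]
    ) / merged["bins"]
    totals = (
        merged.groupby("cluster")
        .agg(
            observed_length_cM=("observed_length_cM", "sum"),
            mean_estimated_length_cM=("mean_estimated_length_cM", "sum"),
            bins=("bins", "sum"),
        )
        .reset_index()
        .assign(lg="Total")
    )
    totals["inflation_per_bin_cM"] = (
        totals["observed_length_cM"] - totals["mean_estimated_length_cM"]
    ) / totals["bins"]
    return pd.concat([merged, totals], ignore_index=True)


def split_accounting(counts: dict) -> dict[str, float]:
    """Percentage identities of the split-scaffold and synteny accounting."""
    pct = lambda a, b: 100.0 * a / b  # noqa: E731
    n_mapped = counts["mapped_scaffolds"]
    n_multi = counts["multi_marker_scaffolds"]
    out = {
        "pct_multi_marker_of_mapped": pct(n_multi, n_mapped),
        "pct_intra_of_mapped": pct(counts["intra_split_scaffolds"], n_mapped),
        "pct_intra_of_multi": pct(counts["intra_split_scaffolds"], n_multi),
        "pct_inter_of_mapped": pct(counts["inter_split_scaffolds"], n_mapped),
        "pct_inter_of_multi": pct(counts["inter_split_scaffolds"], n_multi),
        "pct_splits_at_contig_joins": pct(
            counts["splits_at_contig_joins"], counts["splits_total"]
        ),
        "pct_gene_models_on_split_of_multi": pct(
            counts["gene_models_on_split"], counts["gene_models_on_multi_marker"]
        ),
        "pct_gene_models_internal_split_of_multi": pct(
            counts["gene_models_with_internal_split"],
            counts["gene_models_on_multi_marker"],
        ),
        "pct_glauca_homologous": pct(
            counts["glauca_homologous"], counts["glauca_comparisons"]
        ),
        "pct_abies_array_homologous": pct(
            counts["abies_array_comparisons"] - counts["abies_array_nonhomologous"],
            counts["abies_array_comparisons"],
        ),
    }
    return out
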