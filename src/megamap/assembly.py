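"""Assembly-accuracy evaluation against the consensus genetic map.

Scaffolds carrying two or more mapped markers test the assembly's joining
decisions: if a scaffold's markers map to different linkage groups
(inter-split) or more than the split threshold apart on one LG
(intra-split), some join inside the scaffold is a putative assembly error.
Splits are localized to the bp interval between the nearest disagreeing
markers and intersected with gene models and contig-join N-gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SPLIT_THRESHOLD_CM = 5.0


def classify_scaffolds(
    consensus: pd.DataFrame,
    marker_meta: pd.DataFrame,
    threshold_cM: float = SPLIT_THRESHOLD_CM,
) -> pd.DataFrame:
    """Classify every scaffold with mapped markers.

    ``consensus`` columns: marker_id, lg_id, cM.  ``marker_meta`` columns:
    marker_id, scaffold_id, bp.  Classes: single-marker; consistent (one
    LG, span <= threshold — markers sitting exactly on the threshold count
    as co-located); intra-split (one LG, span > threshold); inter-split-k
    (k = number of LGs, 2 or 3+).
    """
    merged = consensus.merge(marker_meta, on="marker_id", how="left")
    unplaced = merged["scaffold_id"].isna().sum()
    if unplaced:
        import logging

        logging.getLogger(__name__).info("%d mapped markers lack scaffold metadata", unplaced)
    merged = merged.dropna(subset=["scaffold_id"])

    rows = []
    for sid, grp in merged.groupby("scaffold_id", sort=True):
        lgs = sorted(grp["lg_id"].unique())
        spans = grp.groupby("lg_id")["cM"].agg(lambda s: s.max() - s.min())
        span = float(spans.max())
        if len(grp) == 1:
            cls = "single-marker"
        elif len(lgs) == 1:
            cls = "consistent" if span <= threshold_cM else "intra-split"
        else:
            k = min(len(lgs), 3)
            cls = f"inter-split-{k}"
        rows.append(
            {
                "scaffold_id": sid,
                "n_markers": len(grp),
                "lg_set": ",".join(lgs),
                "n_lgs": len(lgs),
                "cM_span": span,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def classification_summary(classification: pd.DataFrame) -> dict[str, float]:
    """Counts and percentages over mapped / multi-marker scaffold denominators."""
    n_mapped = len(classification)
    multi = classification[classification["class"] != "single-marker"]
    n_multi = len(multi)
    n_intra = int((classification["class"] == "intra-split").sum())
    n_inter = int(classification["class"].str.startswith("inter-split").sum())
    n_split = n_intra + n_inter
    pct = lambda a, b: 100.0 * a / b if b else float("nan")  # noqa: E731
    return {
        "n_mapped_scaffolds": n_mapped,
        "n_multi_marker_scaffolds": n_multi,
        "pct_multi_marker": pct(n_multi, n_mapped),
        "n_intra_split": n_intra,
        "n_inter_split": n_inter,
        "n_split": n_split,
        "pct_intra_of_mapped": pct(n_intra, n_mapped),
        "pct_intra_of_multi": pct(n_intra, n_multi),
        "pct_inter_of_mapped": pct(n_inter, n_mapped),
        "pct_inter_of_multi": pct(n_inter, n_multi),
        "pct_split_of_multi": pct(n_split, n_multi),
    }


def crosscheck_component_support(
    splits: pd.DataFrame,
    component_frames: dict[str, pd.DataFrame],
    marker_meta: pd.DataFrame,
    threshold_cM: float = SPLIT_THRESHOLD_CM,
) -> pd.DataFrame:
    """Check whether any component map independently reproduces each split.

    supported — some component holds >= 2 of the scaffold's markers and
    itself splits them (different LGs or same-LG span > threshold);
    artifact — at least one component co-locates >= 2 of them and none
    reproduces the split (the consensus split is a merge artifact);
    unverifiable — no component contains >= 2 of the scaffold's markers.
    """
    scaff_of = marker_meta.set_index("marker_id")["scaffold_id"]
    rows = []
    for sid in splits["scaffold_id"]:
        markers = set(scaff_of[scaff_of == sid].index)
        verdict = "unverifiable"
        any_coloc = False
        for fam, frame in component_frames.items():
            sub = frame[frame["marker_id"].isin(markers)]
            if len(sub) < 2:
                continue
            lgs = sub["lg_id"].unique()
            span = sub.groupby("lg_id")["cM"].agg(lambda s: s.max() - s.min()).max()
            if len(lgs) > 1 or span > threshold_cM:
                verdict = "supported"
                break
            any_coloc = True
        if verdict != "supported" and any_coloc:
            verdict = "artifact"
        rows.append({"scaffold_id": sid, "component_support": verdict})
    return pd.DataFrame(rows)


@dataclass
class SplitAnnotation:
    scaffold_id: str
    bp_left: int  # 1-based position of the last marker before the split
    bp_right: int  # 1-based position of the first marker after it
    category: str  # between-genes / within-gene / interior-region
    at_contig_join: bool
    lg_left: str
    lg_right: str


def annotate_splits(
    splits: pd.DataFrame,
    consensus: pd.DataFrame,
    marker_meta: pd.DataFrame,
    gene_models: pd.DataFrame,
    gap_spans: pd.DataFrame,
    threshold_cM: float = SPLIT_THRESHOLD_CM,
) -> pd.DataFrame:
    """Localize each split to the interval between its flanking markers.

    Markers are walked in scaffold bp order; every adjacent pair that
    disagrees in map position (different LG, or cM gap > threshold on one
    LG) is one split.  A split is ``within-gene`` when both flanking
    markers fall inside a single gene model, ``interior-region`` when the
    scaffold's 5' and 3' markers co-map while an interior block maps
    elsewhere, otherwise ``between-genes``.  ``at_contig_join`` records
    whether the inter-marker interval overlaps an N-gap (contig join).
    """
    pos = consensus.set_index("marker_id")
    meta = marker_meta.set_index("marker_id")
    genes_by_scaffold = dict(tuple(gene_models.groupby("scaffold_id")))
    gaps_by_scaffold = dict(tuple(gap_spans.groupby("scaffold_id")))

    out: list[SplitAnnotation] = []
    for sid in splits["scaffold_id"]:
        markers = meta[meta["scaffold_id"] == sid].copy()
        markers = markers.join(pos, how="inner").sort_values("bp")
        if markers["bp"].isna().any() or len(markers) < 2:
            continue
        # side label per marker: LG, refined by >threshold cM clustering within LG
        sides = []
        for _, row in markers.iterrows():
            sides.append((row["lg_id"], row["cM"]))
        side_ids = [0]
        for i in range(1, len(sides)):
            same = sides[i][0] == sides[i - 1][0] and abs(sides[i][1] - sides[i - 1][1]) <= threshold_cM
            side_ids.append(side_ids[-1] if same else side_ids[-1] + 1)
        markers["side"] = side_ids

        # does the scaffold return to its starting side? (interior-region pattern)
        first_key = sides[0][0]
        last_key = sides[-1][0]
        returning = (
            first_key == last_key
            and abs(sides[0][1] - sides[-1][1]) <= threshold_cM
            and markers["side"].nunique() > 1
        )

        bps = markers["bp"].to_numpy()
        lgs = markers["lg_id"].to_numpy()
        for i in range(len(markers) - 1):
            if side_ids[i] == side_ids[i + 1]:
                continue
            bp_l, bp_r = int(bps[i]), int(bps[i + 1])
            genes = genes_by_scaffold.get(sid, pd.DataFrame(columns=["start_bp", "end_bp"]))
            within = (
                (genes["start_bp"] <= bp_l) & (genes["end_bp"] >= bp_r)
            ).any() if len(genes) else False
            if within:
                cat = "within-gene"
            elif returning:
                cat = "interior-region"
            else:
                cat = "between-genes"
            gaps = gaps_by_scaffold.get(sid, pd.DataFrame(columns=["start", "end"]))
            # interval strictly between the flanking markers, 0-based half-open
            lo, hi = bp_l, bp_r - 1
            at_join = bool(((gaps["start"] < hi) & (gaps["end"] > lo)).any()) if len(gaps) else False
            out.append(
                SplitAnnotation(sid, bp_l, bp_r, cat, at_join, str(lgs[i]), str(lgs[i + 1]))
            )
    return pd.DataFrame([vars(a) for a in out])


@dataclass
class LengthComparison:
    t: float
    df: float
    p_value: float
    median_a: float
    median_b: float


def compare_scaffold_lengths(
    lengths_a: np.ndarray | pd.Series,
    lengths_b: np.ndarray | pd.Series,
) -> LengthComparison:
    """Welch two-sample t-test (two-sided, unequal variances) on lengths."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return LengthComparison(
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        float(np.median(a)),
        float(np.median(b)),
    )
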