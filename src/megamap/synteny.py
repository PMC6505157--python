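"""Inter-map synteny comparison through a marker-correspondence table.

The sequence-homology search producing the correspondences (e.g. reciprocal
best tblastn hits between array probe sequences and assembly scaffolds) is
external; this module consumes its tabular output, assigns linkage-group
homology by majority vote and quantifies per-LG order agreement with
Kendall's tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consensus import OrderCorrelation, order_correlation

CORRESPONDENCE_COLUMNS = (
    "query_marker_id",
    "query_scaffold_id",
    "target_marker_id",
    "identity_pct",
    "reciprocal_best",
)


def load_correspondence(
    table: pd.DataFrame | str,
    min_identity: float = 95.0,
    reciprocal_only: bool = True,
) -> pd.DataFrame:
    """Validate and identity-filter a correspondence table (strict > threshold)."""
    df = pd.read_csv(table, sep="\t") if isinstance(table, str) else table.copy()
    missing = [c for c in CORRESPONDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"correspondence table lacks columns {missing}")
    if ((df["identity_pct"] < 0) | (df["identity_pct"] > 100)).any():
        raise ValueError("identity_pct outside [0, 100]")
    df = df[df["identity_pct"] > min_identity]
    if reciprocal_only:
        df = df[df["reciprocal_best"].astype(bool)]
    return df.reset_index(drop=True)


@dataclass
class LGCorrespondence:
    contingency: pd.DataFrame  # lg_a x lg_b counts
    majority: dict[str, str]  # lg_a -> homologous lg_b
    homologous_fraction: float
    n_comparisons: int
    n_dropped: int
    off_diagonal: pd.DataFrame = field(default_factory=pd.DataFrame)


def lg_correspondence(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    table: pd.DataFrame,
    split_scaffolds: set[str] | None = None,
) -> LGCorrespondence:
    """LG homology between two maps from shared-marker comparisons.

    ``map_a``/``map_b`` columns: marker_id, lg_id, cM.  Each table row whose
    query maps in A and target maps in B becomes one comparison; homology
    per A-side LG is the majority B-side LG, and the homologous fraction is
    the share of comparisons landing on a majority pair.  Off-diagonal
    comparisons are annotated with whether their query scaffold is a known
    split scaffold.
    """
    a = map_a.set_index("marker_id")
    b = map_b.set_index("marker_id")
    joined = table.copy()
    joined["lg_a"] = joined["query_marker_id"].map(a["lg_id"])
    joined["lg_b"] = joined["target_marker_id"].map(b["lg_id"])
    dropped = joined["lg_a"].isna() | joined["lg_b"].isna()
    comp = joined[~dropped]
    if comp.empty:
        raise ValueError("no usable comparisons after identity filtering and map join")

    tab = pd.crosstab(comp["lg_a"], comp["lg_b"])
    majority = {lg: tab.loc[lg].idxmax() for lg in tab.index}
    on_major = sum(
        int(tab.loc[lg, mate]) for lg, mate in majority.items() if mate in tab.columns
    )
    off = comp[
        [m != majority[lg] for lg, m in zip(comp["lg_a"], comp["lg_b"])]
    ].copy()
    if split_scaffolds is not None:
        off["query_on_split_scaffold"] = off["query_scaffold_id"].isin(split_scaffolds)
    return LGCorrespondence(
        tab, majority, on_major / len(comp), len(comp), int(dropped.sum()), off
    )


def marker_order_tau(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    table: pd.DataFrame,
) -> list[OrderCorrelation]:
    """Kendall tau-b of marker order per homologous LG pair.

    Comparisons are restricted to the majority (homologous) LG pair; the
    tau for pair (lg_a, lg_b) is computed over the matched positions of the
    correspondences on that pair.
    """
    corr = lg_correspondence(map_a, map_b, table)
    a = map_a.set_index("marker_id")
    b = map_b.set_index("marker_id")
    joined = table.copy()
    joined["lg_a"] = joined["query_marker_id"].map(a["lg_id"])
    joined["lg_b"] = joined["target_marker_id"].map(b["lg_id"])
    joined["cM_a"] = joined["query_marker_id"].map(a["cM"])
    joined["cM_b"] = joined["target_marker_id"].map(b["cM"])
    out = []
    for lg_a, lg_b in sorted(corr.majority.items()):
        sub = joined[(joined["lg_a"] == lg_a) & (joined["lg_b"] == lg_b)]
        if len(sub) < 2:
            out.append(OrderCorrelation(f"{lg_a}~{lg_b}", None, len(sub)))
            continue
        pos_a = pd.Series(sub["cM_a"].to_numpy(), index=range(len(sub)))
        pos_b = pd.Series(sub["cM_b"].to_numpy(), index=range(len(sub)))
        out.append(order_correlation(pos_a, pos_b, f"{lg_a}~{lg_b}"))
    return out
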