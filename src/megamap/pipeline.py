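"""End-to-end drivers: genotype matrix -> ordered per-LG component map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HaploidGenotypeMatrix
from .linkage import (
    MarkerBin,
    OrderedMap,
    bin_markers,
    bin_signature_matrix,
    group_markers,
    kosambi_map,
    order_record,
    recombinant_counts,
    ripple_window,
)


@dataclass
class ComponentMapResult:
    """Per-family mapping result: ordered LGs plus leftover singleton bins."""

    family_id: str
    maps: dict[str, OrderedMap]
    singleton_bins: list[MarkerBin]
    n_samples: int

    @property
    def n_bins_mapped(self) -> int:
        return sum(m.n_bins for m in self.maps.values())

    def total_length_cM(self) -> float:
        return float(sum(m.length_cM for m in self.maps.values()))


def build_component_map(
    matrix: HaploidGenotypeMatrix,
    family_id: str = "fam",
    lod_min: float = 8.0,
    rf_max: float = 0.35,
    n_counts: int = 16,
    window: int = 10,
    seed: int = 0,
    ripple: bool = True,
    r_clip: float | None = None,
) -> ComponentMapResult:
    """Bin, group, RECORD-order, ripple and Kosambi-map one family's markers.

    Linkage groups are labeled LG01, LG02, ... in decreasing bin count.
    """
    bins = bin_markers(matrix)
    part = group_markers(bins, lod_min=lod_min, rf_max=rf_max)
    maps: dict[str, OrderedMap] = {}
    for gi, group in enumerate(part.groups):
        gbins = [bins[i] for i in group]
        cnt, n_mat = recombinant_counts(bin_signature_matrix(gbins))
        om = order_record(gbins, n_counts=n_counts, seed=seed + gi, cnt=cnt)
        if ripple and len(gbins) > 2:
            om = ripple_window(om, window=window, step=1, seed=seed + 10_000 + gi, cnt=cnt)
        om = kosambi_map(om, r_clip=r_clip, cnt=cnt, n_mat=n_mat)
        om.lg_id = f"LG{gi + 1:02d}"
        maps[om.lg_id] = om
    singles = [bins[i] for i in part.singletons]
    return ComponentMapResult(family_id, maps, singles, matrix.n_samples)


def component_marker_frame(
    result: ComponentMapResult,
    marker_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format map: one row per member marker with (lg_id, cM, bin_id).

    All markers of a bin inherit the bin's cM position.  If ``marker_meta``
    is given (marker_id, scaffold_id, bp), it is joined on.
    """
    rows = []
    for lg_id, om in result.maps.items():
        for rank, bi in enumerate(om.order):
            b = om.bins[bi]
            for mid in b.marker_ids:
                rows.append((mid, lg_id, float(om.positions_cM[rank]), b.bin_id, rank))
    frame = pd.DataFrame(rows, columns=["marker_id", "lg_id", "cM", "bin_id", "bin_rank"])
    if marker_meta is not None:
        frame = frame.merge(
            marker_meta[["marker_id", "scaffold_id", "bp"]], on="marker_id", how="left"
        )
    return frame.sort_values(["lg_id", "cM", "marker_id"]).reset_index(drop=True)
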