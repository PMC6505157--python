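"""Consensus-map construction by linear programming.

Component maps built from independent families are merged per linkage
group: the consensus position vector minimizes the weighted sum of absolute
deviations from each (shifted) component map, subject to ordinal
constraints that preserve each component's marker order within a maximum
interval K.  When components disagree the conflicting ordinal constraints
form directed cycles; constraints contributed by lower-ranked components
(fewer markers) are deleted until the constraint graph is acyclic.  The
procedure is run for K = 1..10 and the candidate with the lowest mean RMSE
against the components is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix
from scipy.stats import kendalltau

from .pipeline import ComponentMapResult, component_marker_frame


@dataclass
class ComponentMap:
    """A component map reduced to per-marker (lg_id, cM) plus a merge weight."""

    family_id: str
    frame: pd.DataFrame  # columns: marker_id, lg_id, cM
    weight: float

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def lg_positions(self, lg_id: str) -> pd.Series:
        sub = self.frame[self.frame["lg_id"] == lg_id]
        return pd.Series(sub["cM"].to_numpy(), index=sub["marker_id"].to_numpy())


def component_from_result(
    result: ComponentMapResult, weight: float, marker_meta: pd.DataFrame | None = None
) -> ComponentMap:
    frame = component_marker_frame(result, marker_meta)
    return ComponentMap(result.family_id, frame[["marker_id", "lg_id", "cM"]], weight)


def align_component_lgs(
    components: list[ComponentMap], marker_meta: pd.DataFrame
) -> list[ComponentMap]:
    """Harmonize LG labels across components by shared-scaffold majority vote.

    The component with the most markers provides the reference labels; each
    other component's LG is renamed to the reference LG with which it shares
    the most scaffolds (ties broken by reference LG label).
    """
    scaff = marker_meta.set_index("marker_id")["scaffold_id"]
    ranked = sorted(components, key=lambda c: -c.n_markers)
    ref = ranked[0]
    ref_lg_by_scaffold = (
        ref.frame.assign(scaffold_id=ref.frame["marker_id"].map(scaff))
        .groupby("scaffold_id")["lg_id"]
        .agg(lambda s: s.mode().iloc[0])
    )
    out = [ComponentMap(ref.family_id, ref.frame.copy(), ref.weight)]
    for comp in ranked[1:]:
        fr = comp.frame.assign(scaffold_id=comp.frame["marker_id"].map(scaff))
        fr["ref_lg"] = fr["scaffold_id"].map(ref_lg_by_scaffold)
        mapping: dict[str, str] = {}
        for lg, grp in fr.groupby("lg_id"):
            votes = grp["ref_lg"].dropna().value_counts()
            mapping[lg] = votes.index[0] if len(votes) else lg
        renamed = comp.frame.copy()
        renamed["lg_id"] = renamed["lg_id"].map(mapping)
        out.append(ComponentMap(comp.family_id, renamed, comp.weight))
    return out


@dataclass
class ConsensusCandidate:
    lg_id: str
    K: int
    positions: pd.Series  # marker_id -> consensus cM
    shifts: dict[str, float]
    rmse_per_component: dict[str, float]
    mean_rmse: float
    n_deleted_constraints: int
    failed: bool = False


@dataclass
class ConsensusMap:
    lg_id: str
    positions: pd.Series
    K: int
    mean_rmse: float
    candidates: list[ConsensusCandidate] = field(default_factory=list)

    @property
    def length_cM(self) -> float:
        return float(self.positions.max()) if len(self.positions) else 0.0


def _ordinal_edges(pos: pd.Series, K: int) -> list[tuple[str, str]]:
    ordered = pos.sort_values(kind="mergesort").index.to_list()
    edges = []
    for i, u in enumerate(ordered):
        for j in range(i + 1, min(i + K + 1, len(ordered))):
            edges.append((u, ordered[j]))
    return edges


def build_consensus_candidates(
    components: list[ComponentMap],
    lg_id: str,
    K_range: range = range(1, 11),
    max_constraint_deletions: int | None = None,
) -> list[ConsensusCandidate]:
    """LPmerge-style consensus candidates for one LG, one per max interval K."""
    comps = [c for c in components if (c.frame["lg_id"] == lg_id).any()]
    if not comps:
        raise ValueError(f"no component covers {lg_id}")
    comps = sorted(comps, key=lambda c: (-len(c.lg_positions(lg_id)), c.family_id))
    w_total = sum(c.weight for c in comps)
    weights = [c.weight / w_total for c in comps]
    positions = [c.lg_positions(lg_id) for c in comps]
    union = sorted(set().union(*[set(p.index) for p in positions]))
    x_idx = {m: i for i, m in enumerate(union)}

    out: list[ConsensusCandidate] = []
    for K in K_range:
        graph = nx.DiGraph()
        graph.add_nodes_from(union)
        for rank, pos in enumerate(positions):
            for u, v in _ordinal_edges(pos, K):
                if graph.has_edge(u, v):
                    graph[u][v]["rank"] = min(graph[u][v]["rank"], rank)
                else:
                    graph.add_edge(u, v, rank=rank)
        n_deleted = 0
        failed = False
        while True:
            try:
                cycle = nx.find_cycle(graph)
            except nx.NetworkXNoCycle:
                break
            # delete the worst-ranked (lowest-priority component) edge in the cycle
            u, v = max(
                ((u, v) for u, v, *_ in cycle),
                key=lambda e: (graph[e[0]][e[1]]["rank"], e),
            )
            graph.remove_edge(u, v)
            n_deleted += 1
            if max_constraint_deletions is not None and n_deleted > max_constraint_deletions:
                failed = True
                break
        if failed:
            out.append(
                ConsensusCandidate(lg_id, K, pd.Series(dtype=float), {}, {}, np.inf, n_deleted, True)
            )
            continue

        cand = _solve_lp(comps, weights, positions, union, x_idx, graph)
        if cand is None:
            out.append(
                ConsensusCandidate(lg_id, K, pd.Series(dtype=float), {}, {}, np.inf, n_deleted, True)
            )
            continue
        x, shifts = cand
        origin = x.min()
        x = x - origin  # translate so the consensus starts at 0
        shifts = shifts - origin
        rmse = {}
        for c, pos, s in zip(comps, positions, shifts):
            fit = x[pos.index.map(x_idx)] - (pos.to_numpy() + s)
            rmse[c.family_id] = float(np.sqrt(np.mean(fit**2)))
        series = pd.Series(x, index=union).sort_values(kind="mergesort")
        out.append(
            ConsensusCandidate(
                lg_id,
                K,
                series,
                {c.family_id: float(s) for c, s in zip(comps, shifts)},
                rmse,
                float(np.mean(list(rmse.values()))),
                n_deleted,
            )
        )
    return out


def _solve_lp(comps, weights, positions, union, x_idx, graph):
    """Solve min sum_i w_i sum_m |x_m - (c_im + s_i)| s.t. ordinal x_u <= x_v."""
    nU = len(union)
    nC = len(comps)
    n_dev = sum(len(p) for p in positions)
    # variable layout: [x (nU) | s_1..s_{C-1} (nC-1) | t (n_dev)]
    n_var = nU + (nC - 1) + n_dev
    cost = np.zeros(n_var)
    rows, cols, vals, b = [], [], [], []
    r = 0
    t0 = nU + (nC - 1)
    ti = t0
    for ci, (pos, w) in enumerate(zip(positions, weights)):
        for m, c_im in pos.items():
            cost[ti] = w
            # x_m - s_i - t <= c_im
            rows += [r, r]
            cols += [x_idx[m], ti]
            vals += [1.0, -1.0]
            if ci > 0:
                rows.append(r)
                cols.append(nU + ci - 1)
                vals.append(-1.0)
            b.append(c_im)
            r += 1
            # -x_m + s_i - t <= -c_im
            rows += [r, r]
            cols += [x_idx[m], ti]
            vals += [-1.0, -1.0]
            if ci > 0:
                rows.append(r)
                cols.append(nU + ci - 1)
                vals.append(1.0)
            b.append(-c_im)
            r += 1
            ti += 1
    for u, v in graph.edges:
        rows += [r, r]
        cols += [x_idx[u], x_idx[v]]
        vals += [1.0, -1.0]
        b.append(0.0)
        r += 1
    A = coo_matrix((vals, (rows, cols)), shape=(r, n_var)).tocsr()
    bounds = [(None, None)] * (nU + nC - 1) + [(0, None)] * n_dev
    res = linprog(cost, A_ub=A, b_ub=np.asarray(b), bounds=bounds, method="highs")
    if not res.success:
        return None
    x = res.x[:nU]
    shifts = np.concatenate([[0.0], res.x[nU : nU + nC - 1]])
    return x, shifts


def select_consensus(candidates: list[ConsensusCandidate]) -> ConsensusMap:
    """Lowest mean RMSE wins; ties go to the smallest max interval K."""
    ok = [c for c in candidates if not c.failed]
    if not ok:
        raise ValueError("all consensus candidates failed")
    best = min(ok, key=lambda c: (c.mean_rmse, c.K))
    return ConsensusMap(best.lg_id, best.positions, best.K, best.mean_rmse, candidates)


def build_consensus(
    components: list[ComponentMap],
    K_range: range = range(1, 11),
    max_constraint_deletions: int | None = None,
) -> dict[str, ConsensusMap]:
    """Consensus map per LG over the union of component LG labels."""
    lgs = sorted(set().union(*[set(c.frame["lg_id"]) for c in components]))
    out = {}
    for lg in lgs:
        cands = build_consensus_candidates(components, lg, K_range, max_constraint_deletions)
        out[lg] = select_consensus(cands)
    return out


def consensus_frame(consensus: dict[str, ConsensusMap]) -> pd.DataFrame:
    rows = [
        (m, lg, float(cm.positions[m]))
        for lg, cm in consensus.items()
        for m in cm.positions.index
    ]
    return pd.DataFrame(rows, columns=["marker_id", "lg_id", "cM"])


@dataclass
class OrderCorrelation:
    lg_id: str
    tau: float | None
    n_shared: int


def order_correlation(
    pos_a: pd.Series, pos_b: pd.Series, lg_id: str = ""
) -> OrderCorrelation:
    """Kendall tau-b between two maps' positions over shared markers.

    Tau-b is tie-corrected: markers binned at identical cM are common in
    dense haploid maps, so ties are the rule rather than the exception.
    """
    shared = pos_a.index.intersection(pos_b.index)
    if len(shared) < 2:
        return OrderCorrelation(lg_id, None, len(shared))
    tau, _ = kendalltau(pos_a[shared].to_numpy(), pos_b[shared].to_numpy())
    return OrderCorrelation(lg_id, float(tau), len(shared))
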