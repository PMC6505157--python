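"""Linkage-map construction for haploid testcross data.

The chain is: identical-signature binning -> pairwise recombination
fraction / LOD estimation -> linkage-group formation (transitive closure at
LOD >= 8, r <= 0.35) -> RECORD ordering (greedy insertion minimizing the
COUNT of adjacent recombination events, repeated over random insertion
sequences) -> sliding-window ripple refinement -> Kosambi centiMorgan
assignment.

For haploid 0/1 calls with unknown phase, the recombinant count between two
markers over the n pairwise-complete samples with k mismatches is
min(k, n - k): the phase (coupling/repulsion) is chosen to minimize
recombination.  All pairwise quantities derive from that primitive,
computed for whole marker sets with masked matrix products.
"""

from __future__ import annotations

import collections
import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import HaploidGenotypeMatrix

LOG10_2 = math.log10(2.0)


# ---------------------------------------------------------------------------
# pairwise primitives
# ---------------------------------------------------------------------------


def pairwise_mismatch_counts(signatures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mismatches and pairwise-complete sample counts for all marker pairs.

    ``signatures`` is markers x samples with values in {0, 1, -1}.  Returns
    (k, n): k[i, j] = observed allele mismatches between i and j over the
    n[i, j] samples where both are non-missing.
    """
    sig = np.asarray(signatures)
    present = (sig != -1).astype(np.float32)
    alt = (sig == 1).astype(np.float32)
    ref = present - alt
    k = alt @ ref.T + ref @ alt.T
    n = present @ present.T
    return np.rint(k).astype(np.int64), np.rint(n).astype(np.int64)


def recombinant_counts(signatures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phase-aligned recombinant counts: min(k, n - k) for every pair."""
    k, n = pairwise_mismatch_counts(signatures)
    return np.minimum(k, n - k), n


def _lod(kr: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD of linkage at r-hat = kr/n vs free recombination (r = 0.5)."""
    kr = np.asarray(kr, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, kr / n, np.nan)
        lod = kr * np.log10(2.0 * r) + (n - kr) * np.log10(2.0 * (1.0 - r))
    lod = np.where(r == 0.0, n * LOG10_2, lod)
    lod = np.where(r == 0.5, 0.0, lod)
    return lod


@dataclass(frozen=True)
class TwoPointEstimate:
    r: float
    lod: float
    n_informative: int
    phase: str  # coupling / repulsion
    recombinants: int


def estimate_rf(sig_a: np.ndarray, sig_b: np.ndarray) -> TwoPointEstimate:
    """Two-point recombination fraction and LOD for one haploid marker pair."""
    a = np.asarray(sig_a)
    b = np.asarray(sig_b)
    both = (a != -1) & (b != -1)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no pairwise-complete samples: estimate undefined")
    k = int((a[both] != b[both]).sum())
    kr = min(k, n - k)
    phase = "coupling" if k <= n - k else "repulsion"
    r = kr / n
    lod = float(_lod(np.array(kr), np.array(n)))
    return TwoPointEstimate(r, lod, n, phase, kr)


# ---------------------------------------------------------------------------
# marker bins
# ---------------------------------------------------------------------------


@dataclass
class MarkerBin:
    bin_id: str
    marker_ids: list[str]
    representative: str
    signature: np.ndarray  # representative's allele vector

    @property
    def size(self) -> int:
        return len(self.marker_ids)


def bin_markers(matrix: HaploidGenotypeMatrix) -> list[MarkerBin]:
    """Partition markers into bins of identical segregation signatures.

    Exact mode: two markers share a bin iff their rows are identical,
    including the missing pattern.  The representative is the member with
    the fewest missing calls (a no-op under exactness, but kept so relaxed
    binning rules can slot in); ties break lexicographically by marker_id.
    Bins are returned sorted by bin_id (= representative marker_id).
    """
    if matrix.n_markers == 0:
        raise ValueError("no markers to bin")
    _, inverse = np.unique(matrix.alleles, axis=0, return_inverse=True)
    ids = matrix.marker_ids
    n_missing = (matrix.alleles == -1).sum(axis=1)
    bins: list[MarkerBin] = []
    members: dict[int, list[int]] = collections.defaultdict(list)
    for row, g in enumerate(inverse):
        members[int(g)].append(row)
    for g, rows in members.items():
        rows_sorted = sorted(rows, key=lambda r: (n_missing[r], ids[r]))
        rep = rows_sorted[0]
        bins.append(
            MarkerBin(
                bin_id=str(ids[rep]),
                marker_ids=sorted(str(ids[r]) for r in rows),
                representative=str(ids[rep]),
                signature=matrix.alleles[rep].copy(),
            )
        )
    bins.sort(key=lambda b: b.bin_id)
    return bins


def bin_signature_matrix(bins: list[MarkerBin]) -> np.ndarray:
    return np.stack([b.signature for b in bins], axis=0)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroupPartition:
    groups: list[list[int]]  # bin indices, largest group first
    singletons: list[int]
    lod_min: float
    rf_max: float


def group_markers(
    bins: list[MarkerBin],
    lod_min: float = 8.0,
    rf_max: float = 0.35,
) -> LinkageGroupPartition:
    """Linkage groups = connected components of the (LOD, r) threshold graph.

    An edge joins two bins when LOD >= lod_min AND r <= rf_max; grouping is
    by transitive closure, so a chain a-b-c lands in one group even if a-c
    alone would not qualify.  Single-bin components are reported separately.
    """
    sig = bin_signature_matrix(bins)
    kr, n = recombinant_counts(sig)
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, kr / np.maximum(n, 1), np.nan)
    lod = _lod(kr, n)
    adj = (lod >= lod_min) & (r <= rf_max) & (n > 0)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    groups = [v for v in comps.values() if len(v) > 1]
    singles = [v[0] for v in comps.values() if len(v) == 1]
    groups.sort(key=lambda g: (-len(g), bins[g[0]].bin_id))
    singles.sort(key=lambda i: bins[i].bin_id)
    return LinkageGroupPartition(groups, singles, lod_min, rf_max)


# ---------------------------------------------------------------------------
# RECORD ordering
# ---------------------------------------------------------------------------


def order_count(order: np.ndarray, cnt: np.ndarray) -> int:
    """COUNT objective: total adjacent recombination events along the order."""
    order = np.asarray(order)
    return int(cnt[order[:-1], order[1:]].sum())


def _greedy_insertion(sequence: np.ndarray, cnt: np.ndarray) -> list[int]:
    order = [int(sequence[0]), int(sequence[1])]
    for m in sequence[2:]:
        arr = np.asarray(order)
        a = cnt[m, arr]
        interior = a[:-1] + a[1:] - cnt[arr[:-1], arr[1:]]
        costs = np.concatenate(([a[0]], interior, [a[-1]]))
        order.insert(int(np.argmin(costs)), int(m))
    return order


def record_order_indices(
    cnt: np.ndarray, n_counts: int, seed: int
) -> tuple[list[int], int]:
    """RECORD over a recombinant-count matrix; returns (order, COUNT)."""
    n = cnt.shape[0]
    if n < 2:
        return list(range(n)), 0
    rng = np.random.default_rng(seed)
    best_order: list[int] = []
    best_count: int | None = None
    for _ in range(max(1, n_counts)):
        seqn = rng.permutation(n)
        order = _greedy_insertion(seqn, cnt)
        c = order_count(np.asarray(order), cnt)
        if best_count is None or c < best_count:
            best_count, best_order = c, order
    return best_order, int(best_count)


def order_record(
    bins: list[MarkerBin],
    n_counts: int = 16,
    seed: int = 0,
    cnt: np.ndarray | None = None,
) -> "OrderedMap":
    """RECORD marker ordering for one linkage group.

    ``n_counts`` independent random insertion sequences are tried; each bin
    is inserted greedily at the position minimizing the running COUNT, and
    the order with the lowest final COUNT wins (first winner on ties, so
    deterministic given the seed).  The result is canonically oriented with
    the lexicographically lower terminal bin_id first.
    """
    if len(bins) == 0:
        raise ValueError("empty group")
    if cnt is None:
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
    if len(bins) == 1:
        return OrderedMap("", [0], bins, np.array([]), np.array([0.0]), 0)
    best_order, best_count = record_order_indices(cnt, n_counts, seed)
    order = _orient(best_order, bins)
    return OrderedMap("", order, bins, np.array([]), np.array([]), int(best_count))


def _orient(order: list[int], bins: list[MarkerBin]) -> list[int]:
    if bins[order[-1]].bin_id < bins[order[0]].bin_id:
        return order[::-1]
    return order


@lru_cache(maxsize=8)
def _all_perms(w: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(w))), dtype=np.int64)


def _window_candidates(w: int, rng, n_random: int) -> np.ndarray:
    """Candidate permutations for one ripple window of width w."""
    if w <= 8:
        return _all_perms(w)
    base = np.arange(w)
    cands = [base]
    for s in range(1, w):  # circular shifts
        cands.append(np.roll(base, s))
    for i in range(w - 1):  # adjacent transpositions
        p = base.copy()
        p[i], p[i + 1] = p[i + 1], p[i]
        cands.append(p)
    rand = np.argsort(rng.random((n_random, w)), axis=1)
    return np.vstack([np.stack(cands), rand])


def ripple_window(
    ordered: "OrderedMap",
    window: int = 10,
    step: int = 1,
    seed: int = 0,
    n_random: int = 5000,
    cnt: np.ndarray | None = None,
) -> "OrderedMap":
    """Sliding-window reordering ('ripple') accepting strict COUNT improvements.

    Windows of ``window`` bins slide by ``step``; within each window every
    permutation is tried when window <= 8, otherwise all circular shifts,
    all adjacent transpositions and ``n_random`` seeded random permutations.
    A permutation is accepted only if it strictly lowers COUNT; passes
    repeat until one full pass makes no change, so COUNT never increases.
    """
    bins = ordered.bins
    if cnt is None:
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
    order = list(ordered.order)
    L = len(order)
    if L < 2:
        return ordered
    w = min(window, L)
    rng = np.random.default_rng(seed)
    perms = _window_candidates(w, rng, n_random)

    changed = True
    while changed:
        changed = False
        for start in range(0, L - w + 1, max(1, step)):
            ids = np.asarray(order[start : start + w])
            cand = ids[perms]  # P x w
            inner = cnt[cand[:, :-1], cand[:, 1:]].sum(axis=1)
            if start > 0:
                inner = inner + cnt[order[start - 1], cand[:, 0]]
            if start + w < L:
                inner = inner + cnt[cand[:, -1], order[start + w]]
            best = int(np.argmin(inner))
            base_ids = ids
            base_cost = cnt[base_ids[:-1], base_ids[1:]].sum()
            if start > 0:
                base_cost += cnt[order[start - 1], base_ids[0]]
            if start + w < L:
                base_cost += cnt[base_ids[-1], order[start + w]]
            if inner[best] < base_cost:
                order[start : start + w] = [int(x) for x in cand[best]]
                changed = True
    order = _orient(order, bins)
    return OrderedMap(
        ordered.lg_id, order, bins, np.array([]), np.array([]), order_count(np.asarray(order), cnt)
    )


# ---------------------------------------------------------------------------
# Kosambi mapping
# ---------------------------------------------------------------------------


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("Kosambi distance requires r in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


@dataclass
class OrderedMap:
    """An ordered linkage group: bins in map order with cM positions."""

    lg_id: str
    order: list[int]  # indices into bins, map order
    bins: list[MarkerBin]
    adjacent_r: np.ndarray
    positions_cM: np.ndarray
    count_score: int

    @property
    def n_bins(self) -> int:
        return len(self.order)

    @property
    def ordered_bin_ids(self) -> list[str]:
        return [self.bins[i].bin_id for i in self.order]

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0


def kosambi_map(
    ordered: OrderedMap,
    r_clip: float | None = None,
    cnt: np.ndarray | None = None,
    n_mat: np.ndarray | None = None,
) -> OrderedMap:
    """Assign cumulative Kosambi cM positions along the order.

    Adjacent r comes from the phase-aligned two-point estimates of the
    representative signatures.  An adjacent r of exactly 0.5 means the order
    places unlinked bins next to each other and is rejected, unless
    ``r_clip`` is given (used by the subsampling inflation estimator, where
    occasional saturated estimates would otherwise abort a round).
    """
    bins = ordered.bins
    if cnt is None or n_mat is None:
        cnt, n_mat = recombinant_counts(bin_signature_matrix(bins))
    arr = np.asarray(ordered.order)
    if len(arr) == 1:
        return OrderedMap(
            ordered.lg_id, list(arr), bins, np.array([]), np.array([0.0]), ordered.count_score
        )
    k_adj = cnt[arr[:-1], arr[1:]].astype(float)
    n_adj = n_mat[arr[:-1], arr[1:]].astype(float)
    if np.any(n_adj == 0):
        raise ValueError("adjacent bins share no pairwise-complete samples")
    r_adj = k_adj / n_adj
    if r_clip is not None:
        r_adj = np.minimum(r_adj, r_clip)
    if np.any(r_adj >= 0.5):
        raise ValueError("adjacent r = 0.5: unlinked bins adjacent in order")
    d = kosambi(r_adj)
    pos = np.concatenate([[0.0], np.cumsum(d)])
    return OrderedMap(ordered.lg_id, list(arr), bins, r_adj, pos, ordered.count_score)


def pairwise_matrices(ordered: OrderedMap) -> tuple[np.ndarray, np.ndarray]:
    """Dense (r, LOD) matrices in map order, for heat-map style diagnostics."""
    sig = bin_signature_matrix(ordered.bins)[np.asarray(ordered.order)]
    kr, n = recombinant_counts(sig)
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, kr / np.maximum(n, 1), np.nan)
    lod = _lod(kr, n)
    np.fill_diagonal(r, 0.0)
    return r, lod
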