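"""Synthetic data generators for the mapping pipeline.

Emulates the study design the pipeline targets: haploid megagametophyte
testcross families segregating 1:1, a fragmented draft assembly whose
scaffolds carry 1-11 mapped markers (with planted mis-joins), diploid
contamination of haploid calls, and neutral coalescent haplotype panels for
the per-probe diversity statistics.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import DiploidCallMatrix, HaploidGenotypeMatrix, HET

LOCI_COLUMNS = ("marker_id", "chromosome_id", "true_cM", "scaffold_id", "scaffold_bp")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TrueMap:
    """Ground-truth genetic map: chromosomes, marker loci and family sizes.

    ``loci`` columns: marker_id, chromosome_id, true_cM, scaffold_id,
    scaffold_bp (1-based).  Loci are kept sorted by (chromosome, cM,
    marker_id).
    """

    chromosomes: list[tuple[str, float]]
    loci: pd.DataFrame
    families: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LOCI_COLUMNS if c not in self.loci.columns]
        if missing:
            raise ValueError(f"loci frame lacks columns {missing}")
        if self.loci["marker_id"].duplicated().any():
            raise ValueError("marker_ids must be unique")
        lengths = dict(self.chromosomes)
        for chrom, grp in self.loci.groupby("chromosome_id"):
            if chrom not in lengths:
                raise ValueError(f"locus on unknown chromosome {chrom}")
            if (grp["true_cM"] < 0).any() or (grp["true_cM"] > lengths[chrom]).any():
                raise ValueError(f"locus cM outside chromosome {chrom}")
        self.loci = (
            self.loci.sort_values(["chromosome_id", "true_cM", "marker_id"])
            .reset_index(drop=True)
        )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def marker_meta(self) -> pd.DataFrame:
        """Marker metadata frame in pipeline convention (marker_id, scaffold_id, bp)."""
        return pd.DataFrame(
            {
                "marker_id": self.loci["marker_id"],
                "scaffold_id": self.loci["scaffold_id"],
                "bp": self.loci["scaffold_bp"],
            }
        )


def evenly_spaced_true_map(
    n_chromosomes: int = 12,
    markers_per_chromosome: int = 80,
    length_cM: float = 100.0,
    family_sizes: tuple[int, ...] = (),
) -> TrueMap:
    """Evenly spaced markers; one provisional single-marker scaffold per locus.

    The workhorse design for order-recovery and inflation experiments.
    Marker spacing is ``length_cM / markers_per_chromosome`` with the first
    marker at half a spacing from the chromosome start.
    """
    rows = []
    spacing = length_cM / markers_per_chromosome
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for m in range(markers_per_chromosome):
            mid = f"{chrom}_m{m + 1:04d}"
            rows.append((mid, chrom, (m + 0.5) * spacing, f"sc_{mid}", 500))
    loci = pd.DataFrame(rows, columns=LOCI_COLUMNS)
    chroms = [(f"chr{c + 1:02d}", float(length_cM)) for c in range(n_chromosomes)]
    fams = [(f"fam{i + 1}", n) for i, n in enumerate(family_sizes)]
    return TrueMap(chroms, loci, fams)


# ---------------------------------------------------------------------------
# haploid families
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFamily:
    """One haploid mapping family plus its ground truth."""

    genotypes: HaploidGenotypeMatrix
    truth_phase: np.ndarray  # per-marker parental orientation, 0/1
    maternal_het: np.ndarray  # per-marker: True where the mother is heterozygous
    error_rate: float
    missing_rate: float
    contamination_rate: float
    seed: int
    family_id: str


def simulate_haploid_family(
    true_map: TrueMap,
    family_id: str,
    n_samples: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    informative_fraction: float = 1.0,
) -> SimulatedFamily:
    """Simulate one haploid testcross family of independent gametes.

    Each sample is a single meiotic product: per chromosome the crossover
    count is Poisson(length_cM / 100) with breakpoints uniform on the
    chromosome (no interference, i.e. Haldane-consistent).  The transmitted
    allele at a locus is the per-marker parental phase XOR the segment
    parity.  Calls are then flipped with ``error_rate`` and set missing with
    ``missing_rate``, independently per call.

    ``informative_fraction`` is the probability a locus is heterozygous in
    the mother; homozygous loci are emitted as a constant allele (they carry
    family identity but no linkage information).
    """
    if true_map.n_loci == 0:
        raise ValueError("empty map: no loci to simulate")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    if not (0.0 < informative_fraction <= 1.0):
        raise ValueError("informative_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    loci = true_map.loci
    n_loci = len(loci)

    phase = rng.integers(0, 2, size=n_loci).astype(np.int8)
    het = rng.random(n_loci) < informative_fraction
    fixed_allele = rng.integers(0, 2, size=n_loci).astype(np.int8)

    alleles = np.empty((n_loci, n_samples), dtype=np.int8)
    lengths = dict(true_map.chromosomes)
    for chrom, grp in loci.groupby("chromosome_id", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["true_cM"].to_numpy()
        length = lengths[chrom]
        n_breaks = rng.poisson(length / 100.0, size=n_samples)
        start = rng.integers(0, 2, size=n_samples).astype(np.int8)
        for j in range(n_samples):
            breaks = np.sort(rng.uniform(0.0, length, size=n_breaks[j]))
            parity = (np.searchsorted(breaks, pos) + start[j]) % 2
            alleles[idx, j] = phase[idx] ^ parity.astype(np.int8)

    alleles[~het, :] = fixed_allele[~het, None]

    if error_rate > 0:
        flips = rng.random(alleles.shape) < error_rate
        alleles[flips] ^= 1
    if missing_rate > 0:
        alleles[rng.random(alleles.shape) < missing_rate] = -1

    samples = [f"{family_id}_s{j + 1:04d}" for j in range(n_samples)]
    matrix = HaploidGenotypeMatrix(alleles, true_map.marker_meta(), samples)
    return SimulatedFamily(
        matrix, phase, het, error_rate, missing_rate, 0.0, seed, family_id
    )


def simulate_mixture_with_contamination(
    families: list[SimulatedFamily],
    contamination_rate: float = 0.0,
    seed: int = 0,
) -> tuple[DiploidCallMatrix, pd.Series]:
    """Concatenate families into one shuffled diploid-coded call matrix.

    Each haploid call is independently replaced by a heterozygous diploid
    call with probability ``contamination_rate`` (emulating residual diploid
    seed-coat tissue).  True family labels are returned separately for
    scoring; sample names are anonymized so the labels do not leak.
    """
    if not families:
        raise ValueError("need at least one family")
    if not (0.0 <= contamination_rate < 1.0):
        raise ValueError("contamination_rate must be in [0, 1)")
    ref_ids = families[0].genotypes.markers["marker_id"]
    for fam in families[1:]:
        if not ref_ids.equals(fam.genotypes.markers["marker_id"]):
            raise ValueError("families have conflicting marker lists")

    rng = np.random.default_rng(seed)
    calls = np.concatenate([f.genotypes.alleles for f in families], axis=1)
    labels = np.concatenate(
        [np.repeat(f.family_id, f.genotypes.n_samples) for f in families]
    )
    order = rng.permutation(calls.shape[1])
    calls = calls[:, order].astype(np.int8)
    labels = labels[order]

    if contamination_rate > 0:
        calls[rng.random(calls.shape) < contamination_rate] = HET

    samples = [f"mix_s{j + 1:05d}" for j in range(calls.shape[1])]
    meta = families[0].genotypes.markers.copy()
    matrix = DiploidCallMatrix(calls, meta, samples)
    return matrix, pd.Series(labels, index=samples, name="family")


# ---------------------------------------------------------------------------
# artificial assembly with planted errors
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    confidence: str  # high / medium / low


@dataclass
class Scaffold:
    scaffold_id: str
    length_bp: int
    contig_spans: list[tuple[int, int]]  # 0-based half-open
    gap_spans: list[tuple[int, int]]
    gene_models: list[GeneModel]
    marker_loci: list[tuple[str, int]]  # (marker_id, 1-based bp)
    chimera_label: str  # none / inter / intra

    def __post_init__(self) -> None:
        spans = sorted(self.contig_spans + self.gap_spans)
        cur = 0
        for a, b in spans:
            if a != cur or b <= a:
                raise ValueError(
                    f"{self.scaffold_id}: contig/gap spans must tile [0, length)"
                )
            cur = b
        if cur != self.length_bp:
            raise ValueError(f"{self.scaffold_id}: spans do not cover scaffold")
        for g in self.gene_models:
            if not (1 <= g.start_bp <= g.end_bp <= self.length_bp):
                raise ValueError(f"{self.scaffold_id}: gene {g.gene_id} out of bounds")


@dataclass
class ScaffoldSet:
    scaffolds: list[Scaffold]

    def gene_models_frame(self) -> pd.DataFrame:
        rows = [
            (s.scaffold_id, g.gene_id, g.start_bp, g.end_bp, g.confidence)
            for s in self.scaffolds
            for g in s.gene_models
        ]
        return pd.DataFrame(
            rows, columns=["scaffold_id", "gene_id", "start_bp", "end_bp", "confidence"]
        )

    def gap_spans_frame(self) -> pd.DataFrame:
        rows = [
            (s.scaffold_id, a, b) for s in self.scaffolds for a, b in s.gap_spans
        ]
        return pd.DataFrame(rows, columns=["scaffold_id", "start", "end"])

    def lengths(self) -> pd.Series:
        return pd.Series(
            {s.scaffold_id: s.length_bp for s in self.scaffolds}, name="length_bp"
        )

    def labels(self) -> pd.Series:
        return pd.Series(
            {s.scaffold_id: s.chimera_label for s in self.scaffolds}, name="chimera_label"
        )


DEFAULT_MARKER_DIST = {k: 0.55 ** (k - 1) for k in range(1, 12)}


def _draw_sizes(rng, dist: dict[int, float], n: int) -> np.ndarray:
    ks = np.array(sorted(dist))
    w = np.array([dist[k] for k in ks], dtype=float)
    return rng.choice(ks, size=n, p=w / w.sum())


def simulate_assembly(
    true_map: TrueMap,
    n_scaffolds: int | None = None,
    markers_per_scaffold_dist: dict[int, float] | None = None,
    inter_chimera_rate: float = 0.0,
    intra_chimera_rate: float = 0.0,
    gap_spec: dict | None = None,
    seed: int = 0,
) -> tuple[ScaffoldSet, TrueMap]:
    """Partition the true map's loci into artificial assembly scaffolds.

    Scaffolds are assembled from contiguous runs of markers in true-map
    order.  With probability ``inter_chimera_rate`` a scaffold concatenates
    runs from 2-3 different chromosomes; with ``intra_chimera_rate`` two
    runs >5 cM apart on the same chromosome.  Chimeric joins sit at an N-gap
    by default (``gap_spec['join_at_gap']``).  Gene models are planted
    within contig spans, occasionally spanning a gap.

    Returns the scaffold set and a new :class:`TrueMap` whose loci carry the
    generated scaffold coordinates.  If ``n_scaffolds`` is given, that many
    scaffolds are drawn with the chimera rates (raising if loci run out) and
    any leftover loci are packed into additional non-chimeric scaffolds so
    every locus keeps a scaffold position.
    """
    for name, rate in (
        ("inter_chimera_rate", inter_chimera_rate),
        ("intra_chimera_rate", intra_chimera_rate),
    ):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    dist = dict(markers_per_scaffold_dist or DEFAULT_MARKER_DIST)
    if min(dist) < 1 or max(dist) > 11:
        raise ValueError("markers_per_scaffold_dist must be over 1..11 markers")
    spec = {
        "marker_spacing_bp": 1000,
        "gap_bp": 100,
        "flank_bp": 400,
        "join_at_gap": True,
        "intra_gap_cM": 8.0,
        "gene_rate": 0.7,
        "gene_span_gap_rate": 0.3,
    }
    spec.update(gap_spec or {})
    rng = np.random.default_rng(seed)

    remaining: dict[str, list[tuple[str, float]]] = {}
    for chrom, grp in true_map.loci.groupby("chromosome_id", sort=True):
        remaining[chrom] = list(zip(grp["marker_id"], grp["true_cM"]))
    chrom_ids = sorted(remaining)

    def n_left() -> int:
        return sum(len(v) for v in remaining.values())

    def take_run(chrom: str, k: int, start_offset: int = 0) -> list[tuple[str, float]]:
        lst = remaining[chrom]
        run = lst[start_offset : start_offset + k]
        del lst[start_offset : start_offset + k]
        return run

    def pick_chrom(min_markers: int, exclude: set[str] = frozenset()) -> str | None:
        avail = [c for c in chrom_ids if c not in exclude and len(remaining[c]) >= min_markers]
        if not avail:
            return None
        weights = np.array([len(remaining[c]) for c in avail], dtype=float)
        return avail[rng.choice(len(avail), p=weights / weights.sum())]

    scaffolds: list[Scaffold] = []
    locus_rows: list[tuple[str, str, float, str, int]] = []
    chrom_of = dict(zip(true_map.loci["marker_id"], true_map.loci["chromosome_id"]))

    def build_scaffold(parts: list[list[tuple[str, float]]], label: str, join_at_gap: bool) -> None:
        sid = f"scf_{len(scaffolds) + 1:05d}"
        spacing, gap_bp, flank = spec["marker_spacing_bp"], spec["gap_bp"], spec["flank_bp"]
        contig_spans: list[tuple[int, int]] = []
        gap_spans: list[tuple[int, int]] = []
        marker_loci: list[tuple[str, int]] = []
        pos = 0
        open_start = 0
        for p_i, part in enumerate(parts):
            if p_i > 0 and join_at_gap:
                contig_spans.append((open_start, pos))
                gap_spans.append((pos, pos + gap_bp))
                pos += gap_bp
                open_start = pos
            # else: consecutive runs fuse inside one contiguous contig
            for q, (mid, _cm) in enumerate(part):
                marker_loci.append((mid, pos + flank + q * spacing + 1))  # 1-based
            pos += flank + (len(part) - 1) * spacing + flank
        contig_spans.append((open_start, pos))
        length = pos

        genes: list[GeneModel] = []
        conf_levels = np.array(["high", "medium", "low"])
        gi = 0
        for a, b in contig_spans:
            if b - a > 600 and rng.random() < spec["gene_rate"]:
                g_start = a + int(rng.integers(50, 200))
                g_end = min(b - 50, g_start + int(rng.integers(300, max(400, b - a - 250))))
                if g_end > g_start:
                    gi += 1
                    genes.append(
                        GeneModel(
                            f"{sid}_g{gi}",
                            g_start + 1,
                            g_end,
                            str(rng.choice(conf_levels, p=[0.5, 0.35, 0.15])),
                        )
                    )
        # occasionally a gene model spans an N-gap (exercises within-gene splits)
        for (a, b) in gap_spans:
            if rng.random() < spec["gene_span_gap_rate"]:
                gi += 1
                genes.append(
                    GeneModel(
                        f"{sid}_g{gi}",
                        max(1, a - 300),
                        min(length, b + 300),
                        str(rng.choice(conf_levels, p=[0.5, 0.35, 0.15])),
                    )
                )

        scaffolds.append(
            Scaffold(sid, length, contig_spans, gap_spans, genes, marker_loci, label)
        )
        for mid, bp in marker_loci:
            locus_rows.append((mid, chrom_of[mid], bp, sid, 0.0))  # cM filled later

    def make_one() -> bool:
        if n_left() == 0:
            return False
        k = int(_draw_sizes(rng, dist, 1)[0])
        u = rng.random()
        if u < inter_chimera_rate and n_left() >= 2:
            k = max(k, 2)
            n_parts = int(rng.integers(2, 4)) if k >= 3 else 2
            sizes = _split_sizes(rng, k, n_parts)
            parts, used = [], set()
            for sz in sizes:
                c = pick_chrom(1, exclude=used)
                if c is None:
                    break
                used.add(c)
                parts.append(take_run(c, min(sz, len(remaining[c]))))
            if len(parts) >= 2:
                build_scaffold(parts, "inter", spec["join_at_gap"])
                return True
            for part in parts:  # give back on failure
                remaining[chrom_of[part[0][0]]][:0] = part
        elif u < inter_chimera_rate + intra_chimera_rate:
            k = max(k, 2)
            s1 = max(1, k // 2)
            c = pick_chrom(2)
            if c is not None:
                lst = remaining[c]
                run1 = lst[:s1]
                cut_cm = run1[-1][1] + spec["intra_gap_cM"]
                j = next((i for i in range(s1, len(lst)) if lst[i][1] >= cut_cm), None)
                if j is not None:
                    run2 = take_run(c, min(k - s1, len(lst) - j), start_offset=j)
                    run1 = take_run(c, s1)
                    build_scaffold([run1, run2], "intra", spec["join_at_gap"])
                    return True
        c = pick_chrom(1)
        run = take_run(c, min(k, len(remaining[c])))
        # plain scaffolds may still contain internal N-gaps (contig joins)
        n_cuts = int(rng.integers(0, 3)) if len(run) > 2 else 0
        if n_cuts:
            cuts = sorted(rng.choice(np.arange(1, len(run)), size=n_cuts, replace=False))
            parts = [run[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(run)])]
        else:
            parts = [run]
        build_scaffold(parts, "none", True)
        return True

    if n_scaffolds is not None:
        for _ in range(n_scaffolds):
            if not make_one():
                raise ValueError("requested scaffolds exceed available loci")
        # sweep leftovers into plain scaffolds
        saved = (inter_chimera_rate, intra_chimera_rate)
        inter_chimera_rate = intra_chimera_rate = 0.0
        while make_one():
            pass
        inter_chimera_rate, intra_chimera_rate = saved
    else:
        while make_one():
            pass

    cm_of = dict(zip(true_map.loci["marker_id"], true_map.loci["true_cM"]))
    loci = pd.DataFrame(
        [(m, c, cm_of[m], s, bp) for (m, c, bp, s, _z) in locus_rows],
        columns=LOCI_COLUMNS,
    )
    new_map = TrueMap(list(true_map.chromosomes), loci, list(true_map.families))
    return ScaffoldSet(scaffolds), new_map


def _split_sizes(rng, k: int, n_parts: int) -> list[int]:
    """Random composition of k into n_parts positive parts."""
    n_parts = min(n_parts, k)
    if n_parts == 1:
        return [k]
    cuts = np.sort(rng.choice(np.arange(1, k), size=n_parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [k]])
    return list(np.diff(bounds).astype(int))


# ---------------------------------------------------------------------------
# neutral coalescent panels
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Infinite-sites haplotype panel from a neutral coalescent realization."""

    haplotypes: np.ndarray  # n_samples x n_sites, 0/1
    site_positions: np.ndarray  # strictly increasing bp offsets
    theta: float
    seed: int

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def simulate_coalescent_probe(
    n_samples: int,
    theta: float,
    region_length_bp: float = 320.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Single-population neutral coalescent with infinite-sites mutation.

    Waiting time at ``k`` lineages is exponential with rate k(k-1)/2 (time
    in units of 2N generations); mutations are dropped on branches as a
    Poisson process of rate theta/2 per unit branch length, each creating
    one new segregating site at a uniform position on the region.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed)

    lineages: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n_samples)
    ]
    branches: list[tuple[frozenset[int], float]] = []  # (subtended leaves, length)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (leaves_j, birth_j) = lineages.pop(j)
        (leaves_i, birth_i) = lineages.pop(i)
        branches.append((leaves_i, t - birth_i))
        branches.append((leaves_j, t - birth_j))
        lineages.append((leaves_i | leaves_j, t))

    cols: list[np.ndarray] = []
    for leaves, length in branches:
        n_mut = rng.poisson(theta / 2.0 * length)
        if n_mut:
            col = np.zeros(n_samples, dtype=np.int8)
            col[list(leaves)] = 1
            cols.extend([col] * n_mut)

    if cols:
        haps = np.stack(cols, axis=1)
        pos = np.sort(rng.uniform(0.0, region_length_bp, size=haps.shape[1]))
    else:
        haps = np.zeros((n_samples, 0), dtype=np.int8)
        pos = np.array([])
    return HaplotypePanel(haps, pos, theta, seed)
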