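"""Per-probe neutrality statistics anchored to the consensus map.

A diversity panel (unrelated individuals, VCF) is hard-filtered, summarized
per extended probe region (segregating sites S, per-site pairwise diversity
pi, Tajima's D, Kelly's ZnS), anchored to consensus cM coordinates via the
physically closest mapped probe on the same scaffold, and smoothed into
sliding-window tracks along the linkage groups.

Diploid genotypes are treated as 2n alleles of unknown phase: S, pi and D
are allele-frequency based; ZnS uses squared genotype correlation
(composite LD), which coincides with haplotype r^2 for phased/haploid
panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import HaplotypePanel


# ---------------------------------------------------------------------------
# probe regions and variant filtering
# ---------------------------------------------------------------------------


@dataclass
class ProbeRegion:
    probe_id: str
    scaffold_id: str
    core_start: int  # 0-based half-open core (probe) interval
    core_end: int
    extension: int = 100

    @property
    def start(self) -> int:
        return max(0, self.core_start - self.extension)

    @property
    def end(self) -> int:
        return self.core_end + self.extension

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint_bp(self) -> int:
        return (self.core_start + self.core_end) // 2


def read_probe_bed(path: str, extension: int = 100) -> list[ProbeRegion]:
    """Probe core intervals from a BED file (0-based half-open, name = probe id)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return [
        ProbeRegion(str(r.name), str(r.chrom), int(r.start), int(r.end), extension)
        for r in df.itertuples(index=False)
    ]


@dataclass
class FilteredVariants:
    dosage: np.ndarray  # sites x samples, alt-allele dosage 0..ploidy, -1 missing
    sites: pd.DataFrame  # chrom, pos (1-based), probe_id
    samples: list[str]
    ploidy: int
    ledger: dict[str, int]


def filter_variants(
    vcf_path: str,
    regions: list[ProbeRegion],
    qd_min: float = 5.0,
    mq_min: float = 50.0,
    dp_range: tuple[float, float] = (3000.0, 16000.0),
    sample_miss_max: float = 0.25,
) -> FilteredVariants:
    """Hard-filter a diversity-panel VCF down to analysis-ready sites.

    Sites kept iff: bi-allelic SNP, inside an extended probe region,
    QD > qd_min, MQ > mq_min and dp_range[0] <= DP <= dp_range[1] (missing
    annotations exclude the site and are counted separately).  Samples with
    a missing-call fraction > sample_miss_max over the kept sites are then
    dropped.  The ledger reports counts removed per rule.
    """
    from cyvcf2 import VCF

    trees: dict[str, IntervalTree] = {}
    for reg in regions:
        trees.setdefault(reg.scaffold_id, IntervalTree())[reg.start : reg.end] = reg.probe_id

    ledger = {
        "not_biallelic_snp": 0,
        "outside_regions": 0,
        "qd": 0,
        "mq": 0,
        "dp": 0,
        "missing_annotation": 0,
        "kept_sites": 0,
        "dropped_samples": 0,
    }
    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            ledger["not_biallelic_snp"] += 1
            continue
        hits = trees.get(v.CHROM, IntervalTree())[v.POS - 1]
        if not hits:
            ledger["outside_regions"] += 1
            continue
        qd, mq, dp = v.INFO.get("QD"), v.INFO.get("MQ"), v.INFO.get("DP")
        if qd is None or mq is None or dp is None:
            ledger["missing_annotation"] += 1
            continue
        if not qd > qd_min:
            ledger["qd"] += 1
            continue
        if not mq > mq_min:
            ledger["mq"] += 1
            continue
        if not (dp_range[0] <= dp <= dp_range[1]):
            ledger["dp"] += 1
            continue
        probe_id = sorted(h.data for h in hits)[0]
        gts = v.gt_types.copy()  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        dose = np.where(gts == 3, -1, gts).astype(np.int8)
        rows.append((v.CHROM, v.POS, probe_id))
        dosages.append(dose)
        ledger["kept_sites"] += 1

    dosage = np.array(dosages, dtype=np.int8) if dosages else np.zeros((0, len(samples)), np.int8)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "probe_id"])
    if len(dosage):
        miss = (dosage == -1).mean(axis=0)
        keep = miss <= sample_miss_max
        ledger["dropped_samples"] = int((~keep).sum())
        dosage = dosage[:, keep]
        samples = [s for s, k in zip(samples, keep) if k]
    return FilteredVariants(dosage, sites, samples, 2, ledger)


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------


def tajima_constants(n: float) -> dict[str, float]:
    """Tajima (1989) normalization constants for sample size n alleles."""
    nf = float(n)
    a1 = sum(1.0 / i for i in range(1, int(round(nf))))
    a2 = sum(1.0 / i**2 for i in range(1, int(round(nf))))
    b1 = (nf + 1.0) / (3.0 * (nf - 1.0))
    b2 = 2.0 * (nf**2 + nf + 3.0) / (9.0 * nf * (nf - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nf + 2.0) / (a1 * nf) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_total: float, n: float) -> float | None:
    """Tajima's D from segregating sites, total pairwise diversity and n alleles."""
    if S == 0 or n < 2:
        return None
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi_total - S / k["a1"]) / math.sqrt(var)


@dataclass
class NeutralityStats:
    probe_id: str
    S: int
    pi_per_site: float
    pi_total: float
    tajima_d: float | None
    zns: float | None
    n_samples: int
    callable_sites: int


def _site_frequencies(dosage: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt-allele frequency and allele count over non-missing calls."""
    present = dosage >= 0
    m = present.sum(axis=1) * ploidy
    alt = np.where(present, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    return p, m


def neutrality_stats(
    dosage: np.ndarray,
    probe_id: str = "",
    callable_sites: int | None = None,
    ploidy: int = 2,
) -> NeutralityStats:
    """S, pi and Tajima's D for one probe region.

    ``dosage``: sites x samples alt-allele dosages (-1 missing).  Per site
    with allele count m and alt frequency p, the unbiased pairwise
    diversity contribution is 2 p (1-p) m / (m-1); pi_per_site divides the
    total by ``callable_sites`` (defaults to the number of sites supplied).
    Tajima's D uses the constants evaluated at the site-wise mean allele
    count over segregating sites; it is undefined (None) when S = 0.
    """
    dosage = np.asarray(dosage)
    if dosage.ndim != 2:
        raise ValueError("dosage must be sites x samples")
    n_samp = dosage.shape[1]
    if callable_sites is None:
        callable_sites = dosage.shape[0]
    p, m = _site_frequencies(dosage, ploidy)
    seg = (p > 0) & (p < 1) & (m > 1)
    S = int(seg.sum())
    contrib = 2.0 * p[seg] * (1.0 - p[seg]) * m[seg] / (m[seg] - 1.0)
    pi_total = float(contrib.sum())
    pi_site = pi_total / callable_sites if callable_sites else 0.0
    n_bar = float(m[seg].mean()) if S else float(n_samp * ploidy)
    d = tajimas_d(S, pi_total, n_bar)
    z = zns(dosage, ploidy=ploidy) if S >= 2 else None
    return NeutralityStats(probe_id, S, pi_site, pi_total, d, z, n_samp, int(callable_sites))


def zns(dosage: np.ndarray, ploidy: int = 2) -> float | None:
    """Kelly's ZnS: mean squared correlation over pairs of segregating sites.

    Correlation is computed between dosage vectors over pairwise-complete
    samples (composite LD for unphased diploids).  Undefined (None) with
    fewer than 2 segregating sites; monomorphic-over-complete-samples pairs
    contribute r^2 = 0.
    """
    dosage = np.asarray(dosage, dtype=float)
    p, m = _site_frequencies(dosage.astype(np.int64), ploidy)
    seg = np.where((p > 0) & (p < 1) & (m > 1))[0]
    if len(seg) < 2:
        return None
    total, n_pairs = 0.0, 0
    for ai in range(len(seg)):
        for bi in range(ai + 1, len(seg)):
            x = dosage[seg[ai]]
            y = dosage[seg[bi]]
            ok = (x >= 0) & (y >= 0)
            n_pairs += 1
            if ok.sum() < 2:
                continue
            xv, yv = x[ok], y[ok]
            sx, sy = xv.std(), yv.std()
            if sx == 0 or sy == 0:
                continue
            r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
            total += r * r
    return total / n_pairs


def panel_stats(panel: HaplotypePanel, callable_sites: int | None = None) -> NeutralityStats:
    """Neutrality statistics for a simulated haploid panel."""
    return neutrality_stats(
        panel.haplotypes.T, probe_id="panel", callable_sites=callable_sites, ploidy=1
    )


def probe_neutrality_table(
    variants: FilteredVariants, regions: list[ProbeRegion]
) -> pd.DataFrame:
    """Per-probe neutrality statistics over all filtered sites."""
    by_probe = {r.probe_id: r for r in regions}
    rows = []
    for probe_id, grp in variants.sites.groupby("probe_id"):
        reg = by_probe.get(probe_id)
        callable_sites = reg.length if reg is not None else len(grp)
        st = neutrality_stats(
            variants.dosage[grp.index.to_numpy()],
            probe_id=probe_id,
            callable_sites=callable_sites,
            ploidy=variants.ploidy,
        )
        rows.append(vars(st))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cM anchoring and sliding windows
# ---------------------------------------------------------------------------


def anchor_probes(
    probes: pd.DataFrame,
    consensus: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each probe a consensus (lg_id, cM).

    ``probes``: probe_id, scaffold_id, bp.  ``consensus``: probe_id (mapped
    probes), scaffold_id, bp, lg_id, cM.  Probes mapped directly keep their
    own coordinates; others take those of the physically closest (|delta
    bp|) mapped probe on the same scaffold — ties resolved toward the
    smaller cM, then lexicographic probe_id.  Probes on unanchored
    scaffolds come back with anchor_source = 'unassigned'.
    """
    mapped = consensus.set_index("probe_id")
    by_scaffold = dict(tuple(consensus.groupby("scaffold_id")))
    rows = []
    for r in probes.itertuples(index=False):
        if r.probe_id in mapped.index:
            hit = mapped.loc[r.probe_id]
            rows.append((r.probe_id, hit["lg_id"], float(hit["cM"]), "direct"))
            continue
        cand = by_scaffold.get(r.scaffold_id)
        if cand is None or cand.empty:
            rows.append((r.probe_id, None, np.nan, "unassigned"))
            continue
        dist = (cand["bp"] - r.bp).abs()
        best = cand.assign(dist=dist).sort_values(
            ["dist", "cM", "probe_id"], kind="mergesort"
        ).iloc[0]
        rows.append((r.probe_id, best["lg_id"], float(best["cM"]), "nearest-bp"))
    return pd.DataFrame(rows, columns=["probe_id", "lg_id", "cM", "anchor_source"])


def sliding_windows(
    anchored: pd.DataFrame,
    value_column: str,
    width_cM: float = 10.0,
    step_cM: float = 1.0,
) -> pd.DataFrame:
    """Sliding-window means of a statistic along each LG.

    Windows are half-open [k*step, k*step + width) for k = 0 ..
    floor(L/step) with L the maximum anchored cM on the LG, so every
    anchored probe — including those within one window width of the LG end
    — falls in the same number of windows; empty windows are reported with
    n_probes = 0 and a missing mean.
    """
    if width_cM <= 0 or step_cM <= 0:
        raise ValueError("width and step must be positive")
    rows = []
    data = anchored.dropna(subset=["cM"])
    for lg, grp in data.groupby("lg_id", sort=True):
        L = grp["cM"].max()
        k_max = max(0, math.floor(L / step_cM))
        cm = grp["cM"].to_numpy()
        vals = grp[value_column].to_numpy(dtype=float)
        for k in range(k_max + 1):
            lo = k * step_cM
            hi = lo + width_cM
            inside = (cm >= lo) & (cm < hi) & ~np.isnan(vals)
            n = int(inside.sum())
            rows.append(
                (lg, lo, hi, float(vals[inside].mean()) if n else np.nan, n)
            )
    return pd.DataFrame(rows, columns=["lg_id", "start_cM", "end_cM", "mean", "n_probes"])
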