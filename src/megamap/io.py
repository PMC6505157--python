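"""Readers and writers for the pipeline's on-disk formats.

Genotype matrices travel as TSV (markers x samples with metadata columns)
or VCF (v4.2; haploid GT for megagametophyte calls, diploid GT for
diploid-coded calls); the artificial assembly exports AGP v2.1 and GFF3;
maps and reports are plain TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import DiploidCallMatrix, HaploidGenotypeMatrix
from .simulate import LOCI_COLUMNS, ScaffoldSet, TrueMap

_META = ["marker_id", "scaffold_id", "bp"]


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------


def write_genotype_tsv(matrix: HaploidGenotypeMatrix | DiploidCallMatrix, path: str) -> None:
    data = matrix.alleles if isinstance(matrix, HaploidGenotypeMatrix) else matrix.calls
    frame = pd.concat(
        [matrix.markers[_META].reset_index(drop=True),
         pd.DataFrame(data, columns=matrix.samples)],
        axis=1,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str, diploid: bool = False):
    frame = pd.read_csv(path, sep="\t")
    meta = frame[_META].copy()
    data = frame.drop(columns=_META).to_numpy(dtype=np.int8)
    samples = [c for c in frame.columns if c not in _META]
    cls = DiploidCallMatrix if diploid else HaploidGenotypeMatrix
    return cls(data, meta, samples)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(matrix: HaploidGenotypeMatrix | DiploidCallMatrix, path: str) -> None:
    """VCFv4.2 export; haploid GT (0/1/.) or diploid GT per matrix type."""
    import pysam

    haploid = isinstance(matrix, HaploidGenotypeMatrix)
    data = matrix.alleles if haploid else matrix.calls
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    meta = matrix.markers
    for sid, grp in meta.groupby("scaffold_id", sort=True):
        header.contigs.add(str(sid), length=int(grp["bp"].max()) + 1000)
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, row in meta.iterrows():
            rec = out.new_record(
                contig=str(row["scaffold_id"]), start=int(row["bp"]) - 1,
                stop=int(row["bp"]), alleles=("A", "G"), id=str(row["marker_id"]),
            )
            for j, s in enumerate(matrix.samples):
                v = int(data[i, j])
                if haploid:
                    rec.samples[s]["GT"] = (None,) if v < 0 else (v,)
                else:
                    gt = {0: (0, 0), 1: (1, 1), 2: (0, 1)}.get(v, (None, None))
                    rec.samples[s]["GT"] = gt
            out.write(rec)


def read_vcf_calls(path: str) -> DiploidCallMatrix:
    """Read a VCF into diploid call codes (works for haploid GT too)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, calls = [], []
    for v in vcf:
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS))
        gts = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        code = np.select([gts == 0, gts == 1, gts == 2], [0, 2, 1], default=-1)
        calls.append(code.astype(np.int8))
    meta = pd.DataFrame(rows, columns=_META)
    return DiploidCallMatrix(np.array(calls, dtype=np.int8), meta, samples)


# ---------------------------------------------------------------------------
# true map / scaffolds
# ---------------------------------------------------------------------------


def write_true_map_tsv(true_map: TrueMap, path: str) -> None:
    true_map.loci.to_csv(path, sep="\t", index=False)


def read_true_map_tsv(path: str, chromosome_lengths: dict[str, float] | None = None) -> TrueMap:
    loci = pd.read_csv(path, sep="\t")[list(LOCI_COLUMNS)]
    if chromosome_lengths is None:
        chromosome_lengths = loci.groupby("chromosome_id")["true_cM"].max().to_dict()
    return TrueMap(sorted(chromosome_lengths.items()), loci)


def write_agp(scaffolds: ScaffoldSet, path: str) -> None:
    """AGP v2.1: contig (W) and N-gap components tiling each scaffold."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for s in scaffolds.scaffolds:
            spans = sorted(
                [(a, b, "W") for a, b in s.contig_spans]
                + [(a, b, "N") for a, b in s.gap_spans]
            )
            for part, (a, b, kind) in enumerate(spans, start=1):
                if kind == "W":
                    fh.write(
                        f"{s.scaffold_id}\t{a + 1}\t{b}\t{part}\tW\t"
                        f"{s.scaffold_id}_ctg{part}\t1\t{b - a}\t+\n"
                    )
                else:
                    fh.write(
                        f"{s.scaffold_id}\t{a + 1}\t{b}\t{part}\tN\t{b - a}\t"
                        f"scaffold\tyes\tpaired-ends\n"
                    )


def write_gff3(scaffolds: ScaffoldSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in scaffolds.scaffolds:
            for g in s.gene_models:
                fh.write(
                    f"{s.scaffold_id}\tmegamap\tgene\t{g.start_bp}\t{g.end_bp}\t.\t+\t.\t"
                    f"ID={g.gene_id};confidence={g.confidence}\n"
                )


def read_gene_models_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                (f[0], attrs.get("ID", "?"), int(f[3]), int(f[4]),
                 attrs.get("confidence", "medium"))
            )
    return pd.DataFrame(
        rows, columns=["scaffold_id", "gene_id", "start_bp", "end_bp", "confidence"]
    )


def read_gap_spans_agp(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 5 and f[4] == "N":
                rows.append((f[0], int(f[1]) - 1, int(f[2])))
    return pd.DataFrame(rows, columns=["scaffold_id", "start", "end"])


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------


def write_map_tsv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
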