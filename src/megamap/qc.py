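"""Genotype quality control for haploid megagametophyte panels.

Converts diploid-coded calls to haploid genotypes (heterozygotes flag
diploid-tissue contamination and become missing), filters contaminated or
poorly genotyped samples, assigns samples to maternal families by
PCA + hierarchical clustering, recodes markers to the 1:1 haploid testcross
form, and tests marker bins for segregation distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .genotypes import DiploidCallMatrix, HaploidGenotypeMatrix, HET, MISSING


def collapse_heterozygous_calls(diploid: DiploidCallMatrix) -> HaploidGenotypeMatrix:
    """Collapse diploid codes to haploid alleles; heterozygotes become missing.

    Per-sample ``het_fraction`` is computed over non-missing input calls
    *before* the collapse — a direct estimate of the per-call contamination
    rate — and ``missing_fraction`` over all calls after it.
    """
    calls = diploid.calls
    het = calls == HET
    non_missing = calls != MISSING
    denom = non_missing.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_fraction = np.where(denom > 0, het.sum(axis=0) / denom, 0.0)

    alleles = calls.copy()
    alleles[het] = MISSING
    missing_fraction = (
        (alleles == MISSING).mean(axis=0) if alleles.size else np.zeros(len(diploid.samples))
    )
    stats_df = pd.DataFrame(
        {
            "sample_id": diploid.samples,
            "het_fraction": het_fraction,
            "missing_fraction": missing_fraction,
        }
    )
    return HaploidGenotypeMatrix(alleles, diploid.markers.copy(), list(diploid.samples), stats_df)


def filter_samples(
    matrix: HaploidGenotypeMatrix,
    het_max: float = 0.10,
    miss_max: float = 0.20,
) -> tuple[HaploidGenotypeMatrix, pd.DataFrame]:
    """Drop samples with heterozygosity > het_max or missingness > miss_max.

    Comparisons are strict, so a sample sitting exactly on a threshold is
    retained.  Returns the filtered matrix and an exclusion report with one
    row per removed sample and the reason(s).
    """
    for name, thr in (("het_max", het_max), ("miss_max", miss_max)):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if matrix.sample_stats is not None:
        het = matrix.sample_stats["het_fraction"].to_numpy(dtype=float)
    else:
        het = np.zeros(matrix.n_samples)
    miss = matrix.missing_fraction_per_sample()

    reasons = []
    for j, sample in enumerate(matrix.samples):
        why = []
        if het[j] > het_max:
            why.append(f"het_fraction {het[j]:.4f} > {het_max}")
        if miss[j] > miss_max:
            why.append(f"missing_fraction {miss[j]:.4f} > {miss_max}")
        if why:
            reasons.append((sample, het[j], miss[j], "; ".join(why)))
    report = pd.DataFrame(
        reasons, columns=["sample_id", "het_fraction", "missing_fraction", "reason"]
    )
    keep = [j for j, s in enumerate(matrix.samples) if s not in set(report["sample_id"])]
    if not keep:
        import warnings

        warnings.warn("all samples removed by QC thresholds")
        return matrix.take_samples(np.array([], dtype=int)), report
    return matrix.take_samples(np.array(keep)), report


@dataclass
class FamilyAssignment:
    labels: pd.Series  # sample_id -> family label (int, 0-based)
    k: int
    pca_coordinates: pd.DataFrame
    silhouette_by_k: dict[int, float]

    @property
    def family_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_families(
    matrix: HaploidGenotypeMatrix,
    max_k: int = 6,
    n_components: int = 3,
    min_silhouette: float = 0.45,
) -> FamilyAssignment:
    """Assign samples to putative maternal families.

    PCA on the sample-by-marker allele matrix (missing calls mean-imputed
    per marker), then average-linkage hierarchical clustering (Euclidean) on
    the leading components.  ``k`` is chosen by the largest mean silhouette
    over 2..max_k; if no k reaches ``min_silhouette`` the samples are judged
    a single family (k = 1).  Family structure from unrelated mothers lives
    in the first few components, while within-family segregation noise is
    isotropic — hence few components and a demanding silhouette floor.
    Deterministic given the input.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")

    X = matrix.alleles.T.astype(float)  # samples x markers
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]

    n_comp = min(n_components, matrix.n_samples - 1, matrix.n_markers)
    if n_comp < n_components:
        import warnings

        warnings.warn(f"reducing PCA components to {n_comp}")
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)

    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {1: np.zeros(matrix.n_samples, dtype=int)}
    for k in range(2, min(max_k, matrix.n_samples - 1) + 1):
        model = AgglomerativeClustering(n_clusters=k, linkage="average", metric="euclidean")
        lab = model.fit_predict(coords)
        labels_by_k[k] = lab
        scores[k] = float(silhouette_score(coords, lab))

    if scores and max(scores.values()) >= min_silhouette:
        best_k = max(scores, key=lambda k: (scores[k], -k))
    else:
        best_k = 1
    lab = labels_by_k[best_k]
    # stable relabeling: families numbered by order of first appearance
    order = {old: new for new, old in enumerate(pd.unique(lab))}
    lab = np.array([order[v] for v in lab])

    coords_df = pd.DataFrame(
        coords,
        index=pd.Index(matrix.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return FamilyAssignment(
        pd.Series(lab, index=matrix.samples, name="family"), best_k, coords_df, scores
    )


def recode_testcross(
    matrix: HaploidGenotypeMatrix,
    families: FamilyAssignment | pd.Series,
) -> dict[object, tuple[HaploidGenotypeMatrix, pd.DataFrame]]:
    """Per family: keep only markers segregating in the haploid testcross.

    Within a family a marker is informative iff both alleles are observed
    (the mother was heterozygous at the locus); monomorphic or all-missing
    markers are dropped.  Returns {family: (matrix, drop report)}.
    """
    labels = families.labels if isinstance(families, FamilyAssignment) else families
    if labels.empty:
        raise ValueError("empty family assignment")
    out: dict[object, tuple[HaploidGenotypeMatrix, pd.DataFrame]] = {}
    sample_pos = {s: j for j, s in enumerate(matrix.samples)}
    for fam, members in labels.groupby(labels):
        cols = np.array([sample_pos[s] for s in members.index if s in sample_pos])
        sub = matrix.take_samples(cols)
        has0 = (sub.alleles == 0).any(axis=1)
        has1 = (sub.alleles == 1).any(axis=1)
        informative = has0 & has1
        dropped = sub.markers.loc[~informative, ["marker_id"]].copy()
        dropped["reason"] = np.where(
            (~has0 & ~has1)[~informative], "all-missing", "monomorphic"
        )
        out[fam] = (sub.take_markers(np.where(informative)[0]), dropped.reset_index(drop=True))
    return out


def test_segregation_distortion(
    bin_signatures: np.ndarray,
    bin_ids: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chi-square goodness-of-fit against 1:1 segregation, per marker bin.

    df = 1; the Bonferroni flag compares p to alpha / (number of testable
    bins).  Bins with zero non-missing calls are reported untestable.
    """
    sig = np.asarray(bin_signatures)
    n1 = (sig == 1).sum(axis=1)
    n0 = (sig == 0).sum(axis=1)
    n = n0 + n1
    testable = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(testable, (n0 - n / 2.0) ** 2 / (n / 2.0) * 2.0, np.nan)
    pval = np.where(testable, stats.chi2.sf(chi2, df=1), np.nan)
    n_tests = int(testable.sum())
    flagged = testable & (pval < alpha / max(n_tests, 1))
    return pd.DataFrame(
        {
            "bin_id": bin_ids,
            "n_ref": n0,
            "n_alt": n1,
            "chi2": chi2,
            "p_value": pval,
            "testable": testable,
            "distorted": flagged,
        }
    )
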