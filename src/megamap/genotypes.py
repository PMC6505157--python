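"""Core genotype containers.

Two matrix types flow through the pipeline:

* :class:`DiploidCallMatrix` — raw diploid-coded calls (hom-ref / hom-alt /
  het / missing) as they come out of a diploid-model variant caller run on
  haploid megagametophyte tissue.  Heterozygous calls flag diploid
  contamination and are collapsed to missing downstream.
* :class:`HaploidGenotypeMatrix` — the pipeline's central object: haploid
  alleles in {0, 1} with missing data, plus per-marker scaffold/bp metadata.

Both store markers as rows and samples as columns, with ``int8`` codes and
``-1`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
HOM_REF = np.int8(0)
HOM_ALT = np.int8(1)
HET = np.int8(2)

#: columns every marker-metadata frame must carry
MARKER_META_COLUMNS = ("marker_id", "scaffold_id", "bp")


def _check_meta(meta: pd.DataFrame, n_markers: int) -> pd.DataFrame:
    missing_cols = [c for c in MARKER_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"marker metadata lacks columns {missing_cols}")
    if len(meta) != n_markers:
        raise ValueError(
            f"metadata rows ({len(meta)}) != matrix rows ({n_markers})"
        )
    if meta["marker_id"].duplicated().any():
        raise ValueError("duplicate marker_ids in metadata")
    return meta.reset_index(drop=True)


@dataclass
class DiploidCallMatrix:
    """Markers x samples diploid-coded calls (0=hom-ref, 1=hom-alt, 2=het, -1=missing)."""

    calls: np.ndarray
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (markers x samples)")
        if self.calls.shape[1] != len(self.samples):
            raise ValueError("sample names do not match matrix width")
        self.markers = _check_meta(self.markers, self.calls.shape[0])
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("diploid calls must be coded -1/0/1/2")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]


@dataclass
class HaploidGenotypeMatrix:
    """Markers x samples haploid alleles (0/1, -1=missing) with marker metadata.

    ``sample_stats`` (optional) carries per-sample QC fractions
    (``het_fraction`` measured before heterozygote collapse,
    ``missing_fraction`` measured after).
    """

    alleles: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    sample_stats: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (markers x samples)")
        if self.alleles.shape[1] != len(self.samples):
            raise ValueError("sample names do not match matrix width")
        self.markers = _check_meta(self.markers, self.alleles.shape[0])
        bad = ~np.isin(self.alleles, [-1, 0, 1])
        if bad.any():
            raise ValueError("haploid alleles must be coded -1/0/1")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def missing_fraction_per_sample(self) -> np.ndarray:
        return (self.alleles == MISSING).mean(axis=0)

    def take_samples(self, index: np.ndarray | list[int]) -> "HaploidGenotypeMatrix":
        index = np.asarray(index)
        stats = None
        if self.sample_stats is not None:
            stats = self.sample_stats.iloc[index].reset_index(drop=True)
        return HaploidGenotypeMatrix(
            self.alleles[:, index],
            self.markers.copy(),
            [self.samples[i] for i in index],
            stats,
        )

    def take_markers(self, index: np.ndarray | list[int]) -> "HaploidGenotypeMatrix":
        index = np.asarray(index)
        return HaploidGenotypeMatrix(
            self.alleles[index, :],
            self.markers.iloc[index].reset_index(drop=True),
            list(self.samples),
            None if self.sample_stats is None else self.sample_stats.copy(),
        )
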