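"""Shared fixtures: the heavier simulation designs are session-scoped so the
acceptance-style tests and unit tests reuse one computation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from megamap.pipeline import build_component_map, component_marker_frame
from megamap.simulate import (
    evenly_spaced_true_map,
    simulate_assembly,
    simulate_haploid_family,
)


@pytest.fixture(scope="session")
def order_recovery():
    """Error-free 12 x 80-bin design, n=800: the order-recovery testbed."""
    tm = evenly_spaced_true_map(12, 80, 100.0)
    fam = simulate_haploid_family(tm, "f1", 800, seed=21)
    result = build_component_map(fam.genotypes, seed=22)
    frame = component_marker_frame(result, fam.genotypes.markers)
    return tm, fam, result, frame


@pytest.fixture(scope="session")
def inflation_pair():
    """Matched error-free / 1%-error component maps, 12 x 150 bins, n=300."""
    tm = evenly_spaced_true_map(12, 150, 100.0)
    clean = simulate_haploid_family(tm, "f1", 300, error_rate=0.0, seed=5)
    noisy = simulate_haploid_family(tm, "f1", 300, error_rate=0.01, seed=5)
    res_clean = build_component_map(clean.genotypes, seed=6)
    res_noisy = build_component_map(noisy.genotypes, seed=6)
    return tm, res_clean, res_noisy


@pytest.fixture(scope="session")
def chimera_world():
    """500 drawn scaffolds with 10% planted inter-chimeras on a dense map."""
    tm = evenly_spaced_true_map(12, 250, 50.0)
    scaffolds, tm = simulate_assembly(tm, n_scaffolds=500, inter_chimera_rate=0.10, seed=11)
    fam = simulate_haploid_family(tm, "f1", 400, seed=12)
    result = build_component_map(fam.genotypes, seed=13)
    frame = component_marker_frame(result, fam.genotypes.markers)
    return tm, scaffolds, fam, result, frame


@pytest.fixture(scope="session")
def small_family():
    """Small error-free two-chromosome family for cheap unit tests."""
    tm = evenly_spaced_true_map(2, 30, 100.0)
    fam = simulate_haploid_family(tm, "f1", 300, seed=1)
    return tm, fam
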