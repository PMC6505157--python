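"""Two-point estimates, binning, grouping, RECORD/ripple ordering and the
Kosambi map function, checked against closed forms and exhaustive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megamap.genotypes import HaploidGenotypeMatrix
from megamap.linkage import (
    bin_markers,
    bin_signature_matrix,
    estimate_rf,
    group_markers,
    kosambi,
    kosambi_map,
    order_count,
    order_record,
    pairwise_matrices,
    recombinant_counts,
    ripple_window,
)
from megamap.pipeline import build_component_map
from megamap.simulate import evenly_spaced_true_map, simulate_haploid_family


def _matrix(rows: list[list[int]], ids=None) -> HaploidGenotypeMatrix:
    arr = np.array(rows, dtype=np.int8)
    ids = ids or [f"m{i}" for i in range(arr.shape[0])]
    meta = pd.DataFrame({"marker_id": ids, "scaffold_id": "s", "bp": range(1, arr.shape[0] + 1)})
    return HaploidGenotypeMatrix(arr, meta, [f"x{j}" for j in range(arr.shape[1])])


class TestEstimateRf:
    def test_identical_vectors_lod_closed_form(self):
        sig = np.ones(10, dtype=np.int8)
        est = estimate_rf(sig, sig)
        assert est.r == 0 and est.lod == pytest.approx(10 * math.log10(2))

    def test_two_mismatches_closed_form(self):
        a = np.zeros(10, dtype=np.int8)
        b = np.zeros(10, dtype=np.int8)
        b[:2] = 1
        est = estimate_rf(a, b)
        assert est.r == pytest.approx(0.2)
        expected = 2 * math.log10(0.4) + 8 * math.log10(1.6)
        assert est.lod == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.837, abs=5e-4)

    def test_complement_is_repulsion_phase_r0(self):
        a = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        est = estimate_rf(a, 1 - a)
        assert est.r == 0 and est.phase == "repulsion"

    def test_no_complete_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_rf(np.array([-1, 0], dtype=np.int8), np.array([0, -1], dtype=np.int8))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.choice([-1, 0, 1], size=30).astype(np.int8)
        b = rng.choice([-1, 0, 1], size=30).astype(np.int8)
        if not ((a != -1) & (b != -1)).any():
            return
        assert estimate_rf(a, b) == estimate_rf(b, a)


class TestBinning:
    def test_duplicate_rows_share_bin(self):
        m = _matrix([[0, 1, 0, 1], [0, 1, 0, 1], [1, 1, 0, 0]])
        bins = bin_markers(m)
        sizes = sorted(b.size for b in bins)
        assert sizes == [1, 2]

    def test_single_observed_difference_separates(self):
        m = _matrix([[0, 1, 0, 1], [0, 1, 1, 1]])
        assert len(bin_markers(m)) == 2

    def test_missing_pattern_separates_in_exact_mode(self):
        m = _matrix([[0, 1, 0, 1], [0, 1, -1, 1]])
        assert len(bin_markers(m)) == 2

    def test_representative_prefers_fewest_missing(self):
        # relaxed modes would pick m0; in exact mode equal rows have equal
        # missingness, so the tie falls to the lexicographic marker_id
        m = _matrix([[0, 1, 0, 1], [0, 1, 0, 1]], ids=["mB", "mA"])
        (b,) = bin_markers(m)
        assert b.representative == "mA" and b.bin_id == "mA"


class TestGrouping:
    def test_two_simulated_chromosomes_two_groups(self, small_family):
        _, fam = small_family
        bins = bin_markers(fam.genotypes)
        part = group_markers(bins)
        assert len(part.groups) == 2 and not part.singletons

    def test_chain_transitivity(self):
        rng = np.random.default_rng(1)
        n = 400
        a = rng.integers(0, 2, n).astype(np.int8)
        b = a.copy()
        b[rng.choice(n, 80, replace=False)] ^= 1  # r ~ 0.2 to a
        c = b.copy()
        c[rng.choice(n, 80, replace=False)] ^= 1  # r ~ 0.2 to b, ~ 0.35 to a
        m = _matrix([list(a), list(b), list(c)])
        part = group_markers(bin_markers(m))
        assert len(part.groups) == 1 and len(part.groups[0]) == 3

    def test_unlinked_marker_is_singleton(self):
        rng = np.random.default_rng(2)
        n = 400
        a = rng.integers(0, 2, n).astype(np.int8)
        b = a.copy()
        b[rng.choice(n, 20, replace=False)] ^= 1
        c = rng.integers(0, 2, n).astype(np.int8)
        m = _matrix([list(a), list(b), list(c)])
        part = group_markers(bin_markers(m))
        assert len(part.groups) == 1 and len(part.singletons) == 1


class TestRecord:
    def _six_marker_group(self):
        tm = evenly_spaced_true_map(1, 6, 40.0)
        fam = simulate_haploid_family(tm, "f", 400, seed=8)
        bins = bin_markers(fam.genotypes)
        assert len(bins) == 6
        return bins

    def test_recovers_bruteforce_optimum(self):
        bins = self._six_marker_group()
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
        om = order_record(bins, n_counts=16, seed=0, cnt=cnt)
        best = min(
            order_count(np.array(p), cnt) for p in itertools.permutations(range(6))
        )
        assert om.count_score == best
        # and the optimum is the true order (or its reversal)
        truth = sorted(range(6), key=lambda i: bins[i].bin_id)
        assert om.order in (truth, truth[::-1])

    def test_two_markers_single_order(self):
        m = _matrix([[0, 1, 0, 1], [0, 1, 1, 1]])
        om = order_record(bin_markers(m), seed=0)
        assert len(om.order) == 2

    def test_count_beats_random_shuffle(self):
        bins = self._six_marker_group()
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
        om = order_record(bins, n_counts=4, seed=1, cnt=cnt)
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert om.count_score <= order_count(rng.permutation(6), cnt)


class TestRipple:
    def test_repairs_adjacent_swap(self):
        tm = evenly_spaced_true_map(1, 12, 60.0)
        fam = simulate_haploid_family(tm, "f", 400, seed=9)
        bins = bin_markers(fam.genotypes)
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
        truth = sorted(range(len(bins)), key=lambda i: bins[i].bin_id)
        from megamap.linkage import OrderedMap

        broken = truth.copy()
        broken[4], broken[5] = broken[5], broken[4]
        om = OrderedMap("", broken, bins, np.array([]), np.array([]),
                        order_count(np.array(broken), cnt))
        fixed = ripple_window(om, window=6, seed=0, cnt=cnt)
        assert fixed.order in (truth, truth[::-1])

    def test_count_never_increases(self):
        tm = evenly_spaced_true_map(1, 15, 80.0)
        fam = simulate_haploid_family(tm, "f", 150, error_rate=0.03, seed=10)
        bins = bin_markers(fam.genotypes)
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
        om = order_record(bins, n_counts=2, seed=4, cnt=cnt)
        rippled = ripple_window(om, window=10, seed=5, cnt=cnt)
        assert rippled.count_score <= om.count_score

    def test_optimal_order_unchanged(self):
        bins = bin_markers(
            _matrix([[0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 1, 1], [0, 1, 1, 1, 1, 1]])
        )
        cnt, _ = recombinant_counts(bin_signature_matrix(bins))
        om = order_record(bins, seed=0, cnt=cnt)
        assert ripple_window(om, window=3, seed=1, cnt=cnt).order == om.order


class TestKosambi:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.1, 25 * math.log(1.5)), (0.25, 25 * math.log(3.0))],
    )
    def test_closed_forms(self, r, expected):
        assert kosambi(r) == pytest.approx(expected)
        if r == 0.1:
            assert expected == pytest.approx(10.14, abs=5e-3)
        if r == 0.25:
            assert expected == pytest.approx(27.47, abs=5e-3)

    @given(st.floats(0.0, 0.499))
    @settings(max_examples=50, deadline=None)
    def test_dominates_linear_map(self, r):
        assert kosambi(r) >= 100 * r - 1e-9

    def test_rejects_half(self):
        with pytest.raises(ValueError):
            kosambi(0.5)

    def test_map_positions_cumulative(self, small_family):
        _, fam = small_family
        res = build_component_map(fam.genotypes, seed=2)
        for om in res.maps.values():
            assert om.positions_cM[0] == 0
            assert (np.diff(om.positions_cM) >= 0).all()
            assert om.length_cM == pytest.approx(kosambi(om.adjacent_r).sum())


class TestPairwiseMatrices:
    def test_entries_match_pairwise_estimates(self):
        tm = evenly_spaced_true_map(1, 5, 30.0)
        fam = simulate_haploid_family(tm, "f", 200, seed=11)
        bins = bin_markers(fam.genotypes)
        om = order_record(bins, seed=0)
        r_mat, lod_mat = pairwise_matrices(om)
        sig = bin_signature_matrix(bins)[np.array(om.order)]
        for i in range(len(bins)):
            for j in range(i + 1, len(bins)):
                est = estimate_rf(sig[i], sig[j])
                assert r_mat[i, j] == pytest.approx(est.r)
                assert lod_mat[i, j] == pytest.approx(est.lod)
        assert (np.diag(r_mat) == 0).all()


class TestRecovery:
    def test_partition_preserving(self, order_recovery):
        tm, fam, result, frame = order_recovery
        n_bins = len(bin_markers(fam.genotypes))
        assert result.n_bins_mapped + len(result.singleton_bins) == n_bins

    def test_error_inflates_map_length(self):
        tm = evenly_spaced_true_map(2, 60, 100.0)
        clean = simulate_haploid_family(tm, "f", 300, error_rate=0.0, seed=12)
        noisy = simulate_haploid_family(tm, "f", 300, error_rate=0.01, seed=12)
        len_clean = build_component_map(clean.genotypes, seed=13).total_length_cM()
        len_noisy = build_component_map(noisy.genotypes, seed=13).total_length_cM()
        assert len_noisy > len_clean
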