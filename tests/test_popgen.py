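"""Neutrality statistics against brute-force oracles, VCF hard filtering,
cM anchoring and sliding windows."""

import math

import numpy as np
import pandas as pd
import pytest

from megamap.popgen import (
    ProbeRegion,
    anchor_probes,
    filter_variants,
    neutrality_stats,
    panel_stats,
    sliding_windows,
    tajima_constants,
    zns,
)
from megamap.simulate import simulate_coalescent_probe

# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation)
# ---------------------------------------------------------------------------


def brute_pi_total(haps: np.ndarray) -> float:
    """Mean pairwise difference count over all haplotype pairs (complete data)."""
    n = haps.shape[0]
    total = sum(
        (haps[i] != haps[j]).sum() for i in range(n) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def brute_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype r^2 via D = P11 - p q."""
    p, q = x.mean(), y.mean()
    d = (x * y).mean() - p * q
    return d * d / (p * (1 - p) * q * (1 - q))


class TestTajima:
    def test_ladder_fixture(self):
        # 4 haplotypes, 3 sites forming a cumulative 0/1 ladder
        haps = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=np.int8)
        st = neutrality_stats(haps.T, callable_sites=3, ploidy=1)
        assert st.S == 3
        assert st.pi_total == pytest.approx(10 / 6)
        assert st.pi_total == pytest.approx(brute_pi_total(haps))
        # independent recomputation of the constants gives D ~ +0.168
        k = tajima_constants(4)
        var = k["e1"] * 3 + k["e2"] * 6
        expected = (10 / 6 - 3 / k["a1"]) / math.sqrt(var)
        assert st.tajima_d == pytest.approx(expected)
        assert st.tajima_d == pytest.approx(0.168, abs=1e-3)

    def test_monomorphic_probe(self):
        haps = np.zeros((6, 4), dtype=np.int8)
        st = neutrality_stats(haps.T, ploidy=1)
        assert st.S == 0 and st.pi_per_site == 0 and st.tajima_d is None

    def test_exact_zero_d_fixture(self):
        # n=4: 8 singletons + 3 doubletons gives pi_total = S/a1 exactly
        cols = [[1, 0, 0, 0]] * 8 + [[1, 1, 0, 0]] * 3
        haps = np.array(cols, dtype=np.int8).T  # samples x sites
        st = neutrality_stats(haps.T, ploidy=1)
        assert st.S == 11
        assert st.pi_total == pytest.approx(11 / tajima_constants(4)["a1"])
        assert st.tajima_d == pytest.approx(0.0, abs=1e-12)

    def test_pi_matches_bruteforce_on_random_panels(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            haps = (rng.random((8, 12)) < rng.random(12)).astype(np.int8)
            st = neutrality_stats(haps.T, ploidy=1)
            assert st.pi_total == pytest.approx(brute_pi_total(haps))

    def test_sample_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        haps = (rng.random((10, 15)) < 0.3).astype(np.int8)
        st1 = neutrality_stats(haps.T, ploidy=1)
        st2 = neutrality_stats(haps[rng.permutation(10)].T, ploidy=1)
        assert st1.pi_total == st2.pi_total and st1.tajima_d == st2.tajima_d

    def test_diploid_dosage_equivalent_to_alleles(self):
        # hom-alt diploids carry two alt alleles: frequencies must reflect that
        dosage = np.array([[2, 0, 1, 1]], dtype=np.int8)  # p = 4/8 = 0.5
        st = neutrality_stats(dosage, ploidy=2)
        assert st.S == 1
        assert st.pi_total == pytest.approx(2 * 0.5 * 0.5 * 8 / 7)


class TestZns:
    def test_identical_sites_r2_one(self):
        haps = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        assert zns(haps.T, ploidy=1) == pytest.approx(1.0)

    def test_orthogonal_sites_r2_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        assert zns(haps.T, ploidy=1) == pytest.approx(0.0)

    def test_three_sites_match_bruteforce(self):
        rng = np.random.default_rng(3)
        haps = (rng.random((10, 3)) < 0.4).astype(np.int8)
        while any(len(set(haps[:, j])) < 2 for j in range(3)):
            haps = (rng.random((10, 3)) < 0.4).astype(np.int8)
        expected = np.mean(
            [brute_r2(haps[:, i], haps[:, j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        )
        assert zns(haps.T, ploidy=1) == pytest.approx(expected)

    def test_site_reordering_invariance(self):
        rng = np.random.default_rng(4)
        haps = (rng.random((12, 6)) < 0.5).astype(np.int8)
        a = zns(haps.T, ploidy=1)
        b = zns(haps[:, rng.permutation(6)].T, ploidy=1)
        assert a == pytest.approx(b)

    def test_undefined_below_two_segregating(self):
        assert zns(np.array([[0, 1, 0, 1]], dtype=np.int8), ploidy=1) is None


class TestCoalescentCalibration:
    def test_watterson_consistency(self):
        theta, n, reps = 5.0, 10, 2000
        a1 = sum(1.0 / i for i in range(1, n))
        S = [simulate_coalescent_probe(n, theta, seed=s).n_sites for s in range(reps)]
        se = np.std(S) / math.sqrt(reps)
        assert abs(np.mean(S) / a1 - theta) < 3 * se / a1


def _write_vcf(path, records, samples=("s1", "s2", "s3", "s4")):
    head = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">\n'
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        "##contig=<ID=scf1,length=10000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path.write_text(head + "".join(records))


def _rec(pos, ref="A", alt="G", qd=10, mq=60, dp=500, gts=("0/0", "0/1", "1/1", "0/0")):
    info = f"QD={qd};MQ={mq};DP={dp}"
    return f"scf1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"


class TestFilterVariants:
    def test_toy_vcf_hand_ledger(self, tmp_path):
        regions = [ProbeRegion("p1", "scf1", 100, 220, extension=100)]
        dp = (300, 1600)
        records = [
            _rec(150),                              # keep
            _rec(155, qd=4),                        # QD <= 5
            _rec(160, mq=50),                       # MQ not > 50
            _rec(165, dp=200),                      # DP below range
            _rec(170, dp=1601),                     # DP above range
            _rec(2000),                             # outside extended region
            _rec(175, alt="G,T"),                   # not bi-allelic
            _rec(180, ref="AT", alt="A"),           # indel
            "scf1\t185\t.\tA\tG\t50\tPASS\tMQ=60;DP=500\tGT\t0/0\t0/1\t1/1\t0/0\n",  # no QD
            _rec(190),                              # keep
        ]
        vcf = tmp_path / "panel.vcf"
        _write_vcf(vcf, records)
        res = filter_variants(str(vcf), regions, dp_range=dp)
        assert res.ledger["kept_sites"] == 2
        assert res.ledger["qd"] == 1 and res.ledger["mq"] == 1 and res.ledger["dp"] == 2
        assert res.ledger["outside_regions"] == 1
        assert res.ledger["not_biallelic_snp"] == 2
        assert res.ledger["missing_annotation"] == 1
        assert list(res.sites["pos"]) == [150, 190]

    def test_high_missing_sample_dropped(self, tmp_path):
        regions = [ProbeRegion("p1", "scf1", 100, 220, extension=100)]
        records = [
            _rec(150, gts=("./.", "0/1", "1/1", "0/0")),
            _rec(160, gts=("./.", "0/1", "1/1", "0/0")),
            _rec(170, gts=("0/0", "0/1", "1/1", "0/0")),
        ]
        vcf = tmp_path / "panel.vcf"
        _write_vcf(vcf, records)
        res = filter_variants(str(vcf), regions, dp_range=(300, 1600))
        assert res.ledger["dropped_samples"] == 1  # s1 at 2/3 missing > 0.25
        assert res.samples == ["s2", "s3", "s4"]
        assert res.dosage.shape == (3, 3)


class TestAnchoring:
    consensus = pd.DataFrame(
        {
            "probe_id": ["pA", "pB"],
            "scaffold_id": ["sc1", "sc1"],
            "bp": [100, 300],
            "lg_id": ["LGI", "LGI"],
            "cM": [12.0, 5.0],
        }
    )

    def test_direct_anchor(self):
        probes = pd.DataFrame({"probe_id": ["pA"], "scaffold_id": ["sc1"], "bp": [100]})
        res = anchor_probes(probes, self.consensus)
        assert res.loc[0, "anchor_source"] == "direct" and res.loc[0, "cM"] == 12.0

    def test_nearest_and_tie_to_lower_cm(self):
        probes = pd.DataFrame(
            {"probe_id": ["near", "mid"], "scaffold_id": "sc1", "bp": [120, 200]}
        )
        res = anchor_probes(probes, self.consensus).set_index("probe_id")
        assert res.loc["near", "cM"] == 12.0  # closest by bp
        assert res.loc["mid", "cM"] == 5.0  # equidistant: lower cM wins

    def test_unmapped_scaffold_unassigned(self):
        probes = pd.DataFrame({"probe_id": ["pX"], "scaffold_id": ["other"], "bp": [5]})
        res = anchor_probes(probes, self.consensus)
        assert res.loc[0, "anchor_source"] == "unassigned"


class TestWindows:
    def test_single_probe_window_membership(self):
        anchored = pd.DataFrame({"lg_id": ["LGI"], "cM": [10.5], "v": [2.0]})
        track = sliding_windows(anchored, "v", width_cM=10, step_cM=1)
        hit = track[track["n_probes"] > 0]
        assert list(hit["start_cM"]) == list(np.arange(1.0, 11.0))  # starts 1..10
        assert (hit["mean"] == 2.0).all()

    def test_constant_statistic_constant_windows(self):
        anchored = pd.DataFrame(
            {"lg_id": "LGI", "cM": np.linspace(0, 30, 40), "v": 3.14}
        )
        track = sliding_windows(anchored, "v")
        assert track["mean"].dropna().unique() == pytest.approx([3.14])
        widths = track["end_cM"] - track["start_cM"]
        assert (widths == 10.0).all()

    def test_empty_lg_empty_track(self):
        anchored = pd.DataFrame({"lg_id": [], "cM": [], "v": []})
        assert sliding_windows(anchored, "v").empty

    def test_bad_width_rejected(self):
        anchored = pd.DataFrame({"lg_id": ["LGI"], "cM": [1.0], "v": [1.0]})
        with pytest.raises(ValueError):
            sliding_windows(anchored, "v", width_cM=0)


class TestPanelStats:
    def test_panel_wrapper_matches_direct_call(self):
        p = simulate_coalescent_probe(12, 4.0, seed=6)
        st = panel_stats(p)
        assert st.S == p.n_sites
        assert st.n_samples == 12
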