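"""Codon-usage metrics, NG86 rates vs a brute-force oracle, filters, tests."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from zstrata import codonevol, simdata
from zstrata.codonevol import (
    accelerated_genes,
    codon_usage_metrics,
    default_optimal_codons,
    filter_rates,
    hypergeom_enrichment,
    lineage_rates,
    ng86_rates,
    RateEstimate,
)

# ---------------------------------------------------------------------------
# independent oracle: enumeration with Biopython translation

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _oracle_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    total = 0.0
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        muts = [m for m in muts if m not in _STOPS]
        if not muts:
            continue
        total += 1
        syn += sum(1 for m in muts if _aa(m) == _aa(codon)) / len(muts)
    return syn, total - syn


def _oracle_diffs(c1: str, c2: str) -> tuple[float, float]:
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    n = 0
    for order in itertools.permutations(pos):
        cur, s, ns, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                ns += 1
            cur = nxt
        if ok:
            syn += s
            nonsyn += ns
            n += 1
    if n == 0:
        return len(pos) / 2.0, len(pos) / 2.0
    return syn / n, nonsyn / n


SENSE = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)


class TestNG86Oracle:
    def test_site_and_difference_counts_match_enumeration(self):
        # 500 random codon pairs: exact agreement of S, N, Sd, Nd
        rnd = random.Random(99)
        for _ in range(500):
            c1, c2 = rnd.choice(SENSE), rnd.choice(SENSE)
            s1o, _ = _oracle_sites(c1)
            s2o, _ = _oracle_sites(c2)
            if s1o + s2o == 0:
                # a lone Met/Trp pair has no synonymous opportunity at all
                with pytest.raises(ValueError, match="zero synonymous"):
                    ng86_rates(c1, c2, gene_id="pair")
                continue
            est = ng86_rates(c1, c2, gene_id="pair")
            s1, n1 = _oracle_sites(c1)
            s2, n2 = _oracle_sites(c2)
            sd, nd = _oracle_diffs(c1, c2)
            assert est.syn_sites == pytest.approx((s1 + s2) / 2, abs=1e-12)
            assert est.nonsyn_sites == pytest.approx((n1 + n2) / 2, abs=1e-12)
            assert est.syn_diffs == pytest.approx(sd, abs=1e-12)
            assert est.nonsyn_diffs == pytest.approx(nd, abs=1e-12)

    def test_identical_pair_zero_rates(self):
        cds = "ATGGCTAGCGTT" * 20
        r = ng86_rates(cds, cds)
        assert r.dn == 0.0 and r.ds == 0.0

    def test_synonymous_only_changes(self):
        # GCT->GCC: a third-position synonymous swap in one codon per repeat
        a = "ATGGCTAAAGGT" * 10
        b = "ATGGCCAAAGGT" * 10
        r = ng86_rates(a, b)
        assert r.dn == 0.0
        assert r.ds > 0.0

    def test_omega_recovery_under_purifying_selection(self):
        oms = []
        for i in range(60):
            s1, s2 = simdata.simulate_coding_pair(300, 0.2, rng=4000 + i)
            oms.append(ng86_rates(s1, s2).omega)
        assert 0.15 <= np.mean(oms) <= 0.25

    def test_gapped_codons_dropped_codonwise(self):
        a = "ATG---GCTAAA"
        b = "ATGCCCGCTAAA"
        r = ng86_rates(a, b)
        # 3 usable codons x 3 sites each; the gapped codon column is excluded
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(9.0)
        assert r.ds == 0.0 and r.dn == 0.0


class TestCodonUsage:
    def test_all_optimal_cds(self):
        opt = default_optimal_codons()
        cds = "".join(sorted(opt)[:10])
        m = codon_usage_metrics(cds, opt)
        assert m.fop == 1.0
        assert m.cbi == pytest.approx(1.0)

    def test_uniform_synonymous_usage_gives_cbi_zero(self):
        # every Phe codon equally often: Nopt == Nrand exactly
        m = codon_usage_metrics("TTTTTC", {"TTC"})
        assert m.cbi == pytest.approx(0.0, abs=1e-12)
        assert m.fop == pytest.approx(0.5)

    def test_gc3_of_atg_gcc(self):
        m = codon_usage_metrics("ATGGCC", set())
        assert m.gc3 == 1.0

    def test_internal_stop_reports_position(self):
        with pytest.raises(ValueError, match="codon 1"):
            codon_usage_metrics("ATGTAAGCC", set())

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            codon_usage_metrics("ATGGC", set())

    def test_invariant_to_codon_order_shuffle(self, rng):
        codons = ["GCC", "GCT", "AAA", "AAG", "TTC", "GGG"] * 5
        opt = default_optimal_codons()
        base = codon_usage_metrics("".join(codons), opt)
        perm = list(codons)
        rng.shuffle(perm)
        shuf = codon_usage_metrics("".join(perm), opt)
        assert shuf.fop == base.fop
        assert shuf.cbi == base.cbi
        assert shuf.gc3 == base.gc3

    def test_gci_from_intron(self):
        m = codon_usage_metrics("ATGGCC", set(), introns="GGCCAATT")
        assert m.gci == pytest.approx(0.5)


class TestLineageRates:
    def test_focal_equals_sister_zero_branch(self):
        s1, s2 = simdata.simulate_coding_pair(150, 1.0, rng=7)
        rf, rs = lineage_rates(s1, s1, s2)
        assert rf.ds == pytest.approx(0.0, abs=1e-9)
        assert rf.dn == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_rates_balanced(self):
        dfs, dss = [], []
        for i in range(25):
            f, s, o = simdata.simulate_coding_triplet(300, 1.0, 0.2, 0.2, 0.4, rng=i)
            rf, rs = lineage_rates(f, s, o)
            dfs.append(rf.ds + rf.dn)
            dss.append(rs.ds + rs.dn)
        assert np.mean(dfs) == pytest.approx(np.mean(dss), rel=0.15)

    def test_accelerated_focal_branch_ratio(self):
        dfs, dss = [], []
        for i in range(25):
            f, s, o = simdata.simulate_coding_triplet(300, 1.0, 0.3, 0.1, 0.4, rng=100 + i)
            rf, rs = lineage_rates(f, s, o)
            dfs.append(rf.ds)
            dss.append(rs.ds)
        assert np.mean(dfs) / np.mean(dss) == pytest.approx(3.0, rel=0.25)


class TestRateFilter:
    @pytest.mark.parametrize(
        "dn,ds,expected",
        [
            (0.01, 0.1, True),
            (0.0005, 0.1, False),  # dN below 0.001
            (0.01, 2.5, False),  # dS above 2
            (0.001, 2.0, True),  # inclusive bounds survive
        ],
    )
    def test_threshold_rules(self, dn, ds, expected):
        r = RateEstimate("g", dn, ds, None, 1, 1, 0, 0)
        flagged, passing = filter_rates([r])
        assert flagged[0].pass_filter is expected
        assert (len(passing) == 1) is expected

    def test_idempotent(self):
        rates = [
            RateEstimate(f"g{i}", dn, ds, None, 1, 1, 0, 0)
            for i, (dn, ds) in enumerate([(0.01, 0.1), (3.0, 0.1), (0.1, 0.0005)])
        ]
        once, _ = filter_rates(rates)
        twice, _ = filter_rates(once)
        assert [r.pass_filter for r in once] == [r.pass_filter for r in twice]


class TestAcceleratedGenes:
    def test_zero_differences_skipped(self):
        cds = "ATGGCTAGC" * 10
        with pytest.warns(UserWarning, match="zero informative"):
            out = accelerated_genes({"g": (cds, cds, cds)})
        assert out.empty

    def test_equal_rates_not_flagged_in_most_replicates(self):
        flags = []
        for i in range(40):
            f, s, o = simdata.simulate_coding_triplet(200, 1.0, 0.2, 0.2, 0.4, rng=500 + i)
            res = accelerated_genes({"g": (f, s, o)}, p_cut=0.05)
            flags.append(bool(res.iloc[0]["accelerated"]))
        assert np.mean(flags) < 0.2

    def test_fivefold_acceleration_detected(self):
        flags = []
        for i in range(25):
            f, s, o = simdata.simulate_coding_triplet(300, 1.0, 0.5, 0.1, 0.4, rng=800 + i)
            res = accelerated_genes({"g": (f, s, o)}, p_cut=0.05)
            flags.append(bool(res.iloc[0]["accelerated"]))
        assert np.mean(flags) > 0.8


class TestEnrichment:
    @pytest.fixture
    def term_map(self):
        rows = [{"gene": f"g{i}", "term": "common"} for i in range(100)]
        rows += [{"gene": f"g{i}", "term": "rare"} for i in range(5)]
        return pd.DataFrame(rows)

    def test_extreme_enrichment_small_p(self, term_map):
        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(5)}  # exactly the 'rare' genes
        out = hypergeom_enrichment(fg, bg, term_map)
        rare = out[out.term == "rare"].iloc[0]
        assert rare["p"] < 1e-6
        assert rare["significant"]

    def test_brute_force_tail_matches(self, term_map):
        # P(X >= k) by direct summation of the hypergeometric pmf
        from math import comb

        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(0, 20)}
        out = hypergeom_enrichment(fg, bg, term_map)
        row = out[out.term == "rare"].iloc[0]
        N, K, n, k = 100, 5, 20, int(row["fg_count"])
        tail = sum(
            comb(K, x) * comb(N - K, n - x) / comb(N, n)
            for x in range(k, min(K, n) + 1)
        )
        assert row["p"] == pytest.approx(tail, rel=1e-9)

    def test_term_absent_from_foreground_large_p(self, term_map):
        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(10, 15)}  # misses all 'rare' genes
        out = hypergeom_enrichment(fg, bg, term_map)
        assert out[out.term == "rare"].iloc[0]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_foreground_rejected(self, term_map):
        with pytest.raises(ValueError, match="empty foreground"):
            hypergeom_enrichment(set(), {"g1"}, term_map)

    def test_foreground_outside_background_rejected(self, term_map):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrichment({"zzz"}, {"g1"}, term_map)
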