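"""Window scan, boundary detection, stratum dating, gene assignment."""

import math

import numpy as np
import pytest

from zstrata import simdata, strata
from zstrata.simdata import SimConfig, StratumSpec
from zstrata.strata import (
    Stratum,
    StratumMap,
    WindowDivergence,
    assign_genes_to_strata,
    classify_stratum_age,
    detect_boundaries,
    window_scan,
)

import pandas as pd


def _uniform_windows(level, n=40, sd=0.0, seed=0, wlen=10_000):
    rng = np.random.default_rng(seed)
    vals = level + rng.normal(0, sd, size=n) if sd else np.full(n, float(level))
    return [
        WindowDivergence(i, i * wlen, (i + 1) * wlen, float(max(v, 0)), 5000)
        for i, v in enumerate(vals)
    ]


class TestWindowScan:
    def test_uniform_divergence_recovers_jc_corrected_level(self, rng):
        # 5% raw mismatch -> JC-corrected ~0.0517 in every window
        n = 200_000
        z = simdata._arr_to_str(simdata._random_seq_array(rng, n))
        zl = np.frombuffer(z.encode(), dtype="S1").copy()
        w = simdata._jc_mutate_array(zl, -0.75 * math.log(1 - 4 * 0.05 / 3), rng)
        wins = window_scan((z, simdata._arr_to_str(w)), window_len=20_000)
        expected = -0.75 * math.log(1 - 4 * 0.05 / 3)
        for wd in wins:
            assert wd.divergence == pytest.approx(expected, abs=0.01)

    def test_par_windows_zero(self, rng):
        z = simdata._arr_to_str(simdata._random_seq_array(rng, 50_000))
        wins = window_scan((z, z), window_len=10_000)
        assert all(wd.divergence == 0.0 for wd in wins)

    def test_all_gap_window_flagged(self, rng):
        z = simdata._arr_to_str(simdata._random_seq_array(rng, 2000))
        zz = z + "-" * 2000 + z
        ww = z + "-" * 2000 + z
        wins = window_scan((zz, ww), window_len=2000, min_sites=100)
        assert [wd.usable for wd in wins] == [True, False, True]

    def test_no_usable_windows_raises(self):
        with pytest.raises(ValueError, match="no usable windows"):
            window_scan(("-" * 5000, "-" * 5000), window_len=1000)

    def test_window_len_floor(self):
        with pytest.raises(ValueError, match="1 kb"):
            window_scan(("ACGT" * 300, "ACGT" * 300), window_len=500)


class TestBoundaryDetection:
    def test_single_step_recovered_near_truth(self, two_strata_cfg):
        gt, pair, _ = simdata.simulate_strata_chromosome(
            two_strata_cfg, gene_span=2000, gametologs_per_stratum=0
        )
        smap = detect_boundaries(
            window_scan(pair, window_len=10_000), flank=10, min_gap=50_000
        )
        assert len(smap) == 2
        boundary = smap.strata[1].start
        assert abs(boundary - 200_000) <= 20_000  # within +/-2 windows
        assert smap.strata[0].stratum_id == "S0"
        assert smap.strata[0].median_divergence > smap.strata[1].median_divergence

    def test_constant_divergence_yields_no_boundaries(self):
        smap = detect_boundaries(_uniform_windows(0.2, sd=0.01, seed=3), flank=10)
        assert len(smap) == 1

    def test_two_steps_three_ordered_strata(self):
        cfg = SimConfig(
            strata_spec=(
                StratumSpec("S0", 100, 0.30),
                StratumSpec("S1", 100, 0.12),
                StratumSpec("PAR", 100, 0.0),
            ),
            seed=21,
        )
        _, pair, _ = simdata.simulate_strata_chromosome(
            cfg, gene_span=2000, gametologs_per_stratum=0
        )
        smap = detect_boundaries(
            window_scan(pair, window_len=10_000), flank=10, min_gap=50_000
        )
        assert [s.stratum_id for s in smap.strata] == ["S0", "S1", "PAR"]
        meds = [s.median_divergence for s in smap.strata]
        assert meds == sorted(meds, reverse=True)

    def test_flank_too_large_raises(self):
        with pytest.raises(ValueError, match="flank"):
            detect_boundaries(_uniform_windows(0.2, n=10), flank=10)

    def test_map_tiles_without_gaps(self, two_strata_cfg):
        _, pair, _ = simdata.simulate_strata_chromosome(
            two_strata_cfg, gene_span=2000, gametologs_per_stratum=0
        )
        smap = detect_boundaries(
            window_scan(pair, window_len=10_000), flank=10, min_gap=50_000
        )
        for a, b in zip(smap.strata, smap.strata[1:]):
            assert a.end == b.start


@pytest.fixture(scope="module")
def gametologs():
    cfg = SimConfig(
        strata_spec=(
            StratumSpec("S0", 10, 0.40, 0.0),  # Z/W split before speciation
            StratumSpec("S2", 10, 0.02, 0.5),  # after speciation
        ),
        seed=31,
    )
    _, _, gam = simdata.simulate_strata_chromosome(
        cfg, species_divergence=0.10, n_species=3
    )
    return gam


class TestStratumAge:
    def test_ancestral_and_lineage_specific_recovered(self, gametologs):
        for gid, seqs in gametologs.items():
            expected = "ancestral" if gid.startswith("S0") else "lineage-specific"
            assert classify_stratum_age(seqs) == expected

    def test_invariant_to_order_and_species_labels(self, gametologs):
        gid, seqs = next(iter(gametologs.items()))
        ref = classify_stratum_age(seqs)
        shuffled = dict(reversed(list(seqs.items())))
        assert classify_stratum_age(shuffled) == ref
        relabeled = {
            name.replace("sp0", "zebrafinch").replace("sp1", "ostrich").replace(
                "sp2", "emu"
            ): s
            for name, s in seqs.items()
        }
        assert classify_stratum_age(relabeled) == ref

    def test_conflicting_topology_unknown(self, rng):
        # sp0's Z/W pair coalesces recently (lineage-specific signal) while
        # sp1/sp2 show the ancestral pattern: neither topology class fits
        anc = simdata._random_seq_array(rng, 600)
        za = simdata._jc_mutate_array(anc, 0.2, rng)
        wa = simdata._jc_mutate_array(anc, 0.2, rng)
        sp0 = simdata._jc_mutate_array(anc, 0.05, rng)
        seqs = {
            "sp0_Z": simdata._arr_to_str(simdata._jc_mutate_array(sp0, 0.01, rng)),
            "sp0_W": simdata._arr_to_str(simdata._jc_mutate_array(sp0, 0.01, rng)),
            "sp1_Z": simdata._arr_to_str(simdata._jc_mutate_array(za, 0.02, rng)),
            "sp2_Z": simdata._arr_to_str(simdata._jc_mutate_array(za, 0.02, rng)),
            "sp1_W": simdata._arr_to_str(simdata._jc_mutate_array(wa, 0.02, rng)),
            "sp2_W": simdata._arr_to_str(simdata._jc_mutate_array(wa, 0.02, rng)),
        }
        assert classify_stratum_age(seqs) == "unknown"

    def test_single_complete_species_rejected(self):
        with pytest.raises(ValueError, match=">= 2 species"):
            classify_stratum_age({"sp0_Z": "ACGT", "sp0_W": "ACGT", "sp1_Z": "ACGT"})


class TestGeneAssignment:
    @pytest.fixture
    def smap(self):
        return StratumMap(
            [Stratum("S0", 0, 150, 0.3), Stratum("S1", 150, 300, 0.1)]
        )

    def test_midpoint_on_boundary_goes_right(self, smap):
        # gene [100, 200): midpoint 150 lies in the half-open [150, 300)
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "Z", "start": 100, "end": 200}]
        )
        out = assign_genes_to_strata(genes, smap)
        assert out.loc[0, "stratum"] == "S1"

    def test_fully_contained_gene(self, smap):
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "Z", "start": 10, "end": 50}])
        assert assign_genes_to_strata(genes, smap).loc[0, "stratum"] == "S0"

    def test_gene_beyond_end_flagged(self, smap):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "Z", "start": 400, "end": 500}]
        )
        with pytest.warns(UserWarning, match="outside"):
            out = assign_genes_to_strata(genes, smap)
        assert out.loc[0, "stratum"] == "."
        assert not out.loc[0, "in_strata"]

    def test_tiling_invariant_enforced(self):
        with pytest.raises(ValueError, match="tile"):
            StratumMap([Stratum("S0", 0, 100, 0.3), Stratum("S1", 120, 200, 0.1)])
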