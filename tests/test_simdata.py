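"""Generator-level checks: closed-form expectations, symmetries, validation."""

import numpy as np
import pytest

from zstrata import malebias, simdata
from zstrata.simdata import SimConfig, StratumSpec


class TestConfigValidation:
    def test_nonincreasing_strata_divergence_rejected(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            SimConfig(
                strata_spec=(StratumSpec("S0", 10, 0.1), StratumSpec("S1", 10, 0.2))
            )

    def test_unknown_dc_regime_rejected(self):
        with pytest.raises(ValueError, match="dc_regime"):
            SimConfig(dc_regime="sometimes")

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(alpha_true=0.0)

    def test_w_retained_bounds(self):
        with pytest.raises(ValueError):
            StratumSpec("S0", 10, 0.2, w_retained=1.5)


class TestIntronAlignments:
    def test_zero_loci_warns_and_returns_empty(self):
        cfg = SimConfig(n_loci_z=0, n_loci_a=0)
        with pytest.warns(UserWarning, match="zero loci"):
            aln = simdata.simulate_intron_alignments(cfg)
        assert len(aln) == 0

    def test_sequences_are_acgt_only(self):
        cfg = SimConfig(n_loci_z=3, n_loci_a=3, locus_len=200, seed=0)
        for locus in simdata.simulate_intron_alignments(cfg):
            for s in locus.seqs:
                assert set(s) <= set("ACGT")

    def test_no_sex_bias_gives_equal_class_divergence(self):
        # alpha = 1: male and female rates equal, so Z and A rates coincide
        cfg = SimConfig(alpha_true=1.0, n_loci_z=300, n_loci_a=300, seed=2)
        assert simdata.expected_divergence(cfg, "Z") == pytest.approx(
            simdata.expected_divergence(cfg, "A")
        )
        aln = simdata.simulate_intron_alignments(cfg)
        dz = np.mean([malebias.pairwise_distance(l).distance for l in aln.subset("Z")])
        da = np.mean([malebias.pairwise_distance(l).distance for l in aln.subset("A")])
        assert dz == pytest.approx(da, rel=0.05)

    def test_male_limit_ratio_approaches_four_thirds(self):
        cfg = SimConfig(alpha_true=1e9)
        ratio = simdata.expected_divergence(cfg, "Z") / simdata.expected_divergence(
            cfg, "A"
        )
        assert ratio == pytest.approx(4.0 / 3.0, rel=1e-6)

    def test_divergence_ratio_matches_closed_form(self):
        # alpha=2, mu_f=0.01, t=10: ratio (2a+1)*2 / (3(a+1)) = 10/9,
        # checked within 3 Monte-Carlo standard errors of the per-class means
        cfg = SimConfig(
            alpha_true=2.0, female_rate=0.01, divergence_time=10.0,
            n_loci_z=500, n_loci_a=500, locus_len=1000, seed=3,
        )
        aln = simdata.simulate_intron_alignments(cfg)
        dz = np.array([malebias.pairwise_distance(l).distance for l in aln.subset("Z")])
        da = np.array([malebias.pairwise_distance(l).distance for l in aln.subset("A")])
        for vals, expected in ((dz, simdata.expected_divergence(cfg, "Z")),
                               (da, simdata.expected_divergence(cfg, "A"))):
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 3 * se
        assert dz.mean() / da.mean() == pytest.approx(10.0 / 9.0, rel=0.02)


class TestWrightFisher:
    def test_nonpositive_mutation_rate_rejected(self):
        with pytest.raises(ValueError, match="mut_rate"):
            simdata.simulate_zw_population(SimConfig(), mut_rate=0.0)

    def test_insufficient_burnin_rejected(self):
        with pytest.raises(ValueError, match="generations"):
            simdata.simulate_zw_population(SimConfig(), generations=100)

    def test_tiny_population_produces_diversity(self):
        cfg = SimConfig(pop_n_males=8, pop_n_females=8, seed=4)
        res = simdata.simulate_zw_population(cfg, n_loci=4, mut_rate=1e-4)
        assert res["pi_z"] > 0 and res["pi_a"] > 0

    def test_harem_mating_depresses_z_diversity(self):
        # few breeding males: Ne_Z/Ne_A = 9NmNf/((2Nm+4Nf)*4NmNf/(Nm+Nf))
        # drops well below 3/4 (here ~0.58)
        cfg = SimConfig(pop_n_males=4, pop_n_females=50, seed=6)
        res = simdata.simulate_zw_population(
            cfg, generations=1200, n_loci=40, rng=np.random.default_rng(60)
        )
        assert res["ratio"] < 0.75


class TestStrataChromosome:
    def test_needs_two_strata(self):
        cfg = SimConfig(strata_spec=(StratumSpec("S0", 10, 0.3),))
        with pytest.raises(ValueError, match=">= 2 strata"):
            simdata.simulate_strata_chromosome(cfg)

    def test_par_region_identical_zw(self, two_strata_cfg):
        cfg = SimConfig(
            strata_spec=(StratumSpec("S0", 20, 0.3), StratumSpec("PAR", 20, 0.0)),
            seed=7,
        )
        gt, (z, w), _ = simdata.simulate_strata_chromosome(cfg, gene_span=2000)
        par_start = gt[gt.stratum_true == "PAR"]["start"].min()
        assert z[par_start:] == w[par_start:]
        assert z[:par_start] != w[:par_start]

    def test_step_means_differ_by_construction(self, two_strata_cfg):
        gt, (z, w), _ = simdata.simulate_strata_chromosome(
            two_strata_cfg, gene_span=2000, noise_sd=0.02
        )
        from zstrata import strata as st

        wins = st.window_scan((z, w), window_len=10_000)
        divs = np.array([wd.divergence for wd in wins])
        left, right = divs[:20].mean(), divs[20:].mean()
        assert left - right == pytest.approx(0.2, abs=0.03)

    def test_ancestral_gametologs_cluster_by_chromosome(self, two_strata_cfg):
        _, _, gam = simdata.simulate_strata_chromosome(two_strata_cfg)
        # S0 divergence 0.30 >> species divergence 0.05: Z-Z < Z-W always
        for gid, seqs in gam.items():
            if not gid.startswith("S0"):
                continue
            zz = malebias.pairwise_distance(
                simdata.Locus("p", "Z", (seqs["sp0_Z"], seqs["sp1_Z"]))
            ).distance
            for pair in (("sp0_Z", "sp0_W"), ("sp1_Z", "sp1_W"), ("sp0_Z", "sp1_W")):
                zw = malebias.pairwise_distance(
                    simdata.Locus("p", "Z", (seqs[pair[0]], seqs[pair[1]]))
                ).distance
                assert zz < zw


class TestExpressionGenerator:
    @pytest.mark.parametrize(
        "regime,wret,expected",
        [("global", 0.0, 1.0), ("none", 0.0, 2.0), ("none", 1.0, 1.0)],
    )
    def test_expected_mf_ratio_by_regime(self, regime, wret, expected):
        cfg = SimConfig(
            dc_regime=regime,
            strata_spec=(
                StratumSpec("S0", 300, 0.3, wret),
                StratumSpec("PAR", 10, 0.0, 1.0),
            ),
            seed=8,
        )
        counts, samples, genes = simdata.simulate_expression(cfg, n_samples_per_sex=6)
        male = counts.loc[:, samples[samples.sex == "male"]["sample"]].mean(axis=1)
        female = counts.loc[:, samples[samples.sex == "female"]["sample"]].mean(axis=1)
        s0 = genes[genes.stratum == "S0"]["gene_id"]
        ratio = (male[s0] + 1) / (female[s0] + 1)
        assert np.median(ratio) == pytest.approx(expected, rel=0.15)


class TestDepthProfile:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simdata.simulate_depth_profile("male", 0.0)
        with pytest.raises(ValueError):
            simdata.simulate_depth_profile("intersex", 30.0)

    @pytest.mark.parametrize("sex,expected", [("male", 1.0), ("female", 0.5)])
    def test_depth_ratio_by_sex(self, sex, expected):
        df = simdata.simulate_depth_profile(sex, 40.0, rng=9, n_windows=1000)
        z = df[df.chrom == "Z"]["depth"].mean()
        a = df[df.chrom != "Z"]["depth"].mean()
        # Poisson(40) over 1000 windows: 3 sd of the ratio is well under 0.03
        assert z / a == pytest.approx(expected, abs=0.03)


class TestTraits:
    def test_rejects_negative_branch_lengths(self):
        with pytest.raises(ValueError, match="negative"):
            simdata.simulate_traits(
                "(((a:1,b:-1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);",
                1.0,
                0.5,
            )

    def test_rejects_too_few_tips(self):
        with pytest.raises(ValueError, match=">= 8 tips"):
            simdata.simulate_traits("((a:1,b:1):1,(c:1,d:1):1);", 1.0, 0.5)

    def test_zero_slope_centered_at_zero(self, small_tree):
        from zstrata import phylotraits

        slopes = []
        rng = np.random.default_rng(10)
        for _ in range(40):
            tt = simdata.simulate_traits(small_tree, 1.0, 0.0, seed=rng)
            fit = phylotraits.pgls(
                tt["response"], tt["predictor"], small_tree, species=tt["species"]
            )
            slopes.append(fit.slope)
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes)) + 0.05

    def test_lambda_zero_residuals_lack_phylo_signal(self, small_tree):
        # white-noise response: ML lambda for the residual trait stays low
        from zstrata import phylotraits

        tt = simdata.simulate_traits(small_tree, 0.0, 0.0, seed=12)
        fit = phylotraits.fit_lambda(
            tt["response"], small_tree, species=tt["species"]
        )
        assert fit.lambda_ < 0.5
        assert fit.p_lambda1 < 0.05
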