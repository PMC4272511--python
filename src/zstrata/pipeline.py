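"""End-to-end orchestration of the synthetic analysis pipeline.

Runs the stages in dependency order (simulate -> alpha -> strata ->
codon/rates -> popgen -> expression -> traits) on generated data, writes
per-stage TSVs and a machine-readable run manifest. Identical configuration
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, codonevol, expression, io, malebias, popgen, strata
from . import phylotraits, simdata

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("alpha", "strata", "codon", "popgen", "expression", "traits")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "zstrata_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    alpha_true: float = 2.0
    n_loci: int = 300
    locus_len: int = 1000
    n_boot: int = 1000
    wf_n_loci: int = 10
    wf_pop_per_sex: int = 20
    n_tips: int = 20

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid: {list(STAGES)}")
        if not self.stages:
            raise ValueError("no stages enabled")


def _sim_config(cfg: PipelineConfig) -> simdata.SimConfig:
    return simdata.SimConfig(
        alpha_true=cfg.alpha_true,
        n_loci_z=cfg.n_loci,
        n_loci_a=cfg.n_loci,
        locus_len=cfg.locus_len,
        pop_n_males=cfg.wf_pop_per_sex,
        pop_n_females=cfg.wf_pop_per_sex,
        seed=cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest dictionary.

    Any stage error halts the run with :class:`PipelineError` naming the
    stage; outputs of completed stages are preserved on disk.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = _sim_config(cfg)
    manifest: dict = {
        "tool": "zstrata",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, results: dict, files: list[str]) -> None:
        manifest["stages"][stage] = results
        manifest["outputs"].extend(files)

    stage = "simulate"
    try:
        rng = np.random.default_rng(cfg.seed)
        aln = simdata.simulate_intron_alignments(scfg, rng=rng)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(stage, exc)

    if "alpha" in cfg.stages:
        stage = "alpha"
        try:
            est = malebias.bootstrap_alpha(aln, n_boot=cfg.n_boot, seed=cfg.seed)
            df = pd.DataFrame(
                [
                    {
                        "species": "synthetic",
                        "n_loci_z": cfg.n_loci,
                        "n_loci_a": cfg.n_loci,
                        "median_z": est.median_z,
                        "median_a": est.median_a,
                        "ratio": est.ratio_za,
                        "alpha": est.alpha,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                ]
            )
            io.write_tsv(out / "alpha.tsv", df)
            record(
                "alpha",
                {"alpha": est.alpha, "ci": [est.ci_low, est.ci_high], "alpha_true": cfg.alpha_true},
                ["alpha.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    smap = None
    gene_table = None
    if "strata" in cfg.stages:
        stage = "strata"
        try:
            gene_table, (z_seq, w_seq), gametologs = simdata.simulate_strata_chromosome(
                scfg, rng=np.random.default_rng(cfg.seed + 1)
            )
            windows = strata.window_scan((z_seq, w_seq), window_len=100_000)
            smap = strata.detect_boundaries(windows, flank=10, min_gap=500_000)
            ages = {
                gid: strata.classify_stratum_age(seqs) for gid, seqs in gametologs.items()
            }
            assigned = strata.assign_genes_to_strata(gene_table, smap)
            smap.to_bed().to_csv(out / "strata.bed", sep="\t", index=False, header=False)
            io.write_tsv(out / "genes_strata.tsv", assigned)
            record(
                "strata",
                {
                    "n_strata": len(smap),
                    "boundaries": [s.start for s in smap.strata[1:]],
                    "gametolog_ages": ages,
                },
                ["strata.bed", "genes_strata.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    if "codon" in cfg.stages:
        stage = "codon"
        try:
            rngc = np.random.default_rng(cfg.seed + 2)
            rate_rows = []
            metric_rows = []
            for i in range(40):
                omega = 0.2 if i < 20 else 1.0
                s1, s2 = simdata.simulate_coding_pair(200, omega, rng=rngc)
                r = codonevol.ng86_rates(s1, s2, gene_id=f"gene_{i:03d}")
                rate_rows.append(r)
                m = codonevol.codon_usage_metrics(s1, gene_id=f"gene_{i:03d}")
                metric_rows.append(m)
            flagged, passing = codonevol.filter_rates(rate_rows)
            rates_df = pd.DataFrame([dataclasses.asdict(r) for r in flagged])
            metrics_df = pd.DataFrame([dataclasses.asdict(m) for m in metric_rows])
            io.write_tsv(out / "rates.tsv", rates_df)
            io.write_tsv(out / "codon_metrics.tsv", metrics_df)
            record(
                "codon",
                {
                    "n_genes": len(flagged),
                    "n_pass_filter": len(passing),
                    "mean_omega_constrained": float(
                        np.nanmean([r.omega for r in passing[:20] if r.omega is not None])
                    ),
                },
                ["rates.tsv", "codon_metrics.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    if "popgen" in cfg.stages:
        stage = "popgen"
        try:
            wf = simdata.simulate_zw_population(
                scfg,
                generations=20 * 2 * cfg.wf_pop_per_sex,
                n_loci=cfg.wf_n_loci,
                rng=np.random.default_rng(cfg.seed + 3),
            )
            # toy SNP table exercising the filters on the way to densities
            rngp = np.random.default_rng(cfg.seed + 4)
            snp_rows = []
            regions = []
            for cls, dens in (("Z", 3.0), ("A", 4.0)):
                for g in range(60):
                    start, end = g * 2000, (g + 1) * 2000
                    regions.append(
                        {
                            "region_id": f"{cls}_r{g}",
                            "chrom": cls,
                            "start": start,
                            "end": end,
                            "chrom_class": cls,
                        }
                    )
                    n = rngp.poisson(dens * 2)
                    pos = np.sort(rngp.choice(2000, size=min(n, 2000), replace=False)) + start
                    for p in pos:
                        snp_rows.append(
                            {
                                "chrom": cls,
                                "pos": int(p),
                                "depth": int(rngp.poisson(30)),
                                "ref": "A",
                                "alt": "G",
                            }
                        )
            snps = pd.DataFrame(snp_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
            filtered = popgen.filter_snps(snps)
            per_region, summary = popgen.snp_density(filtered, pd.DataFrame(regions))
            io.write_tsv(out / "snp_density.tsv", per_region)
            record(
                "popgen",
                {
                    "pi_z": wf["pi_z"],
                    "pi_a": wf["pi_a"],
                    "pi_ratio_za": wf["ratio"],
                    "snp_density_ratio_za": summary["ratio_za"],
                    "n_snps_in": len(snps),
                    "n_snps_kept": len(filtered),
                },
                ["snp_density.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    if "expression" in cfg.stages:
        stage = "expression"
        try:
            counts, samples, genes = simdata.simulate_expression(
                scfg, rng=np.random.default_rng(cfg.seed + 5)
            )
            # fixed library size: mapped-fragment totals are genome-wide in
            # real data, so the simulated gene subset must not renormalize them
            totals = pd.Series(1e6, index=counts.columns)
            fpkm = expression.fpkm(
                counts, genes.set_index("gene_id")["length"], totals
            )
            sex = samples.set_index("sample")["sex"]
            ratios = expression.mf_ratio(fpkm, sex)
            ratios["stratum"] = genes.set_index("gene_id")["stratum"]
            ratios["chrom"] = genes.set_index("gene_id")["chrom"]
            z_ratios = ratios[ratios["chrom"] == "Z"]
            wins = expression.window_scan_expression(z_ratios)
            order = [s.stratum_id for s in reversed(scfg.strata_spec)]
            medians, pairs = expression.strata_expression_test(z_ratios, order)
            io.write_tsv(out / "mf_ratio.tsv", ratios.reset_index(names="gene_id"))
            io.write_tsv(out / "expression_windows.tsv", wins)
            io.write_tsv(out / "strata_expression.tsv", medians)
            record(
                "expression",
                {
                    "strata_median_mf": dict(
                        zip(medians["stratum"], medians["median_mf"])
                    ),
                    "n_windows": len(wins),
                },
                ["mf_ratio.tsv", "expression_windows.tsv", "strata_expression.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    if "traits" in cfg.stages:
        stage = "traits"
        try:
            tree = simdata.random_ultrametric_tree(
                cfg.n_tips, rng=np.random.default_rng(cfg.seed + 6)
            )
            traits = simdata.simulate_traits(tree, 1.0, 0.5, seed=cfg.seed + 7)
            traits = traits.rename(columns={"predictor": "life_span", "response": "alpha"})
            screen = phylotraits.rate_trait_screen(
                traits, tree, responses=["alpha"], predictors=["life_span"]
            )
            io.write_tsv(out / "trait_screen.tsv", screen)
            record(
                "traits",
                {"screen": screen.to_dict(orient="records")},
                ["trait_screen.tsv"],
            )
        except Exception as exc:
            raise PipelineError(stage, exc)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"].append("manifest.json")
    return manifest
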