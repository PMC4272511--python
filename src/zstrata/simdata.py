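"""Synthetic data with the statistical structure of avian Z-chromosome analyses.

Generates every input the downstream stages consume: intron alignments whose
Z/autosome divergence ratio encodes a chosen male mutation bias, forward
Wright-Fisher ZW populations, stratified Z/W divergence landscapes with
gametolog sequences, sex-biased expression counts under selectable dosage
compensation regimes, sequencing depth profiles, and Brownian trait data on a
phylogeny.

All randomness flows from ``SimConfig.seed`` (or an explicit ``rng``); every
output is reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._genetics import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, single_mutants

__all__ = [
    "SimConfig",
    "StratumSpec",
    "Locus",
    "AlignmentSet",
    "simulate_intron_alignments",
    "simulate_zw_population",
    "simulate_strata_chromosome",
    "simulate_expression",
    "simulate_depth_profile",
    "simulate_traits",
    "simulate_coding_pair",
    "simulate_coding_triplet",
]

_NT = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class StratumSpec:
    """One evolutionary stratum: a block of genes sharing a Z/W divergence level.

    ``zw_divergence`` is the expected Z/W substitutions per site inside the
    stratum (0 for the still-recombining PAR); ``w_retained`` is the fraction
    of genes whose W copy is still intact and expressed.
    """

    stratum_id: str
    n_genes: int
    zw_divergence: float
    w_retained: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.zw_divergence < 0:
            raise ValueError("zw_divergence must be >= 0")
        if not 0.0 <= self.w_retained <= 1.0:
            raise ValueError("w_retained must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    alpha_true
        Male/female germline mutation-rate ratio. 1 = no sex bias.
    female_rate
        Female-lineage substitution rate, substitutions/site/time-unit.
    divergence_time
        Total pairwise separation (sum of both branch lengths), time units.
    strata_spec
        Ordered oldest (S0) -> youngest -> PAR; Z/W divergence levels must
        strictly decrease along that order.
    dc_regime
        Dosage compensation: 'none', 'regional', or 'global'.
    """

    alpha_true: float = 2.0
    female_rate: float = 0.01
    divergence_time: float = 10.0
    n_loci_z: int = 500
    n_loci_a: int = 500
    locus_len: int = 1000
    strata_spec: tuple[StratumSpec, ...] = (
        StratumSpec("S0", 100, 0.30, 0.0),
        StratumSpec("S1", 100, 0.18, 0.3),
        StratumSpec("S2", 100, 0.08, 0.8),
        StratumSpec("PAR", 50, 0.0, 1.0),
    )
    dc_regime: str = "none"
    pop_n_males: int = 50
    pop_n_females: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be > 0")
        if self.female_rate < 0 or self.divergence_time < 0:
            raise ValueError("rates and times must be >= 0")
        if self.locus_len <= 0:
            raise ValueError("locus_len must be > 0")
        if self.dc_regime not in ("none", "regional", "global"):
            raise ValueError(f"unknown dc_regime {self.dc_regime!r}")
        levels = [s.zw_divergence for s in self.strata_spec]
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError(
                "strata_spec Z/W divergence must strictly decrease from S0 to PAR"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# alignment containers (shared with malebias)


@dataclass(frozen=True)
class Locus:
    """One aligned locus tagged with its chromosome class.

    ``chrom_class`` is 'Z' or a macro-autosome label ('A', 'A1', ...);
    ``seqs`` holds the aligned sequences (equal length).
    """

    locus_id: str
    chrom_class: str
    seqs: tuple[str, ...]
    stratum: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: aligned sequences differ in length")

    @property
    def is_z(self) -> bool:
        return self.chrom_class == "Z"


@dataclass
class AlignmentSet:
    """An ordered collection of loci; the unit the alpha estimator consumes."""

    loci: list[Locus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def subset(self, chrom_class: str) -> list[Locus]:
        return [l for l in self.loci if l.chrom_class == chrom_class]


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NT[rng.integers(0, 4, size=length)]


def _jc_mutate_array(
    seq: np.ndarray, d: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a nucleotide array along a branch of expected length d (subs/site).

    Under Jukes-Cantor the probability a site ends in a different base after
    branch length d is 3/4*(1 - exp(-4d/3)); changed sites pick one of the
    other three bases uniformly.
    """
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p_diff)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_NT, out[hit])
        out[hit] = _NT[(idx + shift) % 4]
    return out


def _arr_to_str(a: np.ndarray) -> str:
    return a.tobytes().decode()


def expected_divergence(cfg: SimConfig, chrom_class: str) -> float:
    """Closed-form expected substitutions/site for a locus class.

    Autosomes spend half their time in each sex: rate = mu_f*(alpha+1)/2.
    The Z spends 2/3 of its time in males: rate = mu_f*(2*alpha+1)/3.
    """
    a = cfg.alpha_true
    if chrom_class == "Z":
        rate = cfg.female_rate * (2.0 * a + 1.0) / 3.0
    else:
        rate = cfg.female_rate * (a + 1.0) / 2.0
    return rate * cfg.divergence_time


# ---------------------------------------------------------------------------
# intron alignments


def simulate_intron_alignments(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> AlignmentSet:
    """Pairwise intron alignments for Z-linked and macro-autosomal loci.

    Each locus is an independent Jukes-Cantor pair at the closed-form
    expected divergence of its chromosome class (see
    :func:`expected_divergence`); site histories are independent.
    """
    rng = cfg.rng() if rng is None else rng
    if cfg.n_loci_z == 0 and cfg.n_loci_a == 0:
        warnings.warn("zero loci requested; returning empty AlignmentSet")
        return AlignmentSet([])
    loci: list[Locus] = []
    for chrom_class, n in (("Z", cfg.n_loci_z), ("A", cfg.n_loci_a)):
        d = expected_divergence(cfg, chrom_class)
        for i in range(n):
            anc = _random_seq_array(rng, cfg.locus_len)
            other = _jc_mutate_array(anc, d, rng)
            loci.append(
                Locus(
                    locus_id=f"{chrom_class}_intron_{i:04d}",
                    chrom_class=chrom_class,
                    seqs=(_arr_to_str(anc), _arr_to_str(other)),
                )
            )
    return AlignmentSet(loci)


# ---------------------------------------------------------------------------
# forward Wright-Fisher with ZW inheritance


def _wf_locus_pi(
    n_males: int,
    n_females: int,
    generations: int,
    mu_locus: float,
    rng: np.random.Generator,
    z_linked: bool,
    prune_every: int = 25,
) -> float:
    """Nucleotide diversity (mean pairwise differences) of one neutral locus
    after `generations` of forward Wright-Fisher reproduction.

    Copies are tracked as a boolean matrix (segregating mutations x gene
    copies); reproduction is a column gather by parent copy index. Z-linked
    loci follow ZW transmission (males ZZ, females ZW; only Z copies carry
    the locus), autosomal loci ordinary diploid transmission with separate
    sexes. Infinite sites: every mutation is a fresh row.
    """
    if z_linked:
        # copy layout: male i -> [2i, 2i+1]; female j -> [2*Nm + j]
        n_copies = 2 * n_males + n_females
    else:
        # copy layout: individual k -> [2k, 2k+1]; 0..Nm-1 male, rest female
        n_copies = 2 * (n_males + n_females)

    m = np.zeros((0, n_copies), dtype=bool)
    for gen in range(generations):
        if z_linked:
            # male offspring: one Z from a random father, one from the mother
            fathers_m = rng.integers(0, n_males, size=n_males)
            pat_m = 2 * fathers_m + rng.integers(0, 2, size=n_males)
            mat_m = 2 * n_males + rng.integers(0, n_females, size=n_males)
            # female offspring: single Z from a random father
            fathers_f = rng.integers(0, n_males, size=n_females)
            pat_f = 2 * fathers_f + rng.integers(0, 2, size=n_females)
            parents = np.empty(n_copies, dtype=np.int64)
            parents[0 : 2 * n_males : 2] = pat_m
            parents[1 : 2 * n_males : 2] = mat_m
            parents[2 * n_males :] = pat_f
        else:
            n_ind = n_males + n_females
            pat = 2 * rng.integers(0, n_males, size=n_ind) + rng.integers(
                0, 2, size=n_ind
            )
            mat = (
                2 * (n_males + rng.integers(0, n_females, size=n_ind))
                + rng.integers(0, 2, size=n_ind)
            )
            parents = np.empty(n_copies, dtype=np.int64)
            parents[0::2] = pat
            parents[1::2] = mat
        m = m[:, parents]
        k = rng.poisson(n_copies * mu_locus)
        if k:
            new = np.zeros((k, n_copies), dtype=bool)
            new[np.arange(k), rng.integers(0, n_copies, size=k)] = True
            m = np.vstack([m, new])
        if gen % prune_every == 0 and m.shape[0]:
            counts = m.sum(axis=1)
            m = m[(counts > 0) & (counts < n_copies)]
    if not m.shape[0]:
        return 0.0
    p = m.mean(axis=1)
    # population heterozygosity with the n/(n-1) small-sample correction
    return float(np.sum(2.0 * p * (1.0 - p)) * n_copies / (n_copies - 1))


def simulate_zw_population(
    cfg: SimConfig,
    generations: int | None = None,
    n_loci: int = 40,
    locus_len: int = 1000,
    mut_rate: float = 5e-5,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Forward Wright-Fisher simulation of neutral diversity under ZW inheritance.

    Females are ZW, males ZZ, mating is random within the configured sex
    numbers, and mutation follows the infinite-sites model. Returns per-site
    nucleotide diversity of Z-linked and autosomal loci and their ratio; under
    equal sex numbers the neutral expectation is pi_Z/pi_A = 3/4 because
    there are three Z copies for every four autosomal copies.

    Loci recombine freely (independent transmissions). ``generations``
    defaults to 20x the total population size for equilibration; values below
    10x the population size are rejected as insufficient burn-in.
    """
    if mut_rate <= 0:
        raise ValueError("mut_rate must be > 0")
    if cfg.pop_n_males < 2 or cfg.pop_n_females < 2:
        raise ValueError("need at least 2 individuals of each sex")
    n_total = cfg.pop_n_males + cfg.pop_n_females
    if generations is None:
        generations = 20 * n_total
    if generations < 10 * n_total:
        raise ValueError("generations must be >= 10x total population size")
    rng = cfg.rng() if rng is None else rng
    mu_locus = mut_rate * locus_len
    pi_z = np.array(
        [
            _wf_locus_pi(cfg.pop_n_males, cfg.pop_n_females, generations, mu_locus, rng, True)
            for _ in range(n_loci)
        ]
    )
    pi_a = np.array(
        [
            _wf_locus_pi(cfg.pop_n_males, cfg.pop_n_females, generations, mu_locus, rng, False)
            for _ in range(n_loci)
        ]
    )
    mean_z = float(pi_z.mean()) / locus_len
    mean_a = float(pi_a.mean()) / locus_len
    return {
        "pi_z": mean_z,
        "pi_a": mean_a,
        "ratio": mean_z / mean_a if mean_a > 0 else math.nan,
        "n_loci": n_loci,
        "generations": generations,
    }


# ---------------------------------------------------------------------------
# stratified Z/W divergence landscape


def simulate_strata_chromosome(
    cfg: SimConfig,
    gene_span: int = 20_000,
    noise_sd: float = 0.02,
    species_divergence: float = 0.05,
    n_species: int = 2,
    gametologs_per_stratum: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, tuple[str, str], dict[str, dict[str, str]]]:
    """A Z chromosome whose Z/W divergence is a step function over strata.

    Returns ``(gene_table, (z_seq, w_seq), gametologs)``:

    * ``gene_table`` - gene_id, chrom, start, end (0-based half-open),
      stratum_true, zw_divergence, age_true;
    * ``(z_seq, w_seq)`` - a full-length aligned Z/W pair whose local
      divergence equals the stratum level plus Gaussian noise per gene
      (PAR: ~0, still recombining);
    * ``gametologs`` - per sampled gene, sequences named ``sp{i}_Z`` /
      ``sp{i}_W``. Strata whose Z/W divergence predates the species split
      (ancestral) yield trees where Z copies of different species cluster
      apart from W copies; younger, lineage-specific strata yield trees
      where each species' Z/W pair clusters.
    """
    if len(cfg.strata_spec) < 2:
        raise ValueError("need >= 2 strata in strata_spec")
    rng = cfg.rng() if rng is None else rng

    rows = []
    pos = 0
    for spec in cfg.strata_spec:
        age = (
            "par"
            if spec.zw_divergence == 0
            else ("ancestral" if spec.zw_divergence > species_divergence else "lineage-specific")
        )
        for g in range(spec.n_genes):
            rows.append(
                {
                    "gene_id": f"{spec.stratum_id}_g{g:04d}",
                    "chrom": "Z",
                    "start": pos,
                    "end": pos + gene_span,
                    "stratum_true": spec.stratum_id,
                    "zw_divergence": spec.zw_divergence,
                    "age_true": age,
                }
            )
            pos += gene_span
    gene_table = pd.DataFrame(rows)

    z_parts: list[np.ndarray] = []
    w_parts: list[np.ndarray] = []
    for row in gene_table.itertuples():
        d = row.zw_divergence
        if d > 0:
            d = max(0.0, rng.normal(d, noise_sd))
        z = _random_seq_array(rng, gene_span)
        w = _jc_mutate_array(z, d, rng) if d > 0 else z.copy()
        z_parts.append(z)
        w_parts.append(w)
    z_seq = _arr_to_str(np.concatenate(z_parts))
    w_seq = _arr_to_str(np.concatenate(w_parts))

    gametologs: dict[str, dict[str, str]] = {}
    glen = 900
    for spec in cfg.strata_spec:
        if spec.zw_divergence == 0:
            continue
        chosen = rng.choice(spec.n_genes, size=min(gametologs_per_stratum, spec.n_genes), replace=False)
        for g in np.sort(chosen):
            gene_id = f"{spec.stratum_id}_g{g:04d}"
            anc = _random_seq_array(rng, glen)
            seqs: dict[str, str] = {}
            if spec.zw_divergence > species_divergence:
                # recombination stopped before speciation: Z and W lineages
                # split first, then each duplicates at the species split
                half_zw = (spec.zw_divergence - species_divergence) / 2.0
                z_anc = _jc_mutate_array(anc, half_zw, rng)
                w_anc = _jc_mutate_array(anc, half_zw, rng)
                for i in range(n_species):
                    seqs[f"sp{i}_Z"] = _arr_to_str(
                        _jc_mutate_array(z_anc, species_divergence / 2.0, rng)
                    )
                    seqs[f"sp{i}_W"] = _arr_to_str(
                        _jc_mutate_array(w_anc, species_divergence / 2.0, rng)
                    )
            else:
                # speciation first, recombination stopped independently after
                for i in range(n_species):
                    sp_anc = _jc_mutate_array(anc, species_divergence / 2.0, rng)
                    seqs[f"sp{i}_Z"] = _arr_to_str(
                        _jc_mutate_array(sp_anc, spec.zw_divergence / 2.0, rng)
                    )
                    seqs[f"sp{i}_W"] = _arr_to_str(
                        _jc_mutate_array(sp_anc, spec.zw_divergence / 2.0, rng)
                    )
            gametologs[gene_id] = seqs
    return gene_table, (z_seq, w_seq), gametologs


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimConfig,
    n_samples_per_sex: int = 4,
    n_autosomal: int = 300,
    base_fpkm_log_mean: float = 3.0,
    base_fpkm_log_sd: float = 1.0,
    dispersion: float = 0.1,
    regional_window: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression counts for Z-linked and autosomal genes in both sexes.

    Autosomal genes have equal expected expression in the sexes. A Z-linked
    gene's female expectation is scaled by ``w + (1 - w) * c`` where ``w`` is
    its stratum's W-retention fraction and ``c`` the compensation factor:
    0.5 with no dosage compensation (single Z, no upregulation), 1.0 under
    global compensation, and 1.0 only inside ``regional_window`` (gene-index
    range on the Z, default the middle third) under regional compensation.
    Counts are negative binomial with the given dispersion (var = mu + disp*mu^2).

    Returns ``(counts, samples, gene_table)``: genes x samples integer counts,
    a sample sheet with sex labels, and a gene table with chromosome, length
    and stratum.
    """
    rng = cfg.rng() if rng is None else rng
    strata = [s for s in cfg.strata_spec]
    z_rows = []
    idx = 0
    pos = 0
    for spec in strata:
        for g in range(spec.n_genes):
            z_rows.append(
                {
                    "gene_id": f"{spec.stratum_id}_g{g:04d}",
                    "chrom": "Z",
                    "start": pos,
                    "end": pos + 20_000,
                    "stratum": spec.stratum_id,
                    "w_retained": spec.w_retained,
                    "z_index": idx,
                }
            )
            idx += 1
            pos += 20_000
    a_rows = [
        {
            "gene_id": f"A_g{g:04d}",
            "chrom": "A",
            "start": g * 20_000,
            "end": (g + 1) * 20_000,
            "stratum": ".",
            "w_retained": np.nan,
            "z_index": -1,
        }
        for g in range(n_autosomal)
    ]
    gene_table = pd.DataFrame(z_rows + a_rows)
    n_genes = len(gene_table)
    n_z = len(z_rows)
    if regional_window is None:
        regional_window = (n_z // 3, 2 * n_z // 3)

    gene_table["length"] = 1500  # transcript length used for FPKM downstream
    base = rng.lognormal(base_fpkm_log_mean, base_fpkm_log_sd, size=n_genes)

    # per-gene W retention is Bernoulli(w_retained of its stratum)
    w_flag = np.zeros(n_genes)
    is_z = (gene_table["chrom"] == "Z").to_numpy()
    w_flag[is_z] = rng.random(n_z) < gene_table.loc[is_z, "w_retained"].to_numpy()

    if cfg.dc_regime == "global":
        comp = np.ones(n_genes)
    elif cfg.dc_regime == "none":
        comp = np.full(n_genes, 0.5)
    else:  # regional
        comp = np.full(n_genes, 0.5)
        zi = gene_table["z_index"].to_numpy()
        in_win = (zi >= regional_window[0]) & (zi < regional_window[1])
        comp[in_win] = 1.0
    female_scale = np.where(is_z, w_flag + (1.0 - w_flag) * comp, 1.0)

    samples = pd.DataFrame(
        {
            "sample": [f"M{i}" for i in range(n_samples_per_sex)]
            + [f"F{i}" for i in range(n_samples_per_sex)],
            "sex": ["male"] * n_samples_per_sex + ["female"] * n_samples_per_sex,
        }
    )
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    r = 1.0 / dispersion
    for j, sex in enumerate(samples["sex"]):
        mu = base * (female_scale if sex == "female" else 1.0)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=gene_table["gene_id"], columns=samples["sample"])
    gene_table = gene_table.drop(columns=["w_retained", "z_index"])
    return counts_df, samples, gene_table


# ---------------------------------------------------------------------------
# sequencing depth


def simulate_depth_profile(
    sex: str,
    mean_depth: float,
    rng: np.random.Generator | int | None = None,
    n_windows: int = 200,
    chroms: tuple[str, ...] = ("A1", "A2", "Z"),
) -> pd.DataFrame:
    """Per-window Poisson read depths for one sequenced individual.

    Males (ZZ) have the autosomal expected depth on the Z; females (ZW)
    carry a single Z, so its expected depth is half the autosomal one.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for chrom in chroms:
        lam = mean_depth if (chrom != "Z" or sex == "male") else mean_depth / 2.0
        depths = rng.poisson(lam, size=n_windows)
        for w, dep in enumerate(depths):
            rows.append({"chrom": chrom, "window": w, "depth": int(dep)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# traits on a phylogeny


def random_ultrametric_tree(
    n_tips: int, rng: np.random.Generator | int | None = None, depth: float = 1.0
) -> str:
    """A random ultrametric binary tree (Newick) with total depth `depth`.

    Built by recursive random splits at uniformly drawn heights; a stand-in
    for a dated species phylogeny in synthetic trait experiments.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = [f"sp{i:02d}" for i in range(n_tips)]

    def build(tips: list[str], max_height: float) -> tuple[str, float]:
        """Return (newick without root branch, root height above the tips)."""
        if len(tips) == 1:
            return tips[0], 0.0
        node_h = max_height * float(rng.uniform(0.5, 0.95))
        k = int(rng.integers(1, len(tips)))
        left, lh = build(tips[:k], node_h)
        right, rh = build(tips[k:], node_h)
        node = f"({left}:{node_h - lh:.12f},{right}:{node_h - rh:.12f})"
        return node, node_h

    body, _ = build(labels, depth)
    return body + ";"


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix (shared root-to-MRCA path lengths)."""
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    depth = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    c = np.zeros((n, n))
    for i in range(n):
        c[i, i] = depth[labels[i]]
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[i], taxa[j])
            # shared path = (depth_i + depth_j - patristic) / 2
            c[i, j] = c[j, i] = 0.5 * (depth[labels[i]] + depth[labels[j]] - dij)
    return c, labels


def simulate_traits(
    tree: dendropy.Tree | str,
    lambda_true: float,
    slope: float,
    seed: int | np.random.Generator | None = 0,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Two correlated traits on a phylogeny.

    The predictor evolves by Brownian motion on the tree; the response is
    ``slope * predictor`` plus noise whose covariance is the Brownian matrix
    with off-diagonals damped by ``lambda_true`` (Pagel's lambda transform).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    if len(tree.taxon_namespace) < 8:
        raise ValueError("need >= 8 tips")
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) > 2:
            raise ValueError("tree must be binary")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c, labels = phylo_covariance(tree)
    v_lam = lambda_true * c + (1.0 - lambda_true) * np.diag(np.diag(c))
    lx = np.linalg.cholesky(c + 1e-12 * np.eye(len(labels)))
    le = np.linalg.cholesky(v_lam + 1e-12 * np.eye(len(labels)))
    x = lx @ rng.standard_normal(len(labels))
    y = slope * x + noise_scale * (le @ rng.standard_normal(len(labels)))
    return pd.DataFrame({"species": labels, "predictor": x, "response": y})


# ---------------------------------------------------------------------------
# coding-sequence evolution (for dN/dS estimators)


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = [c for c in SENSE_CODONS if c != "ATG"]
    return ["ATG"] + [codons[i] for i in rng.integers(0, len(codons), size=n_codons - 1)]


def _evolve_codons(
    codons: list[str], events_per_codon: float, omega: float, rng: np.random.Generator
) -> list[str]:
    """Evolve a codon sequence: uniform single-nucleotide proposals, stop
    changes rejected, nonsynonymous changes accepted with probability omega."""
    out = list(codons)
    n = len(out)
    n_events = rng.poisson(events_per_codon * n)
    for _ in range(n_events):
        i = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        mut = single_mutants(out[i], pos)[int(rng.integers(0, 3))]
        if mut in STOP_CODONS:
            continue
        if CODON_TO_AA[mut] != CODON_TO_AA[out[i]] and rng.random() >= omega:
            continue
        out[i] = mut
    return out


def simulate_coding_pair(
    n_codons: int,
    omega: float,
    events_per_codon: float = 0.6,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """An aligned CDS pair diverged under a given dN/dS.

    Substitution proposals are uniform over single-nucleotide changes;
    synonymous proposals always fix, nonsynonymous ones fix with probability
    ``omega``, so the realized rate ratio per opportunity equals ``omega``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    anc = _random_cds(rng, n_codons)
    a = _evolve_codons(anc, events_per_codon / 2.0, omega, rng)
    b = _evolve_codons(anc, events_per_codon / 2.0, omega, rng)
    return "".join(a), "".join(b)


def simulate_coding_triplet(
    n_codons: int,
    omega: float,
    branch_focal: float,
    branch_sister: float,
    branch_outgroup: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str, str]:
    """Aligned (focal, sister, outgroup) CDS with per-branch event counts.

    Branch lengths are expected substitution proposal events per codon. The
    outgroup branch runs from the root; focal and sister diverge from their
    common ancestor midway along the outgroup's history.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    root = _random_cds(rng, n_codons)
    inner = _evolve_codons(root, branch_outgroup / 2.0, omega, rng)
    focal = _evolve_codons(inner, branch_focal, omega, rng)
    sister = _evolve_codons(inner, branch_sister, omega, rng)
    outgroup = _evolve_codons(root, branch_outgroup / 2.0, omega, rng)
    return "".join(focal), "".join(sister), "".join(outgroup)
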