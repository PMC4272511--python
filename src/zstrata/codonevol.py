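"""Codon usage and coding-sequence evolutionary rates.

Codon-usage bias is summarized by the frequency of optimal codons (FOP), the
codon bias index (CBI), and GC content at third codon positions (GC3) and in
linked introns (GCi). Evolutionary rates use the Nei-Gojobori (1986)
counting method: fractional synonymous/nonsynonymous site counts per codon,
multiple-pathway averaging for codons differing at 2-3 positions, and a
Jukes-Cantor correction of the raw proportions. Lineage-specific rates come
from a relative-rate decomposition over a (focal, sister, outgroup) triplet,
and lineage acceleration is tested with a Tajima-style relative-rate
chi-square on lineage-unique substitutions. A generic hypergeometric
enrichment test closes the loop for candidate gene sets.

The optimal-codon set is an input; a default chicken-like table (GC-ending
preferred codons, configurable) ships with the package.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._genetics import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    synonymous_site_fractions,
)

__all__ = [
    "CodonMetrics",
    "RateEstimate",
    "default_optimal_codons",
    "codon_usage_metrics",
    "ng86_rates",
    "lineage_rates",
    "filter_rates",
    "accelerated_genes",
    "hypergeom_enrichment",
]


@dataclass(frozen=True)
class CodonMetrics:
    gene_id: str
    fop: float
    cbi: float
    gc3: float
    gci: float | None
    codons_counted: int


@dataclass(frozen=True)
class RateEstimate:
    gene_id: str
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 or saturated
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False
    pass_filter: bool | None = None
    truncated: bool = False


def default_optimal_codons() -> frozenset[str]:
    """The bundled default optimal-codon set (chicken-like, GC-ending).

    Loaded from package data; replace with a species-specific table for
    real analyses.
    """
    text = resources.files("zstrata.data").joinpath("optimal_codons_chicken_like.tsv").read_text()
    codons = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon = line.split("\t")[-1].upper()
        codons.add(codon)
    return frozenset(codons)


def _split_codons(cds: str, gene_id: str = "?") -> list[str]:
    cds = cds.upper().replace("-", "")
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"{gene_id}: internal stop codon {c} at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def codon_usage_metrics(
    cds: str,
    optimal_codons: frozenset[str] | set[str] | None = None,
    introns: str | None = None,
    gene_id: str = "?",
) -> CodonMetrics:
    """FOP, CBI, GC3 and (optionally) intronic GC for one coding sequence.

    FOP = optimal codons / codons with synonymous alternatives. CBI =
    (Nopt - Nrand) / (Ntot - Nrand) where Nrand is the optimal count
    expected under uniform synonymous usage; 1 at complete bias, 0 at
    uniform usage. GC3 is taken over third positions of all non-stop
    codons. Codons containing N (or other ambiguity) are excluded.
    """
    if optimal_codons is None:
        optimal_codons = default_optimal_codons()
    codons = [c for c in _split_codons(cds, gene_id) if set(c) <= set("ACGT")]
    if not codons:
        raise ValueError(f"{gene_id}: no unambiguous codons")

    with_syn = [c for c in codons if len(SYNONYMOUS_FAMILIES[CODON_TO_AA[c]]) > 1]
    n_opt = sum(1 for c in with_syn if c in optimal_codons)
    n_tot = len(with_syn)
    fop = n_opt / n_tot if n_tot else float("nan")

    n_rand = 0.0
    for c in with_syn:
        family = SYNONYMOUS_FAMILIES[CODON_TO_AA[c]]
        n_rand += sum(1 for f in family if f in optimal_codons) / len(family)
    cbi = (n_opt - n_rand) / (n_tot - n_rand) if n_tot and n_tot != n_rand else float("nan")

    gc3 = sum(1 for c in codons if c[2] in "GC") / len(codons)

    gci = None
    if introns is not None:
        bases = [b for b in introns.upper() if b in "ACGT"]
        gci = sum(1 for b in bases if b in "GC") / len(bases) if bases else float("nan")
    return CodonMetrics(gene_id, fop, cbi, gc3, gci, len(codons))


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaging
    over all orderings of the mutational pathway; pathways through stop
    codons are excluded."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        # every pathway passes through a stop; split evenly as a fallback
        return len(diff_pos) / 2.0, len(diff_pos) / 2.0
    return syn_tot / n_paths, nonsyn_tot / n_paths


def _codon_pairs(seq1: str, seq2: str, gene_id: str) -> list[tuple[str, str]]:
    if len(seq1) != len(seq2):
        raise ValueError(f"{gene_id}: aligned CDS pair must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError(f"{gene_id}: alignment length not divisible by 3")
    pairs = []
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if not (set(c1) <= set("ACGT") and set(c2) <= set("ACGT")):
            continue  # gap/N codon columns dropped codon-wise
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        pairs.append((c1, c2))
    return pairs


def ng86_rates(seq1: str, seq2: str, gene_id: str = "?") -> RateEstimate:
    """Nei-Gojobori counting estimates of dN and dS for an aligned CDS pair.

    Sites: each codon contributes fractional synonymous/nonsynonymous sites
    (averaged over the two sequences). Differences: per differing codon
    pair, averaged over all substitution pathways not passing through a
    stop. The raw proportions pS = Sd/S, pN = Nd/N are Jukes-Cantor
    corrected: d = -(3/4) ln(1 - 4p/3). Proportions >= 3/4 set the
    ``saturated`` flag (distance undefined).
    """
    pairs = _codon_pairs(seq1, seq2, gene_id)
    if not pairs:
        raise ValueError(f"{gene_id}: zero usable codon columns")
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for c1, c2 in pairs:
        s1, n1 = synonymous_site_fractions(c1)
        s2, n2 = synonymous_site_fractions(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        s_diffs += sd
        n_diffs += nd
    if s_sites == 0 or n_sites == 0:
        raise ValueError(f"{gene_id}: zero synonymous or nonsynonymous sites")
    ps = s_diffs / s_sites
    pn = n_diffs / n_sites
    saturated = ps >= 0.75 or pn >= 0.75
    ds = math.nan if ps >= 0.75 else -0.75 * math.log1p(-4.0 * ps / 3.0)
    dn = math.nan if pn >= 0.75 else -0.75 * math.log1p(-4.0 * pn / 3.0)
    omega = None
    if not saturated and ds > 0:
        omega = dn / ds
    return RateEstimate(
        gene_id=gene_id,
        dn=dn,
        ds=ds,
        omega=omega,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=s_diffs,
        nonsyn_diffs=n_diffs,
        saturated=saturated,
    )


def lineage_rates(
    focal: str, sister: str, outgroup: str, gene_id: str = "?"
) -> tuple[RateEstimate, RateEstimate]:
    """Lineage-specific dN and dS by relative-rate decomposition.

    With pairwise distances d_FO, d_FS, d_SO from NG86, the branch leading
    to the focal taxon since its split from the sister is
    d_focal = (d_FO + d_FS - d_SO) / 2, applied separately to the
    synonymous and nonsynonymous components (and symmetrically for the
    sister). Negative decompositions are truncated to 0 and flagged;
    saturation in any pairwise estimate propagates.
    """
    fo = ng86_rates(focal, outgroup, f"{gene_id}:FO")
    fs = ng86_rates(focal, sister, f"{gene_id}:FS")
    so = ng86_rates(sister, outgroup, f"{gene_id}:SO")
    saturated = fo.saturated or fs.saturated or so.saturated

    def _branch(which: str) -> RateEstimate:
        if which == "focal":
            dn_raw = (fo.dn + fs.dn - so.dn) / 2.0
            ds_raw = (fo.ds + fs.ds - so.ds) / 2.0
        else:
            dn_raw = (so.dn + fs.dn - fo.dn) / 2.0
            ds_raw = (so.ds + fs.ds - fo.ds) / 2.0
        truncated = (not math.isnan(dn_raw) and dn_raw < 0) or (
            not math.isnan(ds_raw) and ds_raw < 0
        )
        dn = max(dn_raw, 0.0) if not math.isnan(dn_raw) else math.nan
        ds = max(ds_raw, 0.0) if not math.isnan(ds_raw) else math.nan
        omega = dn / ds if (not saturated and not math.isnan(ds) and ds > 0) else None
        return RateEstimate(
            gene_id=f"{gene_id}:{which}",
            dn=dn,
            ds=ds,
            omega=omega,
            syn_sites=fs.syn_sites,
            nonsyn_sites=fs.nonsyn_sites,
            syn_diffs=math.nan,
            nonsyn_diffs=math.nan,
            saturated=saturated,
            truncated=truncated,
        )

    return _branch("focal"), _branch("sister")


def filter_rates(
    rates: list[RateEstimate], lo: float = 0.001, hi: float = 2.0
) -> tuple[list[RateEstimate], list[RateEstimate]]:
    """Apply the rate-saturation filter: keep genes with both dN and dS
    inside [lo, hi].

    Returns ``(flagged, passing)``: the full list with ``pass_filter`` set,
    and the passing subset. Idempotent.
    """
    flagged = []
    for r in rates:
        ok = (
            not math.isnan(r.dn)
            and not math.isnan(r.ds)
            and lo <= r.dn <= hi
            and lo <= r.ds <= hi
        )
        flagged.append(replace(r, pass_filter=ok))
    return flagged, [r for r in flagged if r.pass_filter]


def _unique_substitutions(focal: str, sister: str, outgroup: str) -> tuple[int, int]:
    """Site counts where exactly one ingroup taxon differs from the other
    two sequences (Tajima's m1: focal unique, m2: sister unique)."""
    m_focal = m_sister = 0
    for a, b, c in zip(focal.upper(), sister.upper(), outgroup.upper()):
        if not ({a, b, c} <= set("ACGT")):
            continue
        if a != b and b == c:
            m_focal += 1
        elif a != b and a == c:
            m_sister += 1
    return m_focal, m_sister


def accelerated_genes(
    triplets: dict[str, tuple[str, str, str]], p_cut: float = 0.05
) -> pd.DataFrame:
    """Tajima relative-rate test for lineage acceleration, per gene.

    For each (focal, sister, outgroup) alignment, counts sites where only
    the focal (m1) or only the sister (m2) sequence carries a derived
    state; under rate equality m1 ~ Binomial(m1+m2, 1/2), tested by a
    1-df chi-square. Genes with p < ``p_cut`` and m1 > m2 are flagged as
    candidate fast-evolving. Genes with zero informative sites are skipped
    with a warning.
    """
    rows = []
    for gene_id, (focal, sister, outgroup) in triplets.items():
        m1, m2 = _unique_substitutions(focal, sister, outgroup)
        if m1 + m2 == 0:
            warnings.warn(f"{gene_id}: zero informative sites; skipped")
            continue
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append(
            {
                "gene_id": gene_id,
                "m_focal": m1,
                "m_sister": m2,
                "chi2": chi2,
                "p": p,
                "accelerated": bool(p < p_cut and m1 > m2),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "m_focal", "m_sister", "chi2", "p", "accelerated"])


def hypergeom_enrichment(
    foreground: set[str],
    background: set[str],
    term_map: pd.DataFrame,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene set.

    ``term_map`` has columns (gene, term); the background is the sampling
    universe. For each term with K background members, the probability of
    drawing >= k members in a foreground of size n is
    P(X >= k) with X ~ Hypergeom(N, K, n). Returns all terms with their p,
    sorted ascending, plus a ``significant`` flag at ``p_cut``.
    """
    if not foreground:
        raise ValueError("empty foreground gene set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    tm = term_map[term_map["gene"].isin(background)]
    n_bg = len(background)
    n_fg = len(foreground)
    rows = []
    for term, group in tm.groupby("term"):
        members = set(group["gene"])
        k_bg = len(members)
        k_fg = len(members & foreground)
        p = float(stats.hypergeom.sf(k_fg - 1, n_bg, k_bg, n_fg))
        rows.append(
            {
                "term": term,
                "fg_count": k_fg,
                "bg_count": k_bg,
                "fg_size": n_fg,
                "bg_size": n_bg,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p"] < p_cut
    return out
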