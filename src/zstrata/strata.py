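"""Evolutionary strata of the Z chromosome from windowed Z/W divergence.

Recombination between the avian Z and W stopped in discrete steps; each step
left a region ("stratum") with its own characteristic Z/W divergence, highest
in the oldest stratum S0 and zero in the still-recombining pseudoautosomal
region (PAR). This module scans a Z-anchored Z/W alignment in windows,
detects breakpoints where the divergence level shifts, labels strata by
descending median divergence, dates strata as ancestral or lineage-specific
from gametolog gene-tree topology, and assigns genes to strata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .malebias import SaturationError, pairwise_distance
from .simdata import Locus

__all__ = [
    "WindowDivergence",
    "Stratum",
    "StratumMap",
    "window_scan",
    "detect_boundaries",
    "classify_stratum_age",
    "assign_genes_to_strata",
]


@dataclass(frozen=True)
class WindowDivergence:
    index: int
    start: int
    end: int
    divergence: float
    informative_sites: int
    usable: bool = True


@dataclass(frozen=True)
class Stratum:
    stratum_id: str
    start: int
    end: int
    median_divergence: float
    age_class: str = "unknown"


@dataclass
class StratumMap:
    """Ordered strata tiling the scanned region, S0 = highest divergence."""

    strata: list[Stratum]

    def __post_init__(self) -> None:
        for a, b in zip(self.strata, self.strata[1:]):
            if a.end != b.start:
                raise ValueError("strata must tile the region without gaps/overlap")

    def __len__(self) -> int:
        return len(self.strata)

    def by_id(self, stratum_id: str) -> Stratum:
        for s in self.strata:
            if s.stratum_id == stratum_id:
                return s
        raise KeyError(stratum_id)

    def to_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": "Z",
                "start": [s.start for s in self.strata],
                "end": [s.end for s in self.strata],
                "name": [s.stratum_id for s in self.strata],
                "score": [s.median_divergence for s in self.strata],
                "age_class": [s.age_class for s in self.strata],
            }
        )


def window_scan(
    zw_alignment: tuple[str, str],
    window_len: int = 100_000,
    model: str = "jc69",
    min_sites: int = 100,
) -> list[WindowDivergence]:
    """Per-window corrected Z/W divergence along Z coordinates.

    Windows with fewer than ``min_sites`` comparable columns, or whose
    mismatch level saturates the distance correction, are flagged unusable
    and excluded from boundary testing. The trailing partial window is kept
    (subject to the same ``min_sites`` guard).
    """
    if window_len < 1000:
        raise ValueError("window_len must be >= 1 kb")
    z, w = zw_alignment
    if len(z) != len(w):
        raise ValueError("Z and W sequences must be aligned (equal length)")
    out: list[WindowDivergence] = []
    for i, start in enumerate(range(0, len(z), window_len)):
        end = min(start + window_len, len(z))
        locus = Locus(f"win_{i}", "Z", (z[start:end], w[start:end]))
        try:
            est = pairwise_distance(locus, model)
            usable = est.sites_used >= min_sites
            div, sites = est.distance, est.sites_used
        except SaturationError:
            usable, div, sites = False, float("nan"), 0
        except ValueError:
            usable, div, sites = False, float("nan"), 0
        out.append(WindowDivergence(i, start, end, div, sites, usable))
    if not any(wd.usable for wd in out):
        raise ValueError("no usable windows in the scan")
    return out


def detect_boundaries(
    windows: list[WindowDivergence],
    flank: int = 10,
    p_cut: float = 0.01,
    min_gap: int = 500_000,
) -> StratumMap:
    """Locate strata boundaries where the windowed divergence level shifts.

    At every candidate breakpoint the ``flank`` usable windows on the left
    are compared with the ``flank`` on the right by a two-sided Mann-Whitney
    rank-sum test; local minima of the p-value profile that stay below
    ``p_cut`` after Bonferroni correction over the number of tested
    breakpoints become boundaries (so ``p_cut`` is a per-chromosome,
    family-wise level), and boundaries closer than ``min_gap`` bp are
    merged keeping the more significant one. Larger flanks buy smaller
    attainable rank-sum p-values and hence resolution under the correction. The resulting segments are labeled by
    descending median divergence: S0 (highest), S1, ..., with the lowest
    segment named PAR when its median divergence is ~0.
    """
    usable = [w for w in windows if w.usable]
    if len(usable) < 2 * flank:
        raise ValueError("flank larger than half the usable windows")
    div = np.array([w.divergence for w in usable])

    pvals = np.full(len(usable), np.nan)
    for cut in range(flank, len(usable) - flank + 1):
        left = div[cut - flank : cut]
        right = div[cut : cut + flank]
        if np.all(left == left[0]) and np.all(right == right[0]) and left[0] == right[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(left, right, alternative="two-sided").pvalue
        if cut < len(pvals):
            pvals[cut] = p

    n_tests = max(1, len(usable) - 2 * flank + 1)
    candidates: list[tuple[int, float]] = []  # (usable-window cut index, p)
    for cut in range(flank, len(usable) - flank):
        p = pvals[cut]
        if np.isnan(p) or p * n_tests >= p_cut:
            continue
        neigh = [pvals[j] for j in (cut - 1, cut + 1) if 0 <= j < len(pvals) and not np.isnan(pvals[j])]
        if all(p <= q for q in neigh):
            candidates.append((cut, p))

    # merge candidates closer than min_gap, keeping the smaller p
    merged: list[tuple[int, float]] = []
    for cut, p in sorted(candidates):
        pos = usable[cut].start
        if merged and pos - usable[merged[-1][0]].start < min_gap:
            if p < merged[-1][1]:
                merged[-1] = (cut, p)
        else:
            merged.append((cut, p))

    cuts = sorted(c for c, _ in merged)
    seg_bounds = [0, *cuts, len(usable)]
    segments = []
    for s, e in zip(seg_bounds, seg_bounds[1:]):
        segments.append(
            {
                "start": usable[s].start,
                "end": usable[e - 1].end,
                "median": float(np.median(div[s:e])),
            }
        )
    # label by descending median divergence
    order = sorted(range(len(segments)), key=lambda i: -segments[i]["median"])
    names = {}
    rank = 0
    for i in order:
        if segments[i]["median"] < 0.005 and i == order[-1]:
            names[i] = "PAR"
        else:
            names[i] = f"S{rank}"
            rank += 1
    strata = [
        Stratum(names[i], seg["start"], seg["end"], seg["median"])
        for i, seg in enumerate(segments)
    ]
    return StratumMap(strata)


def _bipartitions(tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller side's tip-name set)."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(min(side, all_tips - side, key=lambda s: (len(s), sorted(s))))
    return parts


def classify_stratum_age(
    gametologs: dict[str, str], model: str = "k2p"
) -> str:
    """Date a stratum from the topology of its gametolog gene tree.

    ``gametologs`` maps names like ``"sp0_Z"`` / ``"sp0_W"`` to sequences.
    A neighbor-joining tree is built from pairwise distances. If the Z
    copies of all species form one side of an internal edge (separated from
    all W copies), the Z/W split predates speciation: "ancestral". If every
    species' own Z and W pair clusters, recombination stopped independently
    after speciation: "lineage-specific". Anything else is "unknown". The
    two target topologies are distinguishable unrooted, so no rooting is
    needed; the result is invariant to input order and species relabeling.
    """
    by_species: dict[str, set[str]] = {}
    for name in gametologs:
        sp, _, copy = name.rpartition("_")
        if copy not in ("Z", "W") or not sp:
            raise ValueError(f"gametolog name {name!r} must end in _Z or _W")
        by_species.setdefault(sp, set()).add(copy)
    complete = [sp for sp, copies in by_species.items() if copies == {"Z", "W"}]
    if len(complete) < 2:
        raise ValueError("need >= 2 species with both Z and W gametologs")

    names = sorted(n for n in gametologs if n.rpartition("_")[0] in complete)
    dm = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        locus = Locus("g", "Z", (gametologs[names[i]], gametologs[names[j]]))
        d = pairwise_distance(locus, model).distance
        dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=names))
    parts = _bipartitions(tree)

    z_side = frozenset(n for n in names if n.endswith("_Z"))
    w_side = frozenset(n for n in names if n.endswith("_W"))
    zw_split = min(z_side, w_side, key=lambda s: (len(s), sorted(s))) in parts
    if len(complete) == 2:
        # four taxa: one internal edge; the ZW split and the per-species
        # pairings are the two competing resolutions
        sp_pairs = [
            frozenset({f"{sp}_Z", f"{sp}_W"}) for sp in complete
        ]
        pairs_split = any(p in parts for p in sp_pairs)
    else:
        sp_pairs = [frozenset({f"{sp}_Z", f"{sp}_W"}) for sp in complete]
        pairs_split = all(p in parts for p in sp_pairs)
    if zw_split and not pairs_split:
        return "ancestral"
    if pairs_split and not zw_split:
        return "lineage-specific"
    return "unknown"


def assign_genes_to_strata(genes: pd.DataFrame, smap: StratumMap) -> pd.DataFrame:
    """Assign each gene to the stratum containing its midpoint.

    Coordinates are 0-based half-open; a midpoint exactly on a boundary
    belongs to the stratum starting there. Genes outside every stratum get
    stratum '.' and ``in_strata=False``.
    """
    out = genes.copy()
    strata_ids = []
    flags = []
    for row in out.itertuples():
        mid = (row.start + row.end) // 2
        hit = None
        for s in smap.strata:
            if s.start <= mid < s.end:
                hit = s.stratum_id
                break
        strata_ids.append(hit if hit is not None else ".")
        flags.append(hit is not None)
    out["stratum"] = strata_ids
    out["in_strata"] = flags
    if not all(flags):
        warnings.warn(f"{flags.count(False)} gene(s) fall outside all strata")
    return out
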