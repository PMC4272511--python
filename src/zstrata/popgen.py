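"""Population-genetic summaries: SNP filtering, intron SNP density as a
diversity proxy, the fast-Z correlation test, and read-depth sexing.

The Z/A ratio of median intron SNP density approximates the ratio of
effective population sizes Ne_Z/Ne_A (neutral expectation 3/4 at equal sex
numbers and random mating); its decline across species, paired with a rise
in the Z/A dN/dS contrast, is the drift signature of fast-Z evolution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_snps",
    "snp_density",
    "fastz_correlation",
    "infer_sex",
    "za_wilcoxon",
]


def filter_snps(
    snps: pd.DataFrame,
    min_depth: int = 4,
    max_depth: int = 100,
    min_spacing: int = 5,
    keep_one_of_pair: bool = False,
) -> pd.DataFrame:
    """Depth and clustering filters for a SNP table.

    Keeps sites with read depth in [min_depth, max_depth] inclusive (sites
    with depth lower than 4 or higher than 100 are removed under the
    defaults), then removes clustered sites closer than ``min_spacing`` bp
    to a surviving neighbor on the same chromosome. By default both members
    of a close pair are removed; ``keep_one_of_pair=True`` instead keeps
    the first site of each run. Requires positions sorted within chromosome.
    """
    required = {"chrom", "pos", "depth"}
    if not required <= set(snps.columns):
        raise ValueError(f"SNP table must have columns {sorted(required)}")
    for _, group in snps.groupby("chrom"):
        if not group["pos"].is_monotonic_increasing:
            raise ValueError("SNP positions must be sorted within each chromosome")
        if group["pos"].duplicated().any():
            raise ValueError("duplicate SNP positions within a chromosome")
    ok_depth = (snps["depth"] >= min_depth) & (snps["depth"] <= max_depth)
    kept = snps[ok_depth]

    keep_mask = pd.Series(True, index=kept.index)
    for _, group in kept.groupby("chrom"):
        pos = group["pos"].to_numpy()
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        close = gaps < min_spacing
        if keep_one_of_pair:
            # drop the right-hand member of each close step
            drop = np.zeros(pos.size, dtype=bool)
            drop[1:] = close
        else:
            drop = np.zeros(pos.size, dtype=bool)
            drop[:-1] |= close
            drop[1:] |= close
        keep_mask.loc[group.index[drop]] = False
    return kept[keep_mask].reset_index(drop=True)


def snp_density(
    snps: pd.DataFrame, regions: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region SNP density (SNPs per kb) and the Z/A median-density ratio.

    ``regions`` needs columns (region_id, chrom, start, end) with 0-based
    half-open intervals and a ``chrom_class`` column ('Z' or autosomal).
    Zero-length regions are skipped with a warning. The summary holds
    class medians and ``ratio_za`` = median_Z / median_A.
    """
    rows = []
    for row in regions.itertuples():
        length = row.end - row.start
        if length <= 0:
            warnings.warn(f"{row.region_id}: zero-length region skipped")
            continue
        sub = snps[
            (snps["chrom"] == row.chrom)
            & (snps["pos"] >= row.start)
            & (snps["pos"] < row.end)
        ]
        rows.append(
            {
                "region_id": row.region_id,
                "chrom_class": row.chrom_class,
                "snp_count": len(sub),
                "length_bp": length,
                "density_per_kb": 1000.0 * len(sub) / length,
            }
        )
    per_region = pd.DataFrame(rows)
    med_z = float(per_region.loc[per_region["chrom_class"] == "Z", "density_per_kb"].median())
    med_a = float(per_region.loc[per_region["chrom_class"] != "Z", "density_per_kb"].median())
    summary = {
        "median_z": med_z,
        "median_a": med_a,
        "ratio_za": med_z / med_a if med_a > 0 else float("nan"),
    }
    return per_region, summary


def fastz_correlation(per_species: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between the Z/A diversity ratio and the Z/A
    evolutionary-rate ratio across species.

    A significantly negative r indicates that species with a smaller Z
    effective population size show stronger fast-Z evolution, the drift
    explanation. Needs columns ``ratio_za_density`` and ``ratio_za_omega``
    and >= 4 species.
    """
    x = per_species["ratio_za_density"].to_numpy(dtype=float)
    y = per_species["ratio_za_omega"].to_numpy(dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 species for the correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def infer_sex(
    depths: pd.DataFrame,
    z_chrom: str = "Z",
    male_cut: float = 0.75,
    uncertain_band: tuple[float, float] = (0.65, 0.85),
) -> tuple[str, float, str]:
    """Sex an individual from its Z vs autosome sequencing depth.

    Males (ZZ) show similar depth on the Z and autosomes; females (ZW)
    show roughly half depth on the Z. The Z/autosome mean-depth ratio is
    thresholded at ``male_cut`` (male at or above); ratios inside
    ``uncertain_band`` carry a low-confidence note.
    """
    if "chrom" not in depths.columns or "depth" not in depths.columns:
        raise ValueError("depth table must have columns chrom, depth")
    z = depths.loc[depths["chrom"] == z_chrom, "depth"]
    a = depths.loc[depths["chrom"] != z_chrom, "depth"]
    if z.empty:
        raise ValueError("no Z-chromosome depth rows")
    mean_a = float(a.mean())
    if not mean_a > 0:
        raise ValueError("autosomal mean depth must be > 0")
    ratio = float(z.mean()) / mean_a
    sex = "male" if ratio >= male_cut else "female"
    note = (
        "low confidence" if uncertain_band[0] <= ratio <= uncertain_band[1] else "ok"
    )
    return sex, ratio, note


def za_wilcoxon(
    values_z: np.ndarray | list[float],
    values_a: np.ndarray | list[float],
    scale_a: float = 1.0,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test of Z values against (scaled) autosomal values.

    ``scale_a=0.75`` tests the neutral three-quarters null: are Z values
    lower even than 3/4 of the autosomal ones? All-tied degenerate input
    returns p = 1 with a warning.
    """
    z = np.asarray(values_z, dtype=float)
    a = np.asarray(values_a, dtype=float) * scale_a
    if z.size == 0 or a.size == 0:
        raise ValueError("both value lists must be non-empty")
    pooled = np.concatenate([z, a])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; test degenerate")
        return float(z.size * a.size / 2.0), 1.0
    res = stats.mannwhitneyu(z, a, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
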