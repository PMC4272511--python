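"""Sex-biased expression along the Z chromosome and dosage-compensation tests.

Birds lack chromosome-wide dosage compensation: in females the single Z
leaves many Z-linked genes expressed at about half the male level, and the
deficit deepens with stratum age as W-linked copies decay. This module
normalizes counts to FPKM, forms male/female expression ratios, scans them
in five-gene non-overlapping windows along the Z, and compares strata
against their younger neighbors.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fpkm",
    "mf_ratio",
    "window_scan_expression",
    "strata_expression_test",
    "female_za_test",
]

logger = logging.getLogger(__name__)


def fpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s]); ``totals``
    defaults to the per-sample column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive mapped-fragment total")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def mf_ratio(
    expr: pd.DataFrame,
    sex: pd.Series,
    pseudocount: float = 0.1,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene male/female expression ratio.

    ratio = (mean male + eps) / (mean female + eps); log2 also reported.
    Genes below ``expression_floor`` in both sexes are flagged
    ``expressed=False`` and should be excluded from summaries.
    """
    sex = sex.reindex(expr.columns)
    if sex.isna().any():
        raise ValueError("every sample needs a sex label")
    males = expr.loc[:, (sex == "male").to_numpy()]
    females = expr.loc[:, (sex == "female").to_numpy()]
    if males.shape[1] == 0 or females.shape[1] == 0:
        raise ValueError("need >= 1 male and >= 1 female sample")
    m = males.mean(axis=1)
    f = females.mean(axis=1)
    ratio = (m + pseudocount) / (f + pseudocount)
    return pd.DataFrame(
        {
            "mean_male": m,
            "mean_female": f,
            "ratio_mf": ratio,
            "log2_ratio_mf": np.log2(ratio),
            "expressed": (m >= expression_floor) | (f >= expression_floor),
        }
    )


def window_scan_expression(ratios: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Median log2 M/F ratio in non-overlapping k-gene windows along the Z.

    ``ratios`` must be ordered by Z position and carry ``log2_ratio_mf``
    (and optionally ``stratum``). A trailing block of fewer than k genes is
    dropped; with fewer than k genes in total an empty table is returned
    with a warning.
    """
    n = len(ratios)
    if n < k:
        warnings.warn(f"only {n} genes (< window size {k}); no windows emitted")
        return pd.DataFrame(
            columns=["window", "genes", "median_log2_mf", "median_mf", "stratum"]
        )
    n_win = n // k
    dropped = n - n_win * k
    if dropped:
        logger.info("dropping trailing partial window of %d gene(s)", dropped)
    rows = []
    for w in range(n_win):
        block = ratios.iloc[w * k : (w + 1) * k]
        med = float(block["log2_ratio_mf"].median())
        if "stratum" in block.columns:
            stratum = block["stratum"].mode().iloc[0]
        else:
            stratum = "."
        rows.append(
            {
                "window": w,
                "genes": ",".join(map(str, block.index)),
                "median_log2_mf": med,
                "median_mf": 2.0**med,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


def strata_expression_test(
    ratios: pd.DataFrame,
    order_young_to_old: list[str],
    min_genes: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare each stratum's M/F ratios with its next-younger neighbor.

    ``ratios`` needs ``log2_ratio_mf`` and ``stratum`` columns; strata with
    fewer than ``min_genes`` genes are excluded with a warning. Returns
    (per-stratum medians, per-adjacent-pair Mann-Whitney results), pairs
    ordered young -> old.
    """
    usable = ratios
    if "expressed" in ratios.columns:
        usable = ratios[ratios["expressed"]]
    groups = {}
    for s in order_young_to_old:
        vals = usable.loc[usable["stratum"] == s, "log2_ratio_mf"].to_numpy()
        if vals.size < min_genes:
            warnings.warn(f"stratum {s}: {vals.size} genes < {min_genes}; excluded")
            continue
        groups[s] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 strata with enough genes")
    medians = pd.DataFrame(
        {
            "stratum": list(groups),
            "n_genes": [g.size for g in groups.values()],
            "median_log2_mf": [float(np.median(g)) for g in groups.values()],
            "median_mf": [float(2.0 ** np.median(g)) for g in groups.values()],
        }
    )
    pair_rows = []
    names = list(groups)
    for young, old in zip(names, names[1:]):
        res = stats.mannwhitneyu(groups[old], groups[young], alternative="two-sided")
        pair_rows.append(
            {
                "younger": young,
                "older": old,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return medians, pd.DataFrame(pair_rows)


def female_za_test(
    expr: pd.DataFrame,
    sex: pd.Series,
    chrom_class: pd.Series,
    which_sex: str = "female",
) -> tuple[float, float, dict[str, float]]:
    """Mann-Whitney contrast of Z vs autosomal expression within one sex.

    In the absence of dosage compensation, female Z expression is reduced
    relative to autosomes; the same machinery serves the male/testis
    contrast. Returns (statistic, p, medians by class).
    """
    sex = sex.reindex(expr.columns)
    chrom_class = chrom_class.reindex(expr.index)
    cols = (sex == which_sex).to_numpy()
    if cols.sum() == 0:
        raise ValueError(f"no {which_sex} samples")
    per_gene = expr.loc[:, cols].mean(axis=1)
    z = per_gene[(chrom_class == "Z").to_numpy()]
    a = per_gene[(chrom_class != "Z").to_numpy()]
    if z.empty or a.empty:
        raise ValueError("need both Z-linked and autosomal genes")
    res = stats.mannwhitneyu(z, a, alternative="two-sided")
    medians = {"median_z": float(z.median()), "median_a": float(a.median())}
    return float(res.statistic), float(res.pvalue), medians
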