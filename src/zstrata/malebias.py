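"""Male mutation bias (alpha) from the Z/autosome intron divergence ratio.

Because the Z chromosome spends two thirds of its history in males and
autosomes only half, the ratio R of Z-linked to autosomal neutral divergence
is informative about the male/female germline mutation-rate ratio alpha:

    R(alpha) = (4*alpha + 2) / (3*(alpha + 1)),   inverted as
    alpha(R) = (3R - 2) / (4 - 3R).

R is bounded in (2/3, 4/3); estimates at or beyond the bounds are flagged
rather than silently dropped. Per-locus distances use closed-form JC69 or
K2P corrections; class summaries use medians; uncertainty comes from a
nonparametric bootstrap over loci (the independent units), resampled within
the Z and autosome classes separately, with percentile confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._genetics import is_transition
from .simdata import AlignmentSet, Locus

__all__ = [
    "DistanceEstimate",
    "AlphaEstimate",
    "SaturationError",
    "pairwise_distance",
    "class_median_divergence",
    "estimate_alpha",
    "za_ratio_from_alpha",
    "bootstrap_alpha",
]

_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Observed mismatch proportion outside the distance correction's domain."""


@dataclass(frozen=True)
class DistanceEstimate:
    locus_id: str
    chrom_class: str
    model: str
    distance: float
    sites_used: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class AlphaEstimate:
    """Point estimate and bootstrap interval for the male mutation bias.

    ``alpha`` is ``math.inf`` when the point ratio reaches the male-limit
    R >= 4/3 and negative when R <= 2/3; ``n_nonfinite`` counts bootstrap
    replicates whose ratio fell outside (2/3, 4/3).
    """

    ratio_za: float
    alpha: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_nonfinite: int
    median_z: float
    median_a: float
    seed: int | None = None


def _usable_columns(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise deletion: drop columns with a gap/N/ambiguity in either sequence."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    good = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(arr_a, good) & np.isin(arr_b, good)
    return arr_a[valid], arr_b[valid]


def pairwise_distance(locus: Locus, model: str = "jc69") -> DistanceEstimate:
    """Closed-form substitution distance for an aligned pair.

    JC69: d = -(3/4) ln(1 - 4p/3) over sites usable in both sequences.
    K2P: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q) with P, Q the
    transition and transversion proportions. Saturated inputs (p >= 3/4 for
    JC69, non-positive log arguments for K2P) raise :class:`SaturationError`.
    """
    if len(locus.seqs) < 2:
        raise ValueError(f"{locus.locus_id}: need an aligned pair")
    a, b = _usable_columns(locus.seqs[0], locus.seqs[1])
    n = a.size
    if n == 0:
        raise ValueError(f"{locus.locus_id}: zero usable sites after pairwise deletion")
    model = model.lower()
    if model == "jc69":
        p = float(np.mean(a != b))
        if p >= 0.75:
            raise SaturationError(
                f"{locus.locus_id}: p={p:.3f} >= 3/4, JC69 distance undefined"
            )
        d = -0.75 * math.log1p(-4.0 * p / 3.0)
    elif model == "k2p":
        diff = a != b
        if diff.any():
            ts = np.fromiter(
                (
                    is_transition(x.decode(), y.decode())
                    for x, y in zip(a[diff], b[diff])
                ),
                dtype=bool,
            )
            p = float(ts.sum()) / n
            q = float((~ts).sum()) / n
        else:
            p = q = 0.0
        one_m = 1.0 - 2.0 * p - q
        two_m = 1.0 - 2.0 * q
        if one_m <= 0 or two_m <= 0:
            raise SaturationError(f"{locus.locus_id}: K2P log-domain violation")
        d = -0.5 * math.log(one_m) - 0.25 * math.log(two_m)
    else:
        raise ValueError(f"unknown model {model!r}")
    return DistanceEstimate(locus.locus_id, locus.chrom_class, model, max(d, 0.0), n)


def class_median_divergence(
    estimates: list[DistanceEstimate], chrom_class: str
) -> float:
    """Median per-locus distance within one chromosome class.

    Even counts average the central pair (the usual median convention).
    """
    vals = [e.distance for e in estimates if e.chrom_class == chrom_class]
    if not vals:
        raise ValueError(f"no distance estimates in class {chrom_class!r}")
    return float(np.median(vals))


def estimate_alpha(ratio_za: float) -> float:
    """Invert the divergence ratio into the male mutation bias.

    alpha = (3R - 2) / (4 - 3R); strictly increasing on R in (2/3, 4/3).
    R >= 4/3 returns +inf (male-limit exceeded); R <= 2/3 returns the
    (negative) analytic value so callers can see how far below the female
    limit the ratio fell. Both are flagged by being non-finite/negative,
    never dropped.
    """
    if ratio_za <= 0:
        raise ValueError("ratio_za must be > 0")
    if ratio_za >= 4.0 / 3.0:
        return math.inf
    return (3.0 * ratio_za - 2.0) / (4.0 - 3.0 * ratio_za)


def za_ratio_from_alpha(alpha: float) -> float:
    """Forward map R(alpha) = (4*alpha + 2) / (3*(alpha + 1))."""
    return (4.0 * alpha + 2.0) / (3.0 * (alpha + 1.0))


def bootstrap_alpha(
    aln: AlignmentSet,
    model: str = "jc69",
    n_boot: int = 1000,
    seed: int | None = None,
    autosome_classes: tuple[str, ...] | None = None,
) -> AlphaEstimate:
    """Point estimate of alpha with a percentile bootstrap interval.

    Loci are resampled with replacement independently within the Z class and
    within the autosome class(es); medians, the Z/A ratio and alpha are
    recomputed per replicate. The 2.5/97.5 percentiles of the finite
    replicate alphas form the interval; non-finite replicates (ratio outside
    (2/3, 4/3)) are excluded from the percentiles but counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ests = [pairwise_distance(l, model) for l in aln]
    z = np.array([e.distance for e in ests if e.chrom_class == "Z"])
    if autosome_classes is None:
        a = np.array([e.distance for e in ests if e.chrom_class != "Z"])
    else:
        a = np.array([e.distance for e in ests if e.chrom_class in autosome_classes])
    if z.size < 2 or a.size < 2:
        raise ValueError("need >= 2 loci in each of the Z and autosome classes")
    med_z, med_a = float(np.median(z)), float(np.median(a))
    ratio = med_z / med_a
    alpha = estimate_alpha(ratio)

    rng = np.random.default_rng(seed)
    bz = z[rng.integers(0, z.size, size=(n_boot, z.size))]
    ba = a[rng.integers(0, a.size, size=(n_boot, a.size))]
    ratios = np.median(bz, axis=1) / np.median(ba, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alphas = (3.0 * ratios - 2.0) / (4.0 - 3.0 * ratios)
    alphas = np.where(ratios >= 4.0 / 3.0, np.inf, alphas)
    finite = alphas[np.isfinite(alphas)]
    n_nonfinite = int(n_boot - finite.size)
    if finite.size == 0:
        raise ValueError("all bootstrap replicates fell outside the alpha domain")
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return AlphaEstimate(
        ratio_za=ratio,
        alpha=alpha,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_nonfinite=n_nonfinite,
        median_z=med_z,
        median_a=med_a,
        seed=seed,
    )
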