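"""Phylogenetically controlled trait-rate associations (Pagel's lambda, PGLS).

Species are not independent observations: trait and rate values covary with
phylogeny. Under a Brownian-motion model the expected covariance of a trait
between two species equals their shared root-to-divergence path length;
Pagel's lambda damps the off-diagonal covariances, interpolating between a
star phylogeny (lambda = 0, ordinary regression) and full Brownian
dependence (lambda = 1). The screen first asks, by likelihood-ratio test,
whether a trait is fully phylogeny-dependent (lambda = 1); dependent traits
are tested by PGLS, the rest by ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .simdata import phylo_covariance

__all__ = ["PhyloModelFit", "fit_lambda", "pgls", "rate_trait_screen"]

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class PhyloModelFit:
    lambda_: float
    loglik: float
    loglik_lambda1: float
    loglik_lambda0: float
    slope: float | None
    slope_se: float | None
    p_slope: float | None
    p_lambda1: float
    method: str = "pgls"
    note: str = ""


def _v_lambda(c: np.ndarray, lam: float) -> np.ndarray:
    v = lam * c
    np.fill_diagonal(v, np.diag(c))
    return v


def _gls_loglik(
    y: np.ndarray, x: np.ndarray, v: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile (over beta, sigma^2) Gaussian log-likelihood under covariance
    sigma^2 * v; returns (loglik, beta, (X'V^-1 X)^-1, sigma2_ml)."""
    n = y.size
    try:
        l = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance not positive definite") from exc
    # whiten
    li_y = np.linalg.solve(l, y)
    li_x = np.linalg.solve(l, x)
    xtx = li_x.T @ li_x
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (li_x.T @ li_y)
    resid = li_y - li_x @ beta
    # floor guards saturated fits (zero residuals) against log(0)
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(l))))
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return loglik, beta, xtx_inv, sigma2


def _profile_lambda(
    y: np.ndarray, x: np.ndarray, c: np.ndarray, grid_size: int = 101
) -> tuple[float, float]:
    """Maximize the profile log-likelihood over lambda in [0, 1]: coarse grid
    then golden-section refinement inside the best cell."""

    def ll(lam: float) -> float:
        try:
            return _gls_loglik(y, x, _v_lambda(c, lam))[0]
        except np.linalg.LinAlgError:
            return -np.inf

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([ll(g) for g in grid])
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    a, b = lo, hi
    c1 = b - _GOLD * (b - a)
    c2 = a + _GOLD * (b - a)
    f1, f2 = ll(c1), ll(c2)
    for _ in range(40):
        if f1 < f2:
            a, c1, f1 = c1, c2, f2
            c2 = a + _GOLD * (b - a)
            f2 = ll(c2)
        else:
            b, c2, f2 = c2, c1, f1
            c1 = b - _GOLD * (b - a)
            f1 = ll(c1)
    lam = 0.5 * (a + b)
    return float(lam), ll(lam)


def _lrt_lambda1(loglik_ml: float, loglik_1: float) -> float:
    """Boundary-aware LRT p-value for H0: lambda = 1 (50:50 mixture of a
    point mass at 0 and chi-square with 1 df)."""
    stat = max(0.0, 2.0 * (loglik_ml - loglik_1))
    if stat == 0.0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(stat, df=1))


def _align(tree: dendropy.Tree | str, species: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    c, labels = phylo_covariance(tree)
    idx = {s: i for i, s in enumerate(labels)}
    missing = [s for s in species if s not in idx]
    if missing:
        raise ValueError(f"species not in tree: {missing[:5]}")
    order = [idx[s] for s in species]
    return c[np.ix_(order, order)], np.asarray(order)


def fit_lambda(
    y: pd.Series | np.ndarray,
    tree: dendropy.Tree | str,
    species: pd.Series | list[str] | None = None,
) -> PhyloModelFit:
    """ML estimate of Pagel's lambda for one trait (intercept-only model).

    Requires >= 8 species. On a star tree (no shared history) lambda is
    unidentifiable; the fit is flagged and lambda reported as 0.
    """
    if isinstance(y, pd.Series) and species is None:
        species = pd.Series(y.index)
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("need >= 8 species")
    c, _ = _align(tree, pd.Series(species))
    x = np.ones((y.size, 1))
    off = c[~np.eye(c.shape[0], dtype=bool)]
    if np.allclose(off, 0.0):
        ll0 = _gls_loglik(y, x, _v_lambda(c, 0.0))[0]
        return PhyloModelFit(0.0, ll0, ll0, ll0, None, None, None, 1.0,
                             method="lambda", note="star tree: lambda unidentifiable")
    lam, ll_ml = _profile_lambda(y, x, c)
    ll1 = _gls_loglik(y, x, _v_lambda(c, 1.0))[0]
    ll0 = _gls_loglik(y, x, _v_lambda(c, 0.0))[0]
    # the grid/golden search can only undershoot the boundary values
    if ll1 > ll_ml:
        lam, ll_ml = 1.0, ll1
    if ll0 > ll_ml:
        lam, ll_ml = 0.0, ll0
    return PhyloModelFit(
        lambda_=lam,
        loglik=ll_ml,
        loglik_lambda1=ll1,
        loglik_lambda0=ll0,
        slope=None,
        slope_se=None,
        p_slope=None,
        p_lambda1=_lrt_lambda1(ll_ml, ll1),
        method="lambda",
    )


def pgls(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    tree: dendropy.Tree | str,
    lambda_: float | str = "ml",
    species: pd.Series | list[str] | None = None,
) -> PhyloModelFit:
    """Phylogenetic generalized least squares regression of y on x.

    With ``lambda_=0`` the covariance is diagonal and the fit reduces
    exactly to ordinary least squares; ``lambda_='ml'`` profiles lambda
    jointly with the regression. The slope is tested by a t-test with
    n - 2 degrees of freedom.
    """
    if isinstance(y, pd.Series) and species is None:
        species = pd.Series(y.index)
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    if np.std(xv) == 0:
        raise ValueError("predictor has zero variance (collinear with intercept)")
    c, _ = _align(tree, pd.Series(species))
    design = np.column_stack([np.ones_like(xv), xv])
    if lambda_ == "ml":
        lam, ll_ml = _profile_lambda(yv, design, c)
        ll1 = _gls_loglik(yv, design, _v_lambda(c, 1.0))[0]
        ll0 = _gls_loglik(yv, design, _v_lambda(c, 0.0))[0]
        if ll1 > ll_ml:
            lam, ll_ml = 1.0, ll1
        if ll0 > ll_ml:
            lam, ll_ml = 0.0, ll0
    else:
        lam = float(lambda_)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        ll_ml = _gls_loglik(yv, design, _v_lambda(c, lam))[0]
        ll1 = _gls_loglik(yv, design, _v_lambda(c, 1.0))[0]
        ll0 = _gls_loglik(yv, design, _v_lambda(c, 0.0))[0]
    loglik, beta, xtx_inv, sigma2 = _gls_loglik(yv, design, _v_lambda(c, lam))
    n = yv.size
    if n > 2:
        # unbiased error variance for the t-test
        s2 = sigma2 * n / (n - 2)
        se = math.sqrt(s2 * xtx_inv[1, 1])
        tval = beta[1] / se
        p_slope = 2.0 * float(stats.t.sf(abs(tval), df=n - 2))
    else:  # saturated fit (e.g. two tips): slope defined, no error df
        se = math.nan
        p_slope = math.nan
    return PhyloModelFit(
        lambda_=lam,
        loglik=loglik,
        loglik_lambda1=ll1,
        loglik_lambda0=ll0,
        slope=float(beta[1]),
        slope_se=se,
        p_slope=p_slope,
        p_lambda1=_lrt_lambda1(max(ll_ml, ll1), ll1),
        method="pgls" if lam > 0 else "ols",
    )


def rate_trait_screen(
    traits: pd.DataFrame,
    tree: dendropy.Tree | str,
    responses: list[str],
    predictors: list[str] | None = None,
    species_col: str = "species",
    p_dependence: float = 0.05,
) -> pd.DataFrame:
    """Screen genomic-rate responses against life-history traits.

    For every (response, trait) pair with >= 4 jointly observed species:
    the trait's phylogeny dependence is tested first (LRT of lambda = 1);
    dependent traits are tested by PGLS with ML lambda, the rest by
    ordinary regression (PGLS at lambda = 0). Categorical traits are
    compared by Kruskal-Wallis instead. Missing values are dropped
    pairwise; the method used is recorded per row.
    """
    if predictors is None:
        predictors = [
            c for c in traits.columns if c not in responses and c != species_col
        ]
    rows = []
    for resp in responses:
        for trait in predictors:
            sub = traits[[species_col, resp, trait]].dropna()
            if len(sub) < 4:
                warnings.warn(f"{resp} ~ {trait}: <4 species with data; skipped")
                continue
            y = sub[resp].astype(float).to_numpy()
            if not pd.api.types.is_numeric_dtype(sub[trait]):
                groups = [g[resp].to_numpy(dtype=float) for _, g in sub.groupby(trait)]
                if len(groups) < 2:
                    warnings.warn(f"{trait}: single category; skipped")
                    continue
                stat, p = stats.kruskal(*groups)
                rows.append(
                    {
                        "response": resp,
                        "trait": trait,
                        "n": len(sub),
                        "method": "kruskal-wallis",
                        "lambda": np.nan,
                        "slope": np.nan,
                        "sign": ".",
                        "p": float(p),
                    }
                )
                continue
            sp = sub[species_col]
            x = sub[trait].astype(float).to_numpy()
            dep = None
            if len(sub) >= 8:
                dep = fit_lambda(x, tree, species=sp)
            use_pgls = dep is not None and dep.p_lambda1 >= p_dependence
            fit = pgls(y, x, tree, lambda_="ml" if use_pgls else 0.0, species=sp)
            rows.append(
                {
                    "response": resp,
                    "trait": trait,
                    "n": len(sub),
                    "method": "pgls" if use_pgls else "ols",
                    "lambda": fit.lambda_,
                    "slope": fit.slope,
                    "sign": "-" if fit.slope < 0 else "+",
                    "p": fit.p_slope,
                }
            )
    return pd.DataFrame(rows)
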