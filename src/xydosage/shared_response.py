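"""Comparison of two per-gene effect catalogs.

Supports the shared-response questions: do Chr X- and Chr Y-responsive
gene sets overlap more than chance (hypergeometric test), are their
per-copy effects correlated (Pearson, Bonferroni-corrected), what is the
slope relating them when both axes are measured with error (weighted
Deming regression with jackknife CI), how much of one response is
explained by the other (R^2), and which functional categories are
enriched (hypergeometric with BH control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "DemingFit",
    "overlap_test",
    "correlate_effects",
    "weighted_deming",
    "variance_explained",
    "category_enrichment",
]


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p: float
    p_bonferroni: float
    venn: tuple[int, int, int]  # (A only, B only, A and B)


def overlap_test(set_a, set_b, universe, n_tests: int = 1) -> OverlapResult:
    """Upper-tail hypergeometric test of |A intersect B|.

    p = P(X >= k) for X ~ Hypergeometric(N, |A|, |B|), including the
    observed count. ``n_tests`` is the explicit Bonferroni denominator.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    for name, s in (("A", a), ("B", b)):
        stray = s - universe
        if stray:
            raise ValueError(f"set {name} has elements outside the universe: {sorted(stray)[:5]}")
    k = len(a & b)
    n = len(universe)
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    p = min(p, 1.0)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        n_universe=n,
        p=p,
        p_bonferroni=min(1.0, p * n_tests),
        venn=(len(a - b), len(b - a), k),
    )


def _extract(fit: pd.DataFrame, gene_set, coef=None) -> np.ndarray:
    f = fit if coef is None else fit[fit["coef"] == coef]
    v = f.set_index("gene")["log2fc_per_copy"]
    genes = pd.Index(gene_set)
    missing = genes.difference(v.index)
    if len(missing):
        raise KeyError(f"genes absent from the fit: {list(missing)[:5]}")
    return v.loc[genes].to_numpy()


def _aligned_estimates(fit_a, fit_b, gene_set, coef=None):
    return _extract(fit_a, gene_set, coef), _extract(fit_b, gene_set, coef)


def correlate_effects(fit_a, fit_b, gene_set, n_tests: int = 1, coef=None):
    """Pearson correlation of two effect catalogs over a gene set.

    Returns (r, p, Bonferroni-adjusted p). Accepts fit tables from
    :func:`xydosage.dosage_model.fit_dosage_glm` (optionally restricted to
    one coefficient) or any table with gene / log2fc_per_copy columns.
    """
    if len(gene_set) < 3:
        raise ValueError("need at least 3 genes to correlate")
    x, y = _aligned_estimates(fit_a, fit_b, gene_set, coef)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant effect vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), min(1.0, float(res.pvalue) * n_tests)


@dataclass
class DemingFit:
    slope: float
    intercept: float
    se_slope: float
    ci95: tuple[float, float]
    n: int
    xstd: np.ndarray
    ystd: np.ndarray


def _deming_profile(x, y, xstd, ystd):
    """Minimize S(b) = sum (y - a - b x)^2 / (ystd^2 + b^2 xstd^2) over b."""
    vx, vy = xstd**2, ystd**2

    def a_of(b):
        w = 1.0 / (vy + b * b * vx)
        return np.sum(w * (y - b * x)) / np.sum(w)

    def S(b):
        w = 1.0 / (vy + b * b * vx)
        r = y - a_of(b) - b * x
        return np.sum(w * r * r)

    # closed-form start with the mean error-variance ratio
    lam = np.mean(vy) / np.mean(vx)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy != 0:
        b0 = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    else:
        b0 = 0.0
    res = optimize.minimize_scalar(
        S, bracket=(b0 - max(abs(b0), 1.0), b0, b0 + max(abs(b0), 1.0)),
        method="brent", options={"xtol": 1e-12},
    )
    b = float(res.x)
    return b, float(a_of(b))


def weighted_deming(x, y, xstd, ystd) -> DemingFit:
    """Errors-in-variables regression with per-point error SDs.

    Generalized (weighted) Deming fit minimizing the error-scaled
    orthogonal residuals; with constant equal errors this reduces to the
    classical closed-form Deming solution (error-variance ratio 1). The
    slope's standard error is the leave-one-out jackknife, and the 95% CI
    is slope +/- 1.96 SE.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    xstd = np.broadcast_to(np.asarray(xstd, float), x.shape).copy()
    ystd = np.broadcast_to(np.asarray(ystd, float), y.shape).copy()
    n = len(x)
    if not (len(y) == len(xstd) == len(ystd) == n):
        raise ValueError("x, y, xstd, ystd must have equal lengths")
    if n < 3:
        raise ValueError("need at least 3 points for a Deming fit")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    if (xstd < 0).any() or (ystd < 0).any() or ((xstd == 0) & (ystd == 0)).any():
        raise ValueError("error SDs must be positive (one of xstd/ystd may approach 0)")

    slope, intercept = _deming_profile(x, y, xstd, ystd)
    loo = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        loo[i] = _deming_profile(x[keep], y[keep], xstd[keep], ystd[keep])[0]
        keep[i] = True
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return DemingFit(
        slope=slope,
        intercept=intercept,
        se_slope=se,
        ci95=(slope - 1.96 * se, slope + 1.96 * se),
        n=n,
        xstd=xstd,
        ystd=ystd,
    )


def variance_explained(
    fit_perturbation, fit_dosage, gene_set, coef_perturbation=None, coef_dosage=None
):
    """Squared Pearson correlation between two effect catalogs, plus sign.

    Returns (R^2, sign) where sign is the sign of the correlation — e.g.
    knockdown responses run opposite to dosage responses for genes
    activated by the dosed factor.
    """
    if len(gene_set) < 3:
        raise ValueError("need at least 3 genes")
    a = _extract(fit_perturbation, gene_set, coef_perturbation)
    b = _extract(fit_dosage, gene_set, coef_dosage)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("R^2 undefined for a constant effect vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r * r, int(np.sign(r))


def category_enrichment(gene_set, categories: dict, universe, fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of each category in a gene set.

    The background is the full expressed universe; p values are BH-adjusted
    across non-empty categories and flagged significant below ``fdr``.
    Empty categories (after intersecting with the universe) are skipped;
    their number is available in the result's ``attrs['n_skipped_empty']``.
    """
    universe = set(universe)
    genes = set(gene_set)
    if genes - universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows, skipped = [], 0
    for name, members in categories.items():
        m = set(members) & universe
        if not m:
            skipped += 1
            continue
        k = len(m & genes)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(m), len(genes)))
        rows.append((name, len(m), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["category", "n_category", "n_overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["n_skipped_empty"] = skipped
    return out
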