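"""Targeted copy-number recalling from single-cell expression.

Given chromosomal regions derived from genomic SV breakpoints, each region's
average (centered) expression across cells is fit with a two-component
Gaussian mixture; cells carrying a deletion of the region show on-average
lower expression than cells without it, and the component posteriors give a
per-cell copy-number status. Uninformative regions are filtered on a
likelihood-ratio test (BH-adjusted p < 0.01), a BIC improvement of the
two-component model > 200, and > 10 expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .simulate import ExpressionCellMatrix
from .stats import bh_adjust

MIN_GENES_EXPRESSED = 10
SD_FLOOR = 1e-3


@dataclass
class NormalizedExpression:
    """log2(CPM/10 + 1) matrix with per-gene expressed flags."""

    values: pd.DataFrame  # genes x cells
    expressed: pd.Series  # gene_id -> bool
    genes: pd.DataFrame  # gene_id, chrom, start, end


def normalize_expression(
    matrix: ExpressionCellMatrix, min_cells_expr: int = 5
) -> NormalizedExpression:
    """Library-size normalize counts to log2(CPM/10 + 1).

    A gene is flagged expressed when it has a nonzero count in at least
    ``min_cells_expr`` cells. Cells with zero library size are dropped.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    lib = counts.sum(axis=0)
    keep = lib > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {(~keep).sum()} cells with zero library size", stacklevel=2)
    counts = counts[:, keep]
    lib = lib[keep]
    cpm = counts / lib * 1e6
    vals = np.log2(cpm / 10.0 + 1.0)
    cells = matrix.cells.cell_id.to_numpy()[keep]
    values = pd.DataFrame(vals, index=matrix.genes.gene_id, columns=cells)
    expressed = pd.Series(
        (counts > 0).sum(axis=1) >= min_cells_expr, index=matrix.genes.gene_id
    )
    return NormalizedExpression(values=values, expressed=expressed, genes=matrix.genes)


def region_scores(
    region: tuple[str, int, int], expr: NormalizedExpression
) -> pd.Series | None:
    """Per-cell average of centered expression over a region's expressed genes.

    Each gene is centered to mean zero across cells before averaging, so the
    score reflects relative dosage rather than absolute abundance. Regions
    with <= 10 expressed genes are skipped (returns None).
    """
    chrom, start, end = region
    g = expr.genes
    in_region = (
        (g.chrom == chrom) & (g.start < end) & (g.end > start)
    )
    gene_ids = g.gene_id[in_region]
    gene_ids = gene_ids[expr.expressed.loc[gene_ids].to_numpy()]
    if len(gene_ids) <= MIN_GENES_EXPRESSED:
        return None
    sub = expr.values.loc[gene_ids]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return centered.mean(axis=0)


@dataclass
class RegionFit:
    """Two-component Gaussian mixture fit of one region's cell scores."""

    region: tuple[str, int, int]
    n_genes_expressed: int
    scores: pd.Series
    mean1: float
    sd1: float
    loglik1: float
    bic1: float
    means: tuple[float, float]  # mu_low < mu_high
    sds: tuple[float, float]
    weight_low: float
    loglik2: float
    bic2: float
    lrt_stat: float
    lrt_p: float
    adj_p: float = np.nan
    passed: bool = False

    @property
    def delta_bic(self) -> float:
        return self.bic1 - self.bic2


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _em_two_gaussians(x: np.ndarray, mu0, sd0, w0, max_iter=200, tol=1e-6):
    """EM for a 1-D two-component Gaussian mixture with unequal variances."""
    mu = np.array(mu0, dtype=float)
    sd = np.maximum(np.array(sd0, dtype=float), SD_FLOOR)
    w = float(np.clip(w0, 1e-6, 1 - 1e-6))
    ll_prev = -np.inf
    for _ in range(max_iter):
        la = _norm_logpdf(x, mu[0], sd[0]) + np.log(w)
        lb = _norm_logpdf(x, mu[1], sd[1]) + np.log(1 - w)
        m = np.maximum(la, lb)
        ll = float(np.sum(m + np.log(np.exp(la - m) + np.exp(lb - m))))
        ra = np.exp(la - m)
        rb = np.exp(lb - m)
        r = ra / (ra + rb)
        n1 = r.sum()
        n2 = len(x) - n1
        if n1 < 1e-8 or n2 < 1e-8:
            break
        mu = np.array([np.sum(r * x) / n1, np.sum((1 - r) * x) / n2])
        sd = np.sqrt(
            [
                np.sum(r * (x - mu[0]) ** 2) / n1,
                np.sum((1 - r) * (x - mu[1]) ** 2) / n2,
            ]
        )
        sd = np.maximum(sd, SD_FLOOR)
        w = float(np.clip(n1 / len(x), 1e-6, 1 - 1e-6))
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return mu, sd, w, ll


def fit_region_mixture(
    scores: pd.Series,
    region: tuple[str, int, int] = ("", 0, 0),
    n_genes_expressed: int = 0,
    n_restarts: int = 10,
    seed: int = 0,
) -> RegionFit:
    """Fit one- and two-component Gaussians to a region's cell scores.

    The one-component MLE is closed form. The two-component fit runs EM from
    ``n_restarts`` initializations (a 2-means split plus quantile splits at
    deterministic probabilities) and keeps the best log-likelihood. The LRT
    statistic 2(loglik2 - loglik1) is referred to chi-square with 3 degrees
    of freedom (extra mean, variance and mixing weight; the mixture LRT is
    non-regular, so this is an approximation used for ranking/filtering).
    BIC = k ln(n) - 2 loglik with k = 2 and 5.
    """
    x = scores.to_numpy(dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("mixture fit requires >= 20 cells")
    mu1 = float(np.mean(x))
    sd1 = max(float(np.std(x)), SD_FLOOR)
    ll1 = float(np.sum(norm.logpdf(x, mu1, sd1)))
    bic1 = 2 * np.log(n) - 2 * ll1

    if np.ptp(x) < 1e-12:
        return RegionFit(
            region, n_genes_expressed, scores, mu1, sd1, ll1, bic1,
            (mu1, mu1), (sd1, sd1), 0.5, ll1, 5 * np.log(n) - 2 * ll1,
            0.0, 1.0,
        )

    rng = np.random.default_rng(seed)
    inits = []
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    inits.append(((lo.mean(), hi.mean()), (lo.std() + 0.01, hi.std() + 0.01), len(lo) / n))
    for q in np.linspace(0.15, 0.85, max(1, n_restarts - 2)):
        t = np.quantile(x, q)
        a, b = x[x <= t], x[x > t]
        if len(a) < 2 or len(b) < 2:
            continue
        inits.append(((a.mean(), b.mean()), (a.std() + 0.01, b.std() + 0.01), len(a) / n))
    jitter = rng.normal(0, sd1 / 2, size=2)
    inits.append(((mu1 + jitter[0], mu1 + jitter[1]), (sd1, sd1), 0.5))

    best = None
    for mu0, sd0, w0 in inits:
        mu, sd, w, ll = _em_two_gaussians(x, mu0, sd0, w0)
        if best is None or ll > best[3]:
            best = (mu, sd, w, ll)
    mu, sd, w, ll2 = best
    ll2 = max(ll2, ll1)  # the 2-component family nests the 1-component model
    if mu[0] > mu[1]:
        mu = mu[::-1]
        sd = sd[::-1]
        w = 1 - w
    bic2 = 5 * np.log(n) - 2 * ll2
    lrt = 2 * (ll2 - ll1)
    p = float(chi2.sf(lrt, df=3))
    return RegionFit(
        region, n_genes_expressed, scores, mu1, sd1, ll1, bic1,
        (float(mu[0]), float(mu[1])), (float(sd[0]), float(sd[1])), float(w),
        ll2, float(bic2), float(lrt), p,
    )


def filter_and_adjust(
    fits: list[RegionFit], p_cutoff: float = 0.01, bic_cutoff: float = 200.0
) -> list[RegionFit]:
    """BH-adjust LRT p values across regions and set the passed flag.

    passed requires adj_p < ``p_cutoff``, BIC1 - BIC2 > ``bic_cutoff`` and
    more than 10 expressed genes.
    """
    if not fits:
        raise ValueError("no fits to adjust")
    adj = bh_adjust(np.array([f.lrt_p for f in fits]))
    for f, a in zip(fits, adj):
        f.adj_p = float(a)
        f.passed = (
            f.adj_p < p_cutoff
            and f.delta_bic > bic_cutoff
            and f.n_genes_expressed > MIN_GENES_EXPRESSED
        )
    return fits


def posterior_scna(fit: RegionFit, confident_cutoff: float = 0.8) -> pd.DataFrame:
    """Per-cell posterior of the low/high-expression component.

    The component with the lower mean is labeled "low" (fewer copies under
    the dosage assumption). A cell is confidently assigned when its larger
    posterior reaches ``confident_cutoff``.
    """
    x = fit.scores.to_numpy(dtype=float)
    la = norm.logpdf(x, fit.means[0], max(fit.sds[0], SD_FLOOR)) + np.log(
        max(fit.weight_low, 1e-12)
    )
    lb = norm.logpdf(x, fit.means[1], max(fit.sds[1], SD_FLOOR)) + np.log(
        max(1 - fit.weight_low, 1e-12)
    )
    m = np.maximum(la, lb)
    p_low = np.exp(la - m) / (np.exp(la - m) + np.exp(lb - m))
    df = pd.DataFrame(
        {
            "cell_id": fit.scores.index,
            "chrom": fit.region[0],
            "start": fit.region[1],
            "end": fit.region[2],
            "p_low": p_low,
            "p_high": 1.0 - p_low,
        }
    )
    df["confident"] = np.maximum(df.p_low, df.p_high) >= confident_cutoff
    return df


def recall_regions(
    matrix: ExpressionCellMatrix,
    regions: list[tuple[str, int, int]],
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[RegionFit], pd.DataFrame]:
    """Run the full recalling: normalize, score, fit, filter, posteriors.

    Returns the fitted regions (all, with passed flags) and the per-cell
    posterior table concatenated over passed regions.
    """
    expr = normalize_expression(matrix)
    fits = []
    for i, region in enumerate(regions):
        sc = region_scores(region, expr)
        if sc is None:
            continue
        n_genes = _count_expressed(region, expr)
        fits.append(
            fit_region_mixture(sc, region, n_genes, n_restarts=n_restarts, seed=seed + i)
        )
    if not fits:
        return [], pd.DataFrame()
    fits = filter_and_adjust(fits)
    posts = [posterior_scna(f) for f in fits if f.passed]
    table = pd.concat(posts, ignore_index=True) if posts else pd.DataFrame()
    return fits, table


def _count_expressed(region: tuple[str, int, int], expr: NormalizedExpression) -> int:
    chrom, start, end = region
    g = expr.genes
    in_region = (g.chrom == chrom) & (g.start < end) & (g.end > start)
    gene_ids = g.gene_id[in_region]
    return int(expr.expressed.loc[gene_ids].sum())
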