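"""Downstream statistical operations shared across the pipeline.

Covers subclone differential expression with a cell-type covariate
(Welch t on residualized values), per-feature two-group Wilcoxon rank-sum
with BH correction, Fisher's exact 2x2 test, hypergeometric gene-set
over-representation, mean-expression signature scoring, and sequencing
coverage arithmetic. All multiple-testing correction routes through the one
``bh_adjust`` implementation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Remove a categorical covariate by least squares (one-hot design)."""
    cats, idx = np.unique(covariate, return_inverse=True)
    resid = values.astype(float).copy()
    for k in range(len(cats)):
        mask = idx == k
        resid[:, mask] -= resid[:, mask].mean(axis=1, keepdims=True)
    return resid


def pairwise_welch_de(
    values: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    celltype_covariate: pd.Series | None = None,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.1,
) -> pd.DataFrame:
    """Two-sided Welch t per gene between two cell groups.

    ``values`` is genes x cells of normalized expression. When a cell-type
    covariate is given, cell-type means are removed per gene first, so the
    group contrast is not driven by composition differences. The log
    fold-change is the difference of group means on the normalized
    (log-scale) values; only upregulated genes (positive lfc) are flagged,
    at BH FDR <= ``fdr_cut`` and lfc >= ``lfc_cut``.
    """
    cells = values.columns
    groups = groups.loc[cells]
    a_mask = (groups == group_a).to_numpy()
    b_mask = (groups == group_b).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs >= 2 cells")
    X = values.to_numpy(dtype=float)
    raw_lfc = X[:, a_mask].mean(axis=1) - X[:, b_mask].mean(axis=1)
    if celltype_covariate is not None:
        X = _residualize(X, celltype_covariate.loc[cells].to_numpy())
    A = X[:, a_mask]
    B = X[:, b_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene_id": values.index,
            "mean_a": values.to_numpy()[:, a_mask].mean(axis=1),
            "mean_b": values.to_numpy()[:, b_mask].mean(axis=1),
            "lfc": lfc,
            "lfc_unadjusted": raw_lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
        }
    )
    out["de"] = (out.fdr <= fdr_cut) & (out.lfc >= lfc_cut)
    return out


def wilcoxon_feature_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum tests with BH correction.

    ``values_a``/``values_b`` are (n_features, n_obs) arrays (observations
    may differ in count). Exact p for small samples (both sides <= 25),
    normal approximation with continuity correction otherwise. Features are
    flagged at BH FDR < ``fdr_cut``.
    """
    values_a = np.atleast_2d(values_a)
    values_b = np.atleast_2d(values_b)
    if values_a.shape[1] < 3 or values_b.shape[1] < 3:
        raise ValueError("need >= 3 observations per side")
    ps = []
    for a, b in zip(values_a, values_b):
        if np.ptp(np.concatenate([a, b])) < 1e-300:
            ps.append(1.0)
            continue
        method = "exact" if max(len(a), len(b)) <= 25 and not _has_ties(a, b) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        ps.append(float(res.pvalue))
    p = np.array(ps)
    fdr = bh_adjust(p)
    return pd.DataFrame({"p": p, "fdr": fdr, "significant": fdr < fdr_cut})


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    x = np.concatenate([a, b])
    return len(np.unique(x)) < len(x)


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns (sample odds ratio ad/bc, p). The two-sided p sums the
    probabilities of all tables with fixed margins no more probable than the
    observed one. Zero margins give p = 1 by convention.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate margin; p = 1 by convention", stacklevel=2)
        return np.inf if b * c == 0 else (a * d) / (b * c), 1.0
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def hypergeom_enrichment(
    de_genes: set, target_set: set, universe: set
) -> tuple[float, int]:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    Tests whether ``de_genes`` overlaps ``target_set`` more than expected
    when drawing |de_genes| genes from ``universe`` without replacement.
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes <= universe or not target_set <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    M = len(universe)
    n = len(target_set)
    N = len(de_genes)
    k = len(de_genes & target_set)
    p = float(sps.hypergeom.sf(k - 1, M, n, N))
    return p, k


def enrichment_table(
    de_genes: set, gene_sets: dict[str, set], universe: set, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Over-representation across a collection of gene sets, BH-corrected."""
    rows = []
    for name, gs in gene_sets.items():
        p, k = hypergeom_enrichment(de_genes, gs & universe, universe)
        rows.append({"gene_set": name, "overlap": k, "size": len(gs & universe), "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out.p.to_numpy())
    out["significant"] = out.fdr < fdr_cut
    return out


def signature_score(values: pd.DataFrame, gene_set: set) -> pd.Series:
    """Per-cell mean of normalized expression over signature genes.

    Genes absent from the matrix are dropped with a warning; the score of an
    all-zero cell is 0.
    """
    present = [g for g in values.index if g in gene_set]
    missing = gene_set - set(present)
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent; dropped", stacklevel=2)
    return values.loc[present].mean(axis=0)


def coverage_estimate(
    read_pairs: int, read_length_bp: int, genome_length_bp: float
) -> float:
    """Fold coverage from paired-end read counts.

    coverage = read_pairs x 2 x read_length / genome_length.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    if read_pairs < 0 or read_length_bp <= 0:
        raise ValueError("read counts and lengths must be positive")
    return read_pairs * 2 * read_length_bp / genome_length_bp


def spearman_concordance(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided asymptotic t p value.

    Ties are mid-ranked. Raises on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
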