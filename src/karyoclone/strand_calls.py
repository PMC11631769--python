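"""Per-cell structural variant calling from strand-resolved binned counts.

The tri-channel logic: read depth carries copy number, strand orientation
carries inversion status, and the per-chromosome template-strand
configuration of each cell (WW/WC/CC) determines which homolog emits on
which strand. In a WC chromosome the two homologs are separable within the
cell (one emits Watson, the other Crick); in WW/CC chromosomes only the
total over homologs is observable and haplotype-of-origin is reported as
unphased.

Pipeline: ``infer_strand_states`` -> ``segment_genome`` ->
``genotype_segments`` -> ``compile_calls``; ``call_svs`` runs all four.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .simulate import StrandCellMatrix

STATES = ("WW", "WC", "CC", "UNKNOWN")

# fraction of per-copy depth attributed to background mismapping; keeps
# zero-copy genotypes from having -inf likelihood on a stray read
BACKGROUND_RATE = 0.02


@dataclass(frozen=True)
class GenomeSegment:
    chrom: str
    start: int
    end: int
    bin_lo: int
    bin_hi: int

    @property
    def n_bins(self) -> int:
        return self.bin_hi - self.bin_lo


# ---------------------------------------------------------------------------
# strand-state typing


def infer_strand_states(
    matrix: StrandCellMatrix,
    min_reads: int = 20,
    ww_threshold: float = 0.8,
) -> pd.DataFrame:
    """Type each (cell, chromosome) as WW/WC/CC from its Watson fraction.

    Two passes: a first pass types chromosomes from all bins; a second pass
    masks candidate SV bins (pooled depth outliers, and bins where
    nominally one-strand cells show minor-strand reads) and retypes from the
    remaining bins, so large SVs do not distort the template call.
    """
    rows = []
    for chrom in matrix.genome.chrom_names:
        W = matrix.watson[chrom]
        C = matrix.crick[chrom]
        total = W + C
        w_tot = W.sum(axis=1)
        c_tot = C.sum(axis=1)
        n_reads = w_tot + c_tot
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_reads > 0, w_tot / np.maximum(n_reads, 1), 0.5)
        state1 = np.where(
            frac >= ww_threshold, "WW", np.where(frac <= 1 - ww_threshold, "CC", "WC")
        )

        # candidate-SV mask from pooled evidence
        pooled = total.mean(axis=0)
        med = np.median(pooled)
        depth_out = np.abs(pooled - med) > 0.25 * max(med, 1e-9)
        one_strand = (state1 == "WW") | (state1 == "CC")
        strand_out = np.zeros(total.shape[1], dtype=bool)
        if one_strand.any():
            minor = np.where(
                (state1 == "WW")[:, None], C, np.where((state1 == "CC")[:, None], W, 0)
            )[one_strand]
            tot_os = total[one_strand]
            minor_frac = minor.sum(axis=0) / np.maximum(tot_os.sum(axis=0), 1)
            strand_out = minor_frac > 0.2
        keep = ~(depth_out | strand_out)
        if keep.sum() < 10:
            keep = np.ones(total.shape[1], dtype=bool)

        w2 = W[:, keep].sum(axis=1)
        c2 = C[:, keep].sum(axis=1)
        n2 = w2 + c2
        # if masking removed too much signal for a cell, fall back to pass 1
        low = n2 < np.minimum(min_reads, n_reads)
        w2 = np.where(low, w_tot, w2)
        n2 = np.where(low, n_reads, n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac2 = np.where(n2 > 0, w2 / np.maximum(n2, 1), 0.5)
        state2 = np.where(
            frac2 >= ww_threshold, "WW", np.where(frac2 <= 1 - ww_threshold, "CC", "WC")
        )
        state2 = np.where(n_reads >= min_reads, state2, "UNKNOWN")
        for i in range(matrix.n_cells):
            rows.append(
                {
                    "cell_id": matrix.cells.cell_id.iloc[i],
                    "chrom": chrom,
                    "state": state2[i],
                    "watson_fraction": float(frac2[i]),
                    "n_reads": int(n_reads[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segmentation


def _segment_sse(csum: np.ndarray, csq: np.ndarray, lo: int, hi: int) -> float:
    """Within-segment squared error summed over channels; csum/csq are
    per-channel cumulative sums of x and x^2 with a leading zero."""
    s = csum[:, hi] - csum[:, lo]
    q = csq[:, hi] - csq[:, lo]
    n = hi - lo
    return float(np.sum(q - s * s / n))


def _binary_segmentation(X: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Breakpoints from recursive interval (circular binary) segmentation.

    X is (n_channels, T), standardized to unit noise variance. At each step
    the interval [i, j) maximizing the squared-error gain over the current
    segment is split out (i may coincide with the left edge and j with the
    right, recovering a plain binary split); ``penalty`` is charged per new
    changepoint. Testing an interval rather than a single split keeps short
    copy-number islands inside long flat chromosomes detectable.
    """
    nch, T = X.shape
    csum = np.zeros((nch, T + 1))
    csq = np.zeros((nch, T + 1))
    csum[:, 1:] = np.cumsum(X, axis=1)
    csq[:, 1:] = np.cumsum(X * X, axis=1)

    def sse_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """SSE of segments [a_k, b_k) summed over channels (0 if empty)."""
        n = (b - a).astype(float)
        s = csum[:, b] - csum[:, a]
        q = csq[:, b] - csq[:, a]
        with np.errstate(invalid="ignore", divide="ignore"):
            val = q - s * s / np.maximum(n, 1)
        return np.where(n > 0, val, 0.0).sum(axis=0)

    breaks: list[int] = []
    stack = [(0, T)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        base = _segment_sse(csum, csq, lo, hi)
        best_score, best_ij = 0.0, None
        for i in range(lo, hi - min_size + 1):
            if i != lo and i - lo < min_size:
                continue
            j0 = i + min_size
            j_arr = np.arange(j0, hi + 1)
            # right flank must be empty (j == hi) or >= min_size
            j_arr = j_arr[(j_arr == hi) | (hi - j_arr >= min_size)]
            if i == lo:
                j_arr = j_arr[j_arr != hi]  # no changepoint at all otherwise
            if j_arr.size == 0:
                continue
            i_arr = np.full(j_arr.shape, i)
            lo_arr = np.full(j_arr.shape, lo)
            hi_arr = np.full(j_arr.shape, hi)
            cost = sse_vec(lo_arr, i_arr) + sse_vec(i_arr, j_arr) + sse_vec(j_arr, hi_arr)
            n_new = (1 if i > lo else 0) + (j_arr < hi).astype(int)
            score = base - cost - penalty * n_new
            k = int(np.argmax(score))
            if score[k] > best_score:
                best_score = float(score[k])
                best_ij = (i, int(j_arr[k]))
        if best_ij is None:
            continue
        i, j = best_ij
        if i > lo:
            breaks.append(i)
            stack.append((lo, i))
        if j < hi:
            breaks.append(j)
            stack.append((j, hi))
        stack.append((i, j))
    return sorted(breaks)


def _robust_standardize(x: np.ndarray) -> np.ndarray:
    """Center on the median; scale by noise sigma from successive differences."""
    diffs = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0)
    if sigma <= 0:
        sigma = max(np.std(x), 1e-9)
    return (x - np.median(x)) / sigma


def segment_genome(
    matrix: StrandCellMatrix,
    states: pd.DataFrame | None = None,
    min_seg_bins: int = 3,
    penalty_factor: float = 1.5,
) -> list[GenomeSegment]:
    """Joint multi-sample segmentation of the binned counts.

    Three pooled channels per chromosome: (1) mean cell-normalized total
    depth; (2) minor-strand fraction pooled over WW/CC cells (sensitive to
    balanced inversions); (3) mean |W - C| imbalance over WC cells
    (sensitive to haplotype-confined copy changes). Channels are robustly
    standardized and segmented jointly by binary segmentation with a
    BIC-style penalty ``penalty_factor * (n_channels + 1) * log(T)``.
    """
    if matrix.n_cells < 1:
        raise ValueError("need at least one cell")
    if states is None:
        states = infer_strand_states(matrix)
    bs = matrix.genome.bin_size
    segments: list[GenomeSegment] = []
    for chrom in matrix.genome.chrom_names:
        W = matrix.watson[chrom]
        C = matrix.crick[chrom]
        total = W + C
        if total.sum() == 0:
            raise ValueError(f"all-zero count matrix on {chrom}")
        st = states.loc[states.chrom == chrom].set_index("cell_id").loc[
            matrix.cells.cell_id
        ]["state"].to_numpy()

        cell_mean = total.mean(axis=1, keepdims=True)
        norm_total = total / np.maximum(cell_mean, 1e-9)
        channels = [_robust_standardize(norm_total.mean(axis=0))]

        one = (st == "WW") | (st == "CC")
        if one.sum() >= 3:
            minor = np.where((st == "WW")[:, None], C, W)[one]
            minor_frac = minor.sum(axis=0) / np.maximum(total[one].sum(axis=0), 1)
            channels.append(_robust_standardize(minor_frac))
        wc = st == "WC"
        if wc.sum() >= 3:
            imbalance = np.abs(W[wc].astype(float) - C[wc]).mean(axis=0)
            scale = np.maximum(total[wc].mean(axis=0), 1e-9)
            channels.append(_robust_standardize(imbalance / scale))

        X = np.vstack(channels)
        T = X.shape[1]
        penalty = penalty_factor * (X.shape[0] + 1) * np.log(T)
        breaks = _binary_segmentation(X, penalty, min_seg_bins)
        edges = [0] + breaks + [T]
        for lo, hi in zip(edges[:-1], edges[1:]):
            segments.append(GenomeSegment(chrom, lo * bs, hi * bs, lo, hi))
    return segments


# ---------------------------------------------------------------------------
# depth / dispersion estimation


def estimate_depth_dispersion(
    matrix: StrandCellMatrix, states: pd.DataFrame
) -> tuple[float, float]:
    """Per-copy depth and per-strand NB dispersion from background bins.

    Background bins are those whose pooled depth is within 20% of the global
    median (assumed diploid). Dispersion is method-of-moments on
    single-strand counts of WC cells over background bins, floored at 2.
    """
    per_copy_samples = []
    strand_samples = []
    # global diploid level: median pooled depth over all bins of all
    # chromosomes, so a chromosome aberrant end-to-end cannot set its own
    # baseline
    all_pooled = np.concatenate(
        [
            (matrix.watson[c] + matrix.crick[c]).mean(axis=0)
            for c in matrix.genome.chrom_names
        ]
    )
    med = float(np.median(all_pooled))
    for chrom in matrix.genome.chrom_names:
        W = matrix.watson[chrom]
        C = matrix.crick[chrom]
        total = W + C
        pooled = total.mean(axis=0)
        bg = np.abs(pooled - med) <= 0.15 * max(med, 1e-9)
        if bg.sum() < 5:
            continue
        per_copy_samples.append(total[:, bg].ravel() / 2.0)
        st = states.loc[states.chrom == chrom].set_index("cell_id").loc[
            matrix.cells.cell_id
        ]["state"].to_numpy()
        wc = st == "WC"
        if wc.sum() >= 3:
            strand_samples.append(W[wc][:, bg].ravel())
            strand_samples.append(C[wc][:, bg].ravel())
    if not per_copy_samples:
        raise ValueError("no diploid background bins found")
    depth = float(np.concatenate(per_copy_samples).mean())
    if strand_samples:
        s = np.concatenate(strand_samples).astype(float)
        m, v = s.mean(), s.var(ddof=1)
        phi = m * m / (v - m) if v > m else np.inf
    else:
        phi = np.inf
    return depth, float(max(min(phi, 1e6), 2.0))


# ---------------------------------------------------------------------------
# genotyping


def _hap_states(hap_cn_max: int) -> list[tuple[int, int]]:
    return [
        (f, i)
        for f in range(hap_cn_max + 1)
        for i in range(hap_cn_max + 1 - f)
    ]


def _hap_label(f: int, i: int) -> str:
    if (f, i) == (1, 0):
        return "REF"
    cn = f + i
    if cn == 0:
        return "DEL"
    if (f, i) == (0, 1):
        return "INV"
    if (f, i) == (2, 0):
        return "DUP"
    if (f, i) == (1, 1):
        return "INVDUP"
    if i == 0 and cn > 2:
        return "DUP"
    return "COMPLEX"


def sv_label(
    h1: tuple[int, int], h2: tuple[int, int], whole_chromosome: bool = False
) -> str:
    """Deterministic SV label from per-homolog (forward, inverted) copies."""
    l1, l2 = _hap_label(*h1), _hap_label(*h2)
    if l1 == "REF" and l2 == "REF":
        return "REF"
    if l1 != "REF" and l2 != "REF":
        return "COMPLEX"
    lab = l1 if l1 != "REF" else l2
    if whole_chromosome:
        if lab == "DUP" and sum(h1) + sum(h2) == 3:
            return "WC_GAIN"
        if lab == "DEL":
            return "WC_LOSS"
    return lab


def _pair_simplicity(pair: tuple[tuple[int, int], tuple[int, int]]) -> tuple:
    """Deterministic preference order among likelihood-equivalent genotypes:
    fewer altered homologs, then fewer inverted copies, then smaller total
    copy change, then lexicographic."""
    a, b = pair
    n_alt = int(a != (1, 0)) + int(b != (1, 0))
    n_inv = a[1] + b[1]
    dcn = abs(sum(a) - 1) + abs(sum(b) - 1)
    return (n_alt, n_inv, dcn, pair)


def _signature(pair, cfg: str) -> tuple[int, int]:
    """Expected (Watson, Crick) copy multipliers of a genotype under one
    template configuration; genotypes sharing a signature are
    indistinguishable within the cell."""
    a, b = pair
    if cfg == "WC":
        return (a[0] + b[1], b[0] + a[1])
    if cfg == "WW":
        return (a[0] + b[0], a[1] + b[1])
    return (a[1] + b[1], a[0] + b[0])  # CC


def _class_grid(pairs, cfg: str, prior_ref: float):
    """Group the candidate grid into likelihood-equivalence classes.

    Returns (reps, w_mult, c_mult, log_prior) where each class carries the
    summed prior of its members and its simplest member as representative.
    """
    classes: dict[tuple[int, int], list] = {}
    for p in pairs:
        classes.setdefault(_signature(p, cfg), []).append(p)
    prior_alt = (1.0 - prior_ref) / (len(pairs) - 1)
    reps, wm, cm, logp = [], [], [], []
    for sig, members in sorted(classes.items()):
        rep = min(members, key=_pair_simplicity)
        prior = sum(
            prior_ref if m == ((1, 0), (1, 0)) else prior_alt for m in members
        )
        reps.append(rep)
        wm.append(sig[0])
        cm.append(sig[1])
        logp.append(np.log(prior))
    return reps, np.array(wm), np.array(cm), np.array(logp)


def genotype_segments(
    matrix: StrandCellMatrix,
    segments: list[GenomeSegment],
    states: pd.DataFrame | None = None,
    hap_cn_max: int = 4,
    cn_max: int = 6,
    prior_ref: float = 0.5,
) -> pd.DataFrame:
    """MAP genotype for every (cell, segment) by exhaustive enumeration.

    Candidates are per-homolog (forward, inverted) copy pairs, jointly
    capped at ``cn_max`` total copies. Expected Watson/Crick totals over the
    segment follow from each homolog's template strand (inverted copies emit
    opposite); the likelihood is negative binomial on per-strand segment
    totals (a sum of per-bin NB terms with common mean). Genotypes that are
    indistinguishable within the cell (identical expected strand signature
    under its template configuration) are collapsed into one class whose
    prior is the sum over members -- e.g. a duplication of the
    Watson-template homolog and an inverted duplication of the other homolog
    emit identically in a WC chromosome. The posterior puts ``prior_ref``
    mass on the reference genotype and spreads the rest uniformly over
    alternatives; the MAP class is reported through its simplest member.
    """
    if states is None:
        states = infer_strand_states(matrix)
    depth, phi = estimate_depth_dispersion(matrix, states)
    hs = _hap_states(hap_cn_max)
    pairs = [(a, b) for a, b in product(hs, hs) if sum(a) + sum(b) <= cn_max]
    grids = {cfg: _class_grid(pairs, cfg, prior_ref) for cfg in ("WC", "WW", "CC")}

    state_lookup = states.set_index(["cell_id", "chrom"])["state"]
    cell_ids = matrix.cells.cell_id.to_numpy()
    rows = []
    for seg in segments:
        W = matrix.watson[seg.chrom][:, seg.bin_lo : seg.bin_hi].sum(axis=1)
        C = matrix.crick[seg.chrom][:, seg.bin_lo : seg.bin_hi].sum(axis=1)
        D = depth * seg.n_bins
        eps = BACKGROUND_RATE * D
        phi_tot = phi * seg.n_bins
        whole = seg.n_bins == matrix.genome.n_bins(seg.chrom)
        st = np.array([state_lookup[(cid, seg.chrom)] for cid in cell_ids])
        for cfg in ("WC", "WW", "CC", "UNKNOWN"):
            idx = np.flatnonzero(st == cfg)
            if idx.size == 0:
                continue
            if cfg == "UNKNOWN":
                for i in idx:
                    rows.append(_untyped_row(cell_ids[i], seg))
                continue
            reps, wmult, cmult, log_prior = grids[cfg]
            ref_class = reps.index(((1, 0), (1, 0)))
            mu_w = D * wmult + eps
            mu_c = D * cmult + eps
            pw = phi_tot / (phi_tot + mu_w)
            pc = phi_tot / (phi_tot + mu_c)
            ll = (
                nbinom.logpmf(W[idx][:, None], phi_tot, pw[None, :])
                + nbinom.logpmf(C[idx][:, None], phi_tot, pc[None, :])
            )
            post = ll + log_prior[None, :]
            post -= post.max(axis=1, keepdims=True)
            post = np.exp(post)
            post /= post.sum(axis=1, keepdims=True)
            map_idx = post.argmax(axis=1)
            for k, i in enumerate(idx):
                a, b = reps[map_idx[k]]
                label = sv_label(a, b, whole_chromosome=whole)
                rows.append(
                    {
                        "cell_id": cell_ids[i],
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "n_bins": seg.n_bins,
                        "config": cfg,
                        "cn_h1": sum(a),
                        "cn_h2": sum(b),
                        "inverted_h1": a[1] > 0,
                        "inverted_h2": b[1] > 0,
                        "phased": cfg == "WC",
                        "sv_label": label,
                        "log_likelihood": float(ll[k, map_idx[k]]),
                        "posterior": float(post[k, map_idx[k]]),
                        "posterior_ref": float(post[k, ref_class]),
                    }
                )
    return pd.DataFrame(rows)


def _untyped_row(cell_id: str, seg: GenomeSegment) -> dict:
    return {
        "cell_id": cell_id,
        "chrom": seg.chrom,
        "start": seg.start,
        "end": seg.end,
        "n_bins": seg.n_bins,
        "config": "UNKNOWN",
        "cn_h1": -1,
        "cn_h2": -1,
        "inverted_h1": False,
        "inverted_h2": False,
        "phased": False,
        "sv_label": "UNTYPED",
        "log_likelihood": np.nan,
        "posterior": np.nan,
    }


def genotype_posteriors(
    matrix: StrandCellMatrix,
    cell_id: str,
    segment: GenomeSegment,
    states: pd.DataFrame,
    hap_cn_max: int = 4,
    cn_max: int = 6,
    prior_ref: float = 0.5,
) -> pd.DataFrame:
    """Full posterior over the candidate grid for one (cell, segment).

    Exposes the enumeration that ``genotype_segments`` reduces to a MAP, for
    inspection and for validating against independent re-enumeration.
    """
    sub = StrandCellMatrix(
        genome=matrix.genome,
        cells=matrix.cells,
        watson=matrix.watson,
        crick=matrix.crick,
        templates=matrix.templates,
        depth_per_copy=matrix.depth_per_copy,
        nb_dispersion=matrix.nb_dispersion,
    )
    depth, phi = estimate_depth_dispersion(sub, states)
    st = states.set_index(["cell_id", "chrom"])["state"][(cell_id, segment.chrom)]
    i = int(np.flatnonzero(matrix.cells.cell_id.to_numpy() == cell_id)[0])
    W = int(matrix.watson[segment.chrom][i, segment.bin_lo : segment.bin_hi].sum())
    C = int(matrix.crick[segment.chrom][i, segment.bin_lo : segment.bin_hi].sum())
    hs = _hap_states(hap_cn_max)
    pairs = [(a, b) for a, b in product(hs, hs) if sum(a) + sum(b) <= cn_max]
    D = depth * segment.n_bins
    eps = BACKGROUND_RATE * D
    phi_tot = phi * segment.n_bins
    rows = []
    for a, b in pairs:
        if st == "WC":
            mu_w = D * (a[0] + b[1]) + eps
            mu_c = D * (b[0] + a[1]) + eps
        elif st == "WW":
            mu_w = D * (a[0] + b[0]) + eps
            mu_c = D * (a[1] + b[1]) + eps
        elif st == "CC":
            mu_w = D * (a[1] + b[1]) + eps
            mu_c = D * (a[0] + b[0]) + eps
        else:
            raise ValueError("cannot genotype an UNKNOWN-state chromosome")
        ll = float(
            nbinom.logpmf(W, phi_tot, phi_tot / (phi_tot + mu_w))
            + nbinom.logpmf(C, phi_tot, phi_tot / (phi_tot + mu_c))
        )
        prior = 0.5 if (a, b) == ((1, 0), (1, 0)) else 0.5 / (len(pairs) - 1)
        rows.append({"h1": a, "h2": b, "log_likelihood": ll, "log_prior": np.log(prior)})
    df = pd.DataFrame(rows)
    unnorm = df.log_likelihood + df.log_prior
    w = np.exp(unnorm - unnorm.max())
    df["posterior"] = w / w.sum()
    return df


# ---------------------------------------------------------------------------
# call compilation


def harmonize_labels(calls: pd.DataFrame) -> pd.DataFrame:
    """Resolve orientation labels across cells at each segment.

    Within a WC chromosome a duplicated copy's orientation is invisible (its
    reads land on a strand either way), so such cells report the simplest
    class member (DUP/WC_GAIN). Cells whose chromosome is WW or CC see
    inverted copies directly on the minor strand. Majority vote among those
    orientation-informative cells decides between DUP-like and INVDUP at
    each segment and the winning label is applied to all cells carrying the
    gain there.
    """
    if calls.empty:
        return calls
    calls = calls.copy()
    orientation = {"DUP", "INVDUP", "WC_GAIN"}
    for (_chrom, _start, _end), grp in calls.groupby(["chrom", "start", "end"]):
        for _cn, sub in grp.groupby(grp.cn_h1 + grp.cn_h2):
            labels = set(sub.sv_label)
            if len(labels) < 2:
                continue
            if labels <= orientation:
                # DUP vs INVDUP: orientation is visible only in WW/CC cells
                informative = sub[sub.config.isin(("WW", "CC"))]
            else:
                # e.g. COMPLEX (both homologs) vs DUP: the copy split across
                # homologs is visible only in phased (WC) cells
                informative = sub[sub.phased]
            if informative.empty:
                informative = sub
            winner = informative.sv_label.mode().iloc[0]
            calls.loc[sub.index, "sv_label"] = winner
    return calls


def compile_calls(genotypes: pd.DataFrame, call_threshold: float = 0.8) -> pd.DataFrame:
    """Retain confident non-reference calls; flag singletons.

    A call passes with posterior >= ``call_threshold`` and a minimum effect
    (a copy-number change or an inversion flag). Gain-orientation labels are
    harmonized across cells (see ``harmonize_labels``). A call is a
    singleton when its (segment, sv_label) combination occurs in exactly
    one cell.
    """
    g = genotypes
    alt = g[(g.sv_label != "REF") & (g.sv_label != "UNTYPED")].copy()
    effect = (
        (alt.cn_h1 != 1) | (alt.cn_h2 != 1) | alt.inverted_h1 | alt.inverted_h2
    )
    calls = alt[(alt.posterior >= call_threshold) & effect].copy()
    if calls.empty:
        return calls.assign(singleton=pd.Series(dtype=bool))
    calls = harmonize_labels(calls)
    key = calls[["chrom", "start", "end", "sv_label"]].apply(tuple, axis=1)
    counts = key.value_counts()
    calls["singleton"] = key.map(counts).eq(1).to_numpy()
    return calls.reset_index(drop=True)


def call_svs(
    matrix: StrandCellMatrix,
    min_seg_bins: int = 3,
    penalty_factor: float = 1.5,
    call_threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[GenomeSegment], pd.DataFrame, pd.DataFrame]:
    """Full calling pipeline: states, segments, genotypes, compiled calls."""
    states = infer_strand_states(matrix)
    segments = segment_genome(matrix, states, min_seg_bins, penalty_factor)
    genotypes = genotype_segments(matrix, segments, states)
    calls = compile_calls(genotypes, call_threshold)
    return states, segments, genotypes, calls


# ---------------------------------------------------------------------------
# noise-free calls from ground truth


def ground_truth_calls(tree, cells: pd.DataFrame) -> pd.DataFrame:
    """The call table a perfect caller would produce for ``cells``.

    ``cells`` must carry cell_id and clone_id columns (as produced by the
    simulator); every altered segment of the cell's clone karyotype becomes
    one fully confident call. Used as the noise-free reference for recovery
    invariants.
    """
    rows = []
    per_clone = {}
    for cid in tree.clone_ids:
        kt = tree.karyotype_of(cid)
        segs = []
        for chrom, start, end, h1, h2 in kt.altered_segment_states():
            whole = (end - start) == tree.genome.chrom_length(chrom)
            segs.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_bins": (end - start) // tree.genome.bin_size,
                    "config": "TRUTH",
                    "cn_h1": sum(h1),
                    "cn_h2": sum(h2),
                    "inverted_h1": h1[1] > 0,
                    "inverted_h2": h2[1] > 0,
                    "phased": True,
                    "sv_label": sv_label(h1, h2, whole_chromosome=whole),
                    "log_likelihood": 0.0,
                    "posterior": 1.0,
                    "posterior_ref": 0.0,
                }
            )
        per_clone[cid] = segs
    for r in cells.itertuples():
        for seg in per_clone[r.clone_id]:
            rows.append({"cell_id": r.cell_id, **seg})
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls.assign(singleton=pd.Series(dtype=bool))
    key = calls[["chrom", "start", "end", "sv_label"]].apply(tuple, axis=1)
    counts = key.value_counts()
    calls["singleton"] = key.map(counts).eq(1).to_numpy()
    return calls
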