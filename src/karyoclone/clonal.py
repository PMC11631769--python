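"""Subclone definition, clonal hierarchy and karyotype-heterogeneity metrics.

SV burden is the number of SV-altered genomic segments per cell (adjacent
called segments in the same state are merged, so one complex event spanning
several called segments with a shared state counts once per distinct state
block); the standard deviation of per-cell burdens quantifies intrapatient
karyotype heterogeneity. Subclones are groups of >= 3 cells sharing a set of
structural variants, found by Ward clustering of binary SV genotypes on
Jaccard distance; the clonal hierarchy follows from signature containment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

SVKey = tuple  # (chrom, start, end, sv_label)


def _merged_cell_segments(cell_calls: pd.DataFrame) -> int:
    """Count state blocks for one cell: adjacent called segments with equal
    genotype state merge into one."""
    n = 0
    for _chrom, grp in cell_calls.groupby("chrom"):
        grp = grp.sort_values("start")
        prev_end, prev_state = None, None
        for row in grp.itertuples():
            state = (row.cn_h1, row.cn_h2, row.inverted_h1, row.inverted_h2, row.sv_label)
            if prev_end is not None and row.start == prev_end and state == prev_state:
                prev_end = row.end
                continue
            n += 1
            prev_end, prev_state = row.end, state
    return n


def sv_burden(calls: pd.DataFrame, cell_id: str) -> int:
    """Number of SV-altered segments carried by one cell."""
    if calls.empty or cell_id not in set(calls.cell_id):
        warnings.warn(f"no calls for cell {cell_id}; burden 0", stacklevel=2)
        return 0
    sub = calls[calls.cell_id == cell_id].drop_duplicates(["chrom", "start", "end"])
    return _merged_cell_segments(sub)


def burden_profile(calls: pd.DataFrame, cell_ids: list[str]) -> pd.Series:
    """Per-cell SV burden over an explicit cell list (absent cells get 0)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cid in cell_ids:
            out[cid] = sv_burden(calls, cid)
    return pd.Series(out, name="sv_burden")


def karyotype_heterogeneity(burdens) -> float:
    """Sample standard deviation (n-1 denominator) of per-cell SV burdens."""
    b = np.asarray(list(burdens), dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs at least two cells")
    return float(np.std(b, ddof=1))


def cell_fraction(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded half-away-from-zero to ``decimals`` places."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    pct = 100.0 * k / n
    scale = 10 ** decimals
    return math.floor(pct * scale + 0.5) / scale


@dataclass
class SubcloneSet:
    """Cell-to-subclone labels with per-subclone SV signatures."""

    labels: pd.Series  # index cell_id -> subclone label
    signatures: dict[str, frozenset]  # label -> SV keys
    progeny_exception: set[str] = field(default_factory=set)

    @property
    def subclone_ids(self) -> list[str]:
        return sorted(self.signatures, key=lambda s: (-(self.labels == s).sum(), s))

    def n_cells(self, label: str) -> int:
        return int((self.labels == label).sum())

    def fractions(self, decimals: int = 1) -> dict[str, float]:
        n = len(self.labels)
        return {s: cell_fraction(self.n_cells(s), n, decimals) for s in self.subclone_ids}


def _signature(matrix: pd.DataFrame, members: np.ndarray, presence_frac: float) -> frozenset:
    sub = matrix.loc[members]
    frac = sub.mean(axis=0)
    return frozenset(frac.index[frac >= presence_frac])


def sv_genotype_matrix(calls: pd.DataFrame, cell_ids: list[str]) -> pd.DataFrame:
    """Binary cell x SV-key matrix over distinct (segment, label) calls."""
    keys = sorted(
        {(r.chrom, r.start, r.end, r.sv_label) for r in calls.itertuples()}
    )
    mat = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"), columns=keys, dtype=int)
    for r in calls.itertuples():
        mat.loc[r.cell_id, [(r.chrom, r.start, r.end, r.sv_label)]] = 1
    return mat


def _resolve_clusters(
    mat: pd.DataFrame,
    lab: np.ndarray,
    min_cells: int,
    presence_frac: float,
):
    """Post-process a dendrogram cut: keep clusters >= min_cells, flag small
    clusters whose signature strictly extends a retained one (clear
    progeny), merge the rest into the most signature-similar cluster."""
    clusters: dict[int, list[str]] = {
        int(c): list(mat.index[lab == c]) for c in np.unique(lab)
    }
    sigs = {c: _signature(mat, np.array(m), presence_frac) for c, m in clusters.items()}
    retained = {c for c, m in clusters.items() if len(m) >= min_cells}
    progeny = {
        c
        for c in clusters
        if c not in retained and any(sigs[c] > sigs[r] for r in retained)
    }
    for c in list(clusters):
        if c in retained or c in progeny:
            continue
        targets = sorted(retained | progeny)
        if not targets:
            retained.add(c)
            continue

        def overlap(t):
            a, b = sigs[c], sigs[t]
            union = len(a | b)
            return len(a & b) / union if union else 1.0

        tgt = max(targets, key=lambda t: (overlap(t), len(clusters[t])))
        clusters[tgt].extend(clusters.pop(c))
        sigs[tgt] = _signature(mat, np.array(clusters[tgt]), presence_frac)
        sigs.pop(c)
    return clusters, sigs, progeny


def _merge_dropout_clusters(
    clusters: dict,
    sigs: dict,
    progeny: set,
    genotypes: pd.DataFrame,
    palt_threshold: float,
    mat: pd.DataFrame,
    presence_frac: float,
):
    """Merge clusters that look like call-dropout shadows of a larger clone.

    If sig(A) is a strict subset of sig(B), cluster A either predates B's
    private SVs (a true ancestral clone) or consists of B cells whose calls
    at those segments fell below the call threshold. The soft evidence
    separates the two: the mean non-reference posterior of A's cells at the
    distinguishing segments is near the background rate for a true ancestor
    but substantially elevated for dropout.
    """
    palt = (1.0 - genotypes.posterior_ref).rename("palt")
    lut = pd.concat([genotypes[["cell_id", "chrom", "start", "end"]], palt], axis=1)
    lut = lut.groupby(["cell_id", "chrom", "start", "end"])["palt"].max()
    all_segs = {(k[0], k[1], k[2]) for k in mat.columns}

    def mean_palt(members, segset):
        vals = []
        for cid in members:
            for seg in segset:
                key = (cid, *seg)
                if key in lut.index:
                    vals.append(float(lut.loc[key]))
        return float(np.mean(vals)) if vals else np.nan

    changed = True
    while changed:
        changed = False
        for a in sorted(clusters, key=lambda c: len(clusters[c])):
            best_b, best_obs = None, -np.inf
            for b in clusters:
                if a == b or not (sigs[a] < sigs[b]):
                    continue
                diff = {(k[0], k[1], k[2]) for k in sigs[b] - sigs[a]}
                observed = mean_palt(clusters[a], diff)
                bg_segs = all_segs - {(k[0], k[1], k[2]) for k in sigs[b]}
                bg = mean_palt(clusters[a], bg_segs)
                if np.isnan(bg):
                    bg = 0.05
                # dropout evidence: clearly above both the floor and the
                # cluster's own posterior level at truly absent segments
                if not np.isnan(observed) and observed > max(palt_threshold, 3.0 * bg):
                    if observed > best_obs:
                        best_b, best_obs = b, observed
            if best_b is not None:
                clusters[best_b].extend(clusters.pop(a))
                sigs[best_b] = _signature(mat, np.array(clusters[best_b]), presence_frac)
                sigs.pop(a)
                progeny.discard(a)
                changed = True
                break
    return clusters, sigs, progeny


def define_subclones(
    calls: pd.DataFrame,
    cell_ids: list[str],
    min_cells: int = 3,
    presence_frac: float = 2.0 / 3.0,
    max_subclones: int = 12,
    drop_singletons: bool = True,
    genotypes: pd.DataFrame | None = None,
    palt_threshold: float = 0.15,
) -> SubcloneSet:
    """Group cells into subclones by shared structural variants.

    Calls flagged as singletons (one cell only) are excluded from clonality
    analysis by default -- a private event, real or spurious, says nothing
    about shared ancestry. Cells are encoded as binary vectors over distinct
    (segment, sv_label) keys and clustered with Ward linkage on Jaccard
    distance. Dendrogram cuts of increasing k are post-processed (clusters
    below ``min_cells`` merge into the most signature-similar cluster unless
    their signature strictly extends a retained one -- clear progeny); the
    finest cut whose resulting cluster signatures (SVs in >=
    ``presence_frac`` of members) are pairwise distinct is kept.

    When the full ``genotypes`` table is supplied, clusters whose signature
    is a strict subset of another's and whose cells show elevated
    non-reference posterior at the distinguishing segments are folded into
    the larger clone (call dropout, not ancestry); see
    ``_merge_dropout_clusters``.
    """
    cell_ids = list(cell_ids)
    if genotypes is not None and not genotypes.empty:
        # cluster on MAP genotypes rather than the thresholded call table: a
        # borderline-confidence call still carries grouping information, and
        # per-cell dropout at the reporting threshold would otherwise split
        # clones. Labels are collapsed to the dosage direction (gain / loss /
        # copy-neutral inversion) so that copy-number ambiguity between
        # adjacent states (e.g. one- vs two-copy gain) does not split a
        # clone either.
        alt = genotypes[~genotypes.sv_label.isin(("REF", "UNTYPED"))].copy()
        effect = (alt.cn_h1 != 1) | (alt.cn_h2 != 1) | alt.inverted_h1 | alt.inverted_h2
        calls = alt[effect].copy()
        if not calls.empty:
            total = calls.cn_h1 + calls.cn_h2
            calls["sv_label"] = np.where(total > 2, "gain", np.where(total < 2, "loss", "inv"))
            key = calls[["chrom", "start", "end", "sv_label"]].apply(tuple, axis=1)
            counts = key.value_counts()
            calls["singleton"] = key.map(counts).eq(1).to_numpy()
    if drop_singletons and "singleton" in calls.columns and not calls.empty:
        calls = calls[~calls.singleton]
    if calls.empty:
        labels = pd.Series("SC1", index=pd.Index(cell_ids, name="cell_id"))
        return SubcloneSet(labels, {"SC1": frozenset()})
    mat = sv_genotype_matrix(calls, cell_ids)
    X = mat.to_numpy()
    if len(cell_ids) == 1:
        labels = pd.Series("SC1", index=mat.index)
        return SubcloneSet(labels, {"SC1": frozenset(mat.columns[X[0] > 0])})

    dist = pdist(X, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero cells are identical
    Z = linkage(dist, method="ward")

    best = None
    for k in range(1, min(max_subclones, len(cell_ids)) + 1):
        lab = fcluster(Z, t=k, criterion="maxclust")
        clusters, sigs, progeny = _resolve_clusters(mat, lab, min_cells, presence_frac)
        if genotypes is not None and "posterior_ref" in genotypes.columns:
            clusters, sigs, progeny = _merge_dropout_clusters(
                clusters, sigs, progeny, genotypes, palt_threshold, mat, presence_frac
            )
        if len(set(sigs.values())) == len(sigs):
            best = (clusters, sigs, progeny)
    if best is None:  # pragma: no cover - k=1 always passes
        lab = np.ones(len(cell_ids), dtype=int)
        best = _resolve_clusters(mat, lab, min_cells, presence_frac)
    clusters, sigs, progeny = best

    order = sorted(clusters, key=lambda c: (-len(clusters[c]), c))
    rename = {c: f"SC{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series(index=mat.index, dtype=object)
    for c, members in clusters.items():
        labels.loc[members] = rename[c]
    return SubcloneSet(
        labels=labels,
        signatures={rename[c]: sigs[c] for c in clusters},
        progeny_exception={rename[c] for c in progeny},
    )


@dataclass
class CloneHierarchy:
    """Parent links between subclones derived from signature containment."""

    parents: dict[str, str | None]
    trunk: frozenset
    classification: str  # monoclonal | linear | branched

    def children(self, node: str | None) -> list[str]:
        return sorted(k for k, v in self.parents.items() if v == node)


def build_hierarchy(subclones: SubcloneSet) -> CloneHierarchy:
    """Order subclones by signature containment.

    The trunk is the intersection of all signatures. A node's parent is the
    node with the largest signature strictly contained in its own (ties
    broken by larger cell count, then label); nodes with no container are
    roots (parent None). Classification: one subclone -> monoclonal; all
    nodes on a single chain -> linear; otherwise branched.
    """
    ids = subclones.subclone_ids
    if not ids:
        raise ValueError("no subclones")
    sigs = subclones.signatures
    trunk = frozenset.intersection(*[sigs[s] for s in ids]) if ids else frozenset()
    parents: dict[str, str | None] = {}
    for s in ids:
        candidates = [t for t in ids if t != s and sigs[t] < sigs[s]]
        if not candidates:
            parents[s] = None
        else:
            parents[s] = max(
                candidates, key=lambda t: (len(sigs[t]), subclones.n_cells(t), t)
            )
    if len(ids) == 1:
        cls = "monoclonal"
    else:
        n_children = {s: 0 for s in [None] + ids}
        for s, p in parents.items():
            n_children[p] += 1
        roots = [s for s, p in parents.items() if p is None]
        single_chain = len(roots) == 1 and all(
            n_children[s] <= 1 for s in ids
        )
        cls = "linear" if single_chain else "branched"
    return CloneHierarchy(parents=parents, trunk=trunk, classification=cls)
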