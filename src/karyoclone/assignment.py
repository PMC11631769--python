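"""Assignment of expression cells to genome-defined subclones.

Passed SCNA regions act as marker structural variants: for every subclone
the expected mixture component at each marker (low/high/neutral) follows
from the clone's copy number over the region. A cell's clone posterior is
the normalized product of its per-marker component posteriors over the
informative markers; cells below the confidence cutoff stay unassigned.
Also detects pre-leukemic (marker-free, HSPC-labeled) cells and quantifies
cross-modality concordance of subclone fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .karyotype import HaplotypeKaryotype
from .stats import spearman_concordance

Region = tuple[str, int, int]


def region_copy_number(karyotype: HaplotypeKaryotype, region: Region) -> float:
    """Mean total copy number of a karyotype over a region (bin-weighted)."""
    chrom, start, end = region
    genome = karyotype.genome
    b0 = start // genome.bin_size
    b1 = max(b0 + 1, min(end, genome.chrom_length(chrom)) // genome.bin_size)
    return float(karyotype.total_cn(chrom)[b0:b1].mean())


@dataclass
class MarkerProfile:
    """Expected component per subclone per marker region.

    ``expectations[clone][region]`` is "low", "high" or "neutral"; a region
    is informative for a clone pair when their expectations differ and
    neither is neutral-ambiguous. Clone pairs separated by no marker are
    merged for assignment purposes (reported in ``merged_groups``).
    """

    regions: list[Region]
    expectations: dict[str, dict[Region, str]]
    merged_groups: dict[str, str]  # original clone -> assignment group

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.merged_groups.values()))

    def informative_markers(self, group_a: str, group_b: str) -> list[Region]:
        ea = self.expectations[group_a]
        eb = self.expectations[group_b]
        return [r for r in self.regions if ea[r] != eb[r]]


def build_marker_profiles(
    clone_karyotypes: dict[str, HaplotypeKaryotype],
    passed_regions: list[Region],
) -> MarkerProfile:
    """Derive expected components from clone copy numbers over passed regions.

    A clone expects the "low" component where its copy number over the
    region is below the diploid reference, "high" where above, "neutral"
    where equal. Within the two-component mixture, neutral and the majority
    state are not separable per region; the expectation is used relative to
    the other clones (see ``assign_cells``). Clones identical over all
    passed regions are merged into one assignment group.
    """
    if not passed_regions:
        raise ValueError("no passed regions to build marker profiles from")
    expectations: dict[str, dict[Region, str]] = {}
    for clone, kt in clone_karyotypes.items():
        exp = {}
        for region in passed_regions:
            cn = region_copy_number(kt, region)
            exp[region] = "low" if cn < 2 - 1e-9 else "high" if cn > 2 + 1e-9 else "neutral"
        expectations[clone] = exp

    clones = sorted(clone_karyotypes)
    merged: dict[str, str] = {}
    for c in clones:
        placed = False
        for rep in sorted(set(merged.values())):
            if all(expectations[c][r] == expectations[rep][r] for r in passed_regions):
                merged[c] = rep
                placed = True
                break
        if not placed:
            merged[c] = c
    groups = sorted(set(merged.values()))
    if len(groups) == 1 and len(clones) > 1:
        raise ValueError("no informative markers separate any pair of clones")
    return MarkerProfile(
        regions=list(passed_regions),
        expectations={g: expectations[g] for g in groups},
        merged_groups=merged,
    )


def build_marker_profiles_from_calls(
    subclone_signatures: dict[str, frozenset],
    calls: "pd.DataFrame",
    passed_regions: list[Region],
) -> MarkerProfile:
    """Marker expectations from called genotypes instead of true karyotypes.

    For each subclone and passed region, the expected component follows from
    the copy number of the subclone's signature calls overlapping the region
    (median cn_h1 + cn_h2 over overlapping signature segments; no overlap
    means diploid/neutral). This is the fully inferred route: nothing from
    the simulation ground truth enters.
    """
    if not passed_regions:
        raise ValueError("no passed regions to build marker profiles from")
    call_cn = (
        calls.groupby(["chrom", "start", "end", "sv_label"])[["cn_h1", "cn_h2"]]
        .median()
        .sum(axis=1)
    )
    expectations: dict[str, dict[Region, str]] = {}
    for clone, sig in subclone_signatures.items():
        exp = {}
        for region in passed_regions:
            chrom, start, end = region
            states = []
            for key in sig:
                k_chrom, k_start, k_end, k_label = key[0], key[1], key[2], key[3]
                if k_chrom != chrom or k_start >= end or k_end <= start:
                    continue
                if k_label in ("gain", "loss", "inv"):
                    # dosage-direction signature keys carry the state directly
                    states.append({"gain": "high", "loss": "low", "inv": "neutral"}[k_label])
                elif key in call_cn.index:
                    cn = float(call_cn.loc[key])
                    states.append(
                        "low" if cn < 2 - 1e-9 else "high" if cn > 2 + 1e-9 else "neutral"
                    )
            non_neutral = [s for s in states if s != "neutral"]
            if not non_neutral:
                exp[region] = "neutral"
            else:
                exp[region] = max(set(non_neutral), key=non_neutral.count)
        expectations[clone] = exp

    clones = sorted(subclone_signatures)
    merged: dict[str, str] = {}
    for c in clones:
        placed = False
        for rep in sorted(set(merged.values())):
            if all(expectations[c][r] == expectations[rep][r] for r in passed_regions):
                merged[c] = rep
                placed = True
                break
        if not placed:
            merged[c] = c
    groups = sorted(set(merged.values()))
    if len(groups) == 1 and len(clones) > 1:
        raise ValueError("no informative markers separate any pair of clones")
    return MarkerProfile(
        regions=list(passed_regions),
        expectations={g: expectations[g] for g in groups},
        merged_groups=merged,
    )


def assign_cells(
    posteriors: pd.DataFrame,
    profile: MarkerProfile,
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Assign each cell to the subclone best matching its marker posteriors.

    ``posteriors`` is the per-cell per-region table from the mixture fits
    (columns cell_id, chrom, start, end, p_low, p_high). For each clone
    group, the likelihood is the product over marker regions of the
    posterior of the group's expected component, with "neutral"
    expectations read as the high (non-deleted) component for regions whose
    aberrant state is a loss and as the low component for gains -- i.e. the
    component the diploid state falls in. The combined posterior normalizes
    over groups (uniform prior); cells whose best posterior falls below
    ``cutoff`` are UNASSIGNED.
    """
    groups = profile.groups
    # orient "neutral": for each region, which component corresponds to
    # diploid? If any clone expects low there (a deletion carrier), diploid
    # is the high component, and vice versa.
    neutral_side: dict[Region, str] = {}
    for r in profile.regions:
        states = {profile.expectations[g][r] for g in groups}
        neutral_side[r] = "p_high" if "low" in states else "p_low"

    pivot_low = posteriors.pivot_table(
        index="cell_id", columns=["chrom", "start", "end"], values="p_low"
    )
    rows = []
    for cell_id, row in pivot_low.iterrows():
        logls = {}
        for gname in groups:
            exp = profile.expectations[gname]
            logl = 0.0
            used = 0
            for r in profile.regions:
                key = r
                if key not in row.index or np.isnan(row[key]):
                    continue
                p_low = float(row[key])
                p_high = 1.0 - p_low
                want = exp[r]
                if want == "neutral":
                    p = p_high if neutral_side[r] == "p_high" else p_low
                elif want == "low":
                    p = p_low
                else:
                    p = p_high
                logl += np.log(max(p, 1e-300))
                used += 1
            logls[gname] = (logl, used)
        if not logls or all(u == 0 for _l, u in logls.values()):
            rows.append(
                {"cell_id": cell_id, "clone": "UNASSIGNED", "posterior": np.nan, "n_markers": 0}
            )
            continue
        names = list(logls)
        lvals = np.array([logls[g][0] for g in names])
        lvals -= lvals.max()
        post = np.exp(lvals)
        post /= post.sum()
        best = int(np.argmax(post))
        assigned = names[best] if post[best] >= cutoff else "UNASSIGNED"
        rows.append(
            {
                "cell_id": cell_id,
                "clone": assigned,
                "posterior": float(post[best]),
                "n_markers": logls[names[best]][1],
            }
        )
    return pd.DataFrame(rows)


def detect_pre_lsc(
    posteriors: pd.DataFrame,
    profile: MarkerProfile,
    cell_type_labels: pd.Series,
    hspc_label: str = "HSPC",
    cutoff: float = 0.8,
) -> set[str]:
    """Cells confidently lacking every marker SV and annotated as HSPCs.

    For each informative marker the cell's posterior of the non-aberrant
    (diploid-side) component must reach ``cutoff``; the cell must also carry
    the HSPC annotation (cell typing itself is supplied externally).
    """
    if cell_type_labels is None or len(cell_type_labels) == 0:
        import warnings

        warnings.warn("no cell-type labels supplied; empty pre-LSC set", stacklevel=2)
        return set()
    neutral_side: dict[Region, str] = {}
    for r in profile.regions:
        states = {profile.expectations[g][r] for g in profile.groups}
        neutral_side[r] = "p_high" if "low" in states else "p_low"
    pivot_low = posteriors.pivot_table(
        index="cell_id", columns=["chrom", "start", "end"], values="p_low"
    )
    out = set()
    for cell_id, row in pivot_low.iterrows():
        if cell_type_labels.get(cell_id, None) != hspc_label:
            continue
        ok = True
        seen = 0
        for r in profile.regions:
            if r not in row.index or np.isnan(row[r]):
                continue
            p_low = float(row[r])
            p_diploid = (1.0 - p_low) if neutral_side[r] == "p_high" else p_low
            seen += 1
            if p_diploid < cutoff:
                ok = False
                break
        if ok and seen > 0:
            out.add(cell_id)
    return out


def modality_concordance(
    fractions_strand: dict[str, float], fractions_expr: dict[str, float]
) -> tuple[float, float]:
    """Spearman correlation between subclone fractions seen by each modality.

    Expects the same clone keys in both dictionaries (pool clones across
    samples for a meaningful sample size).
    """
    keys = sorted(fractions_strand)
    if set(keys) != set(fractions_expr):
        raise ValueError("clone sets differ between modalities")
    if len(keys) < 3:
        raise ValueError("need >= 3 clones for a rank correlation")
    x = [fractions_strand[k] for k in keys]
    y = [fractions_expr[k] for k in keys]
    return spearman_concordance(x, y)
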