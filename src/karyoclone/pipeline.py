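"""End-to-end orchestration: from simulated readouts to cross-modal clones.

``cross_modal_analysis`` runs the full inferred route on one dataset: SV
calling and subclone definition on the strand side, marker-region recalling
and cell assignment on the expression side, and the concordance of subclone
fractions between the two modalities. Nothing from the simulation ground
truth enters the inference; truth labels are only used by callers to score
the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assignment import assign_cells, build_marker_profiles_from_calls, modality_concordance
from .clonal import SubcloneSet, build_hierarchy, burden_profile, define_subclones
from .scna import recall_regions
from .simulate import ExpressionCellMatrix, StrandCellMatrix
from .strand_calls import call_svs


@dataclass
class CrossModalResult:
    calls: pd.DataFrame
    subclones: SubcloneSet
    hierarchy: object
    burdens: pd.Series
    regions: list[tuple[str, int, int]]
    fits: list
    posteriors: pd.DataFrame
    assignments: pd.DataFrame
    profile: object
    fractions_strand: dict[str, float]
    fractions_expr: dict[str, float]
    spearman: tuple[float, float] | None


def marker_regions_from_calls(calls: pd.DataFrame, min_cells: int = 3) -> list:
    """Candidate SCNA regions: called segments carried by >= min_cells cells
    with a copy-number change (inversions are expression-silent)."""
    if calls.empty:
        return []
    cn_change = (calls.cn_h1 + calls.cn_h2) != 2
    sub = calls[cn_change]
    counts = sub.groupby(["chrom", "start", "end"]).cell_id.nunique()
    return sorted(counts.index[counts >= min_cells])


def subclone_fractions(labels: pd.Series) -> dict[str, float]:
    frac = labels.value_counts(normalize=True)
    return {k: float(v) for k, v in frac.items()}


def cross_modal_analysis(
    strand: StrandCellMatrix,
    expr: ExpressionCellMatrix,
    call_threshold: float = 0.8,
    assignment_cutoff: float = 0.8,
    seed: int = 0,
) -> CrossModalResult:
    """Run the full two-modality analysis on simulated (or real-schema) data."""
    _states, _segments, genotypes, calls = call_svs(
        strand, call_threshold=call_threshold
    )
    subclones = define_subclones(
        calls, list(strand.cells.cell_id), genotypes=genotypes
    )
    hierarchy = build_hierarchy(subclones)
    burdens = burden_profile(calls, list(strand.cells.cell_id))

    regions = marker_regions_from_calls(calls)
    fits, posteriors = recall_regions(expr, regions, seed=seed)
    passed = [f.region for f in fits if f.passed]

    assignments = pd.DataFrame(columns=["cell_id", "clone", "posterior", "n_markers"])
    profile = None
    fractions_strand: dict[str, float] = {}
    fractions_expr: dict[str, float] = {}
    spearman = None
    if passed and len(subclones.signatures) > 1:
        profile = build_marker_profiles_from_calls(
            subclones.signatures, calls, passed
        )
        assignments = assign_cells(posteriors, profile, cutoff=assignment_cutoff)
        merged_strand = subclones.labels.map(profile.merged_groups)
        fractions_strand = subclone_fractions(merged_strand)
        assigned = assignments[assignments.clone != "UNASSIGNED"]
        if not assigned.empty:
            fractions_expr = subclone_fractions(assigned.set_index("cell_id").clone)
        common = sorted(set(fractions_strand) | set(fractions_expr))
        if len(common) >= 3:
            fs = {k: fractions_strand.get(k, 0.0) for k in common}
            fe = {k: fractions_expr.get(k, 0.0) for k in common}
            try:
                spearman = modality_concordance(fs, fe)
            except ValueError:
                spearman = None
    return CrossModalResult(
        calls=calls,
        subclones=subclones,
        hierarchy=hierarchy,
        burdens=burdens,
        regions=regions,
        fits=fits,
        posteriors=posteriors,
        assignments=assignments,
        profile=profile,
        fractions_strand=fractions_strand,
        fractions_expr=fractions_expr,
        spearman=spearman,
    )
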