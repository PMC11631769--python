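"""Plain-text writers for simulator outputs and pipeline tables.

Strand counts go to long-format TSV, expression to MatrixMarket MTX with
gene/cell TSVs, ground truth (tree, karyotypes, labels) to JSON, and SV
regions to BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .simulate import ExpressionCellMatrix, StrandCellMatrix
from .trees import CloneTree


def write_strand_counts(matrix: StrandCellMatrix, path: str | Path) -> None:
    """Long-format TSV: cell_id, chrom, start, end, watson, crick."""
    rows = []
    bs = matrix.genome.bin_size
    for chrom in matrix.genome.chrom_names:
        W = matrix.watson[chrom]
        C = matrix.crick[chrom]
        for i, cid in enumerate(matrix.cells.cell_id):
            nz = (W[i] > 0) | (C[i] > 0)
            for b in nz.nonzero()[0]:
                rows.append((cid, chrom, b * bs, (b + 1) * bs, int(W[i, b]), int(C[i, b])))
    pd.DataFrame(
        rows, columns=["cell_id", "chrom", "start", "end", "watson", "crick"]
    ).to_csv(path, sep="\t", index=False)


def write_expression(matrix: ExpressionCellMatrix, outdir: str | Path) -> None:
    """MatrixMarket counts plus gene and cell annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "counts.mtx"), csr_matrix(matrix.counts))
    matrix.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    matrix.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def tree_to_dict(tree: CloneTree) -> dict:
    return {
        "growth_pattern": tree.growth_pattern,
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id,
                "cell_fraction": c.cell_fraction,
                "private_events": [
                    {
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "haplotype": e.haplotype,
                        "ev_type": e.ev_type,
                        "partner": e.partner,
                    }
                    for e in c.private_events
                ],
            }
            for c in tree.clones
        ],
    }


def write_ground_truth(
    tree: CloneTree,
    strand: StrandCellMatrix | None,
    expr: ExpressionCellMatrix | None,
    path: str | Path,
) -> None:
    """Tree, per-clone altered segments and cell labels as JSON."""
    doc = {"tree": tree_to_dict(tree), "clone_karyotypes": {}, "cell_labels": {}}
    for cid in tree.clone_ids:
        kt = tree.karyotype_of(cid)
        doc["clone_karyotypes"][cid] = [
            {"chrom": c, "start": s, "end": e, "h1": list(h1), "h2": list(h2)}
            for c, s, e, h1, h2 in kt.altered_segment_states()
        ]
    if strand is not None:
        doc["cell_labels"]["strand"] = dict(
            zip(strand.cells.cell_id, strand.cells.clone_id)
        )
    if expr is not None:
        doc["cell_labels"]["expression"] = dict(
            zip(expr.cells.cell_id, expr.cells.clone_id)
        )
    Path(path).write_text(json.dumps(doc, indent=1))


def write_regions_bed(regions: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append((chrom, int(start), int(end)))
    return out


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV of the compiled SV call table."""
    cols = [
        "chrom", "start", "end", "cell_id", "sv_label",
        "cn_h1", "cn_h2", "posterior", "singleton",
    ]
    calls[cols].to_csv(path, sep="\t", index=False)
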