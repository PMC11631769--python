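"""Ready-made simulation scenarios emulating complex-karyotype leukemias.

These assemble the generator primitives into study-like datasets: a branched
clone tree whose subclones are distinguished by large copy-number
alterations (the kind detectable in both strand-resolved and expression
readouts), and a BFB scenario with per-cell jittered terminal deletions.
"""

from __future__ import annotations

from .complex_events import generate_bfb, generate_chromothripsis
from .genome import GenomeModel, toy_genome
from .karyotype import RearrangementEvent
from .trees import Clone, CloneTree


def ck_branched_tree(genome: GenomeModel | None = None) -> tuple[GenomeModel, CloneTree]:
    """A branched 4-clone tree with multi-Mb subclone-defining CNAs.

    The trunk carries a whole-chromosome gain; the three subclones add,
    respectively, a large deletion, a large duplication, and a second
    deletion elsewhere -- each a dosage-visible marker. Fractions follow a
    dominant-clone profile (0.45/0.25/0.20/0.10).
    """
    if genome is None:
        genome = toy_genome(seed=0)
    bs = genome.bin_size
    c1, c2, c3, c4, _c5 = genome.chrom_names
    n2 = genome.n_bins(c2)
    trunk = [RearrangementEvent(c2, 0, n2 * bs, "H1", "WC_GAIN")]
    sc2 = [RearrangementEvent(c3, 100 * bs, 220 * bs, "H1", "DEL")]
    sc3 = [RearrangementEvent(c4, 50 * bs, 180 * bs, "H2", "DUP")]
    sc4 = [RearrangementEvent(c1, 300 * bs, 420 * bs, "H1", "DEL")]
    tree = CloneTree(
        clones=[
            Clone("SC1", None, trunk, 0.45),
            Clone("SC2", "SC1", sc2, 0.25),
            Clone("SC3", "SC1", sc3, 0.20),
            Clone("SC4", "SC2", sc4, 0.10),
        ],
        growth_pattern="branched",
        genome=genome,
    )
    return genome, tree


def chromothripsis_tree(
    genome: GenomeModel | None = None, n_breakpoints: int = 15, seed: int = 2
) -> tuple[GenomeModel, CloneTree]:
    """Monoclonal tree carrying a one-off chromothripsis on one homolog."""
    if genome is None:
        genome = toy_genome(seed=0)
    events = generate_chromothripsis(
        genome, genome.chrom_names[0], "H1", n_breakpoints, 3, seed=seed
    )
    tree = CloneTree(
        clones=[Clone("SC1", None, events, 1.0)], growth_pattern="monoclonal", genome=genome
    )
    return genome, tree


def bfb_scenario(
    genome: GenomeModel | None = None,
    n_cells: int = 100,
    jitter_mb: float = 3.0,
    seed: int = 5,
):
    """Monoclonal tree plus per-cell BFB signatures with jittered deletions.

    Returns (genome, tree, cell_events) where cell_events feeds
    ``simulate_strand_cells``: every cell gets an inverted duplication at a
    common fold point and a terminal deletion whose length varies cell to
    cell within ``jitter_mb`` megabases.
    """
    if genome is None:
        genome = toy_genome(seed=0)
    chrom = genome.chrom_names[1]
    length = genome.chrom_length(chrom)
    fold = genome.snap(length * 3 // 5)
    jitter = (genome.bin_size, int(jitter_mb * 1e6))
    per_cell = generate_bfb(genome, chrom, "H1", fold, jitter, seed=seed, n_cells=n_cells)
    tree = CloneTree(
        clones=[Clone("SC1", None, [], 1.0)], growth_pattern="monoclonal", genome=genome
    )
    return genome, tree, {"SC1": per_cell}
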