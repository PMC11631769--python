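"""Simulated single-cell readouts of a clone tree.

Two modalities are generated from the same ground-truth clone tree:

* strand-resolved binned read counts (Strand-seq-like): each cell inherits,
  per chromosome, a template-strand configuration (WW/WC/CC at Mendelian
  1:2:1); reads from a homolog fall on the strand of its template, and
  inverted copies emit on the opposite strand. Counts per 100-kb bin are
  negative binomial.
* gene-level expression counts: negative binomial with mean proportional to
  baseline x (copy number / 2)^dosage_exponent x library size, so copy-number
  dosage is visible in the transcriptome.

All randomness flows through ``SimConfig.seed``; identical configurations
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .karyotype import HAPLOTYPES, HaplotypeKaryotype
from .trees import CloneTree

TEMPLATE_CONFIGS = ("WW", "WC", "CC")
_TEMPLATE_PROBS = (0.25, 0.5, 0.25)


@dataclass
class SimConfig:
    """Study conditions for the simulated readouts.

    depth_per_copy: expected reads per bin per chromosome copy (5 emulates a
    deeply-covered desk-scale regime; the real assay is far shallower).
    nb_dispersion: negative-binomial dispersion phi, variance m + m^2/phi;
    Poisson is recovered as phi -> infinity.
    dosage_exponent: exponent of the (CN/2) dosage effect on expression.
    background_leakage: fraction of baseline expression retained by genes
    homozygously deleted (so mixture fits never see exact zeros only).
    """

    seed: int = 0
    n_strand_cells: int = 200
    n_expr_cells: int = 1000
    depth_per_copy: float = 5.0
    nb_dispersion: float = 10.0
    dosage_exponent: float = 1.0
    background_leakage: float = 0.01
    library_log_sd: float = 0.25
    clone_fractions: list[float] | None = None

    def __post_init__(self) -> None:
        if self.depth_per_copy <= 0:
            raise ValueError("depth_per_copy must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.clone_fractions is not None:
            if abs(sum(self.clone_fractions) - 1.0) > 1e-9 or min(self.clone_fractions) < 0:
                raise ValueError("clone_fractions must be a valid distribution")


def nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean m and variance m + m^2/dispersion."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


@dataclass
class StrandCellMatrix:
    """Per cell x bin Watson/Crick read counts with ground-truth labels.

    ``watson[chrom]`` and ``crick[chrom]`` are (n_cells, n_bins) integer
    arrays. ``templates[chrom]`` is an (n_cells, 2) array of "W"/"C" giving
    the template strand of H1 and H2 in each cell.
    """

    genome: GenomeModel
    cells: pd.DataFrame  # cell_id, clone_id
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]
    templates: dict[str, np.ndarray]
    depth_per_copy: float
    nb_dispersion: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def config(self, cell_index: int, chrom: str) -> str:
        """Template-strand configuration (WW/WC/CC) of one cell's chromosome."""
        t = list(self.templates[chrom][cell_index])
        if t == ["W", "W"]:
            return "WW"
        if t == ["C", "C"]:
            return "CC"
        return "WC"


def _clone_assignments(tree: CloneTree, n_cells: int, rng: np.random.Generator,
                       fractions: list[float] | None) -> np.ndarray:
    ids = tree.clone_ids
    if fractions is None:
        fractions = [tree.clone(c).cell_fraction for c in ids]
    return rng.choice(np.array(ids), size=n_cells, p=np.array(fractions))


def expected_strand_means(
    karyotype: HaplotypeKaryotype, chrom: str, templates: tuple[str, str], depth_per_copy: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin expected Watson/Crick reads for one cell and chromosome.

    Forward copies of a homolog emit on its template strand; inverted copies
    emit on the opposite strand.
    """
    n = karyotype.genome.n_bins(chrom)
    mu_w = np.zeros(n)
    mu_c = np.zeros(n)
    for hap, tpl in zip(HAPLOTYPES, templates):
        fwd = karyotype.forward(chrom, hap)
        inv = karyotype.inverted(chrom, hap)
        if tpl == "W":
            mu_w += depth_per_copy * fwd
            mu_c += depth_per_copy * inv
        else:
            mu_c += depth_per_copy * fwd
            mu_w += depth_per_copy * inv
    return mu_w, mu_c


def simulate_strand_cells(
    tree: CloneTree,
    genome: GenomeModel,
    config: SimConfig,
    cell_events: dict[str, list] | None = None,
) -> StrandCellMatrix:
    """Draw strand-resolved binned counts for ``config.n_strand_cells`` cells.

    ``cell_events`` optionally maps a clone_id to a list of per-cell event
    lists (e.g. jittered BFB signatures): each cell of that clone receives
    one entry, cycled in order, on top of the clone karyotype.
    """
    if config.n_strand_cells < 1:
        raise ValueError("need at least one cell")
    if not tree.clones:
        raise ValueError("empty clone tree")
    rng = np.random.default_rng(config.seed)
    clone_ids = _clone_assignments(tree, config.n_strand_cells, rng, config.clone_fractions)
    karyotypes = {cid: tree.karyotype_of(cid) for cid in tree.clone_ids}

    per_cell_kt: list[HaplotypeKaryotype] = []
    extra_counter: dict[str, int] = {}
    for cid in clone_ids:
        kt = karyotypes[cid]
        if cell_events and cid in cell_events:
            idx = extra_counter.get(cid, 0)
            extra_counter[cid] = idx + 1
            events = cell_events[cid][idx % len(cell_events[cid])]
            kt = kt.copy()
            for ev in events:
                kt.apply(ev)
        per_cell_kt.append(kt)

    n_cells = config.n_strand_cells
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        W = np.zeros((n_cells, n), dtype=np.int64)
        C = np.zeros((n_cells, n), dtype=np.int64)
        tpl = np.empty((n_cells, 2), dtype="U1")
        for i in range(n_cells):
            cfg = rng.choice(np.array(TEMPLATE_CONFIGS), p=np.array(_TEMPLATE_PROBS))
            if cfg == "WW":
                t = ("W", "W")
            elif cfg == "CC":
                t = ("C", "C")
            else:
                t = ("W", "C") if rng.random() < 0.5 else ("C", "W")
            tpl[i] = t
            mu_w, mu_c = expected_strand_means(per_cell_kt[i], chrom, t, config.depth_per_copy)
            W[i] = nb_draw(rng, mu_w, config.nb_dispersion)
            C[i] = nb_draw(rng, mu_c, config.nb_dispersion)
        watson[chrom] = W
        crick[chrom] = C
        templates[chrom] = tpl

    cells = pd.DataFrame(
        {"cell_id": [f"strand_cell_{i:04d}" for i in range(n_cells)], "clone_id": clone_ids}
    )
    return StrandCellMatrix(
        genome=genome,
        cells=cells,
        watson=watson,
        crick=crick,
        templates=templates,
        depth_per_copy=config.depth_per_copy,
        nb_dispersion=config.nb_dispersion,
    )


@dataclass
class ExpressionCellMatrix:
    """Gene x cell expression counts with ground-truth clone labels."""

    genome: GenomeModel
    genes: pd.DataFrame  # gene_id, chrom, start, end, baseline_mean
    cells: pd.DataFrame  # cell_id, clone_id, library_factor
    counts: np.ndarray  # (n_genes, n_cells) int

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


def gene_copy_number(karyotype: HaplotypeKaryotype, gene_chrom: str, gene_mid: int) -> int:
    """Total copy number of the bin containing a gene's midpoint."""
    b = karyotype.genome.bin_of(gene_chrom, gene_mid)
    return int(karyotype.total_cn(gene_chrom)[b])


def simulate_expression_cells(
    tree: CloneTree, genome: GenomeModel, config: SimConfig
) -> ExpressionCellMatrix:
    """Draw gene-level counts with copy-number dosage effects."""
    if not genome.genes:
        raise ValueError("genome has no genes")
    rng = np.random.default_rng(config.seed + 1)
    clone_ids = _clone_assignments(tree, config.n_expr_cells, rng, config.clone_fractions)
    karyotypes = {cid: tree.karyotype_of(cid) for cid in tree.clone_ids}

    lib = rng.lognormal(0.0, config.library_log_sd, size=config.n_expr_cells)
    genes = genome.genes
    # per-clone dosage factor per gene
    dosage: dict[str, np.ndarray] = {}
    for cid, kt in karyotypes.items():
        cn = np.array([gene_copy_number(kt, g.chrom, g.midpoint) for g in genes], dtype=float)
        factor = np.where(
            cn > 0, (cn / 2.0) ** config.dosage_exponent, config.background_leakage
        )
        dosage[cid] = factor
    baseline = np.array([g.baseline_mean for g in genes])

    counts = np.zeros((len(genes), config.n_expr_cells), dtype=np.int64)
    for j, cid in enumerate(clone_ids):
        mean = baseline * dosage[cid] * lib[j]
        counts[:, j] = nb_draw(rng, mean, config.nb_dispersion)

    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "baseline_mean": baseline,
        }
    )
    cells_df = pd.DataFrame(
        {
            "cell_id": [f"expr_cell_{j:05d}" for j in range(config.n_expr_cells)],
            "clone_id": clone_ids,
            "library_factor": lib,
        }
    )
    return ExpressionCellMatrix(genome=genome, genes=genes_df, cells=cells_df, counts=counts)
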