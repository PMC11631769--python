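"""Genome model: binned chromosomes and a gene annotation with expression baselines.

All coordinates are 0-based, half-open, and event boundaries are snapped to
fixed-size genomic bins (default 100 kb), the resolution at which
strand-resolved single-cell read counts are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_SIZE = 100_000


@dataclass(frozen=True)
class Gene:
    """A gene with genomic coordinates and a baseline mean expression.

    ``baseline_mean`` is the expected transcript count per cell for a diploid
    locus at unit library size.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    baseline_mean: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval")
        if self.baseline_mean < 0:
            raise ValueError(f"gene {self.gene_id}: negative baseline")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeModel:
    """Ordered chromosomes tiled by fixed-size bins, plus a gene list.

    Chromosome lengths are truncated to whole multiples of ``bin_size`` so that
    bins tile each chromosome exactly.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int = DEFAULT_BIN_SIZE
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        trunc = []
        for name, length in self.chromosomes:
            length = (int(length) // self.bin_size) * self.bin_size
            if length <= 0:
                raise ValueError(f"chromosome {name} shorter than one bin")
            trunc.append((name, length))
        self.chromosomes = trunc
        lengths = dict(trunc)
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return self.chrom_length(chrom) // self.bin_size

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing position ``pos`` (0-based)."""
        if not 0 <= pos < self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def snap(self, pos: int) -> int:
        """Round a position down to the nearest bin boundary."""
        return (pos // self.bin_size) * self.bin_size

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]


def toy_genome(
    n_chromosomes: int = 5,
    genes_per_chromosome: int = 150,
    bin_size: int = DEFAULT_BIN_SIZE,
    baseline_log_mean: float = 1.6,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> GenomeModel:
    """A small desk-scale genome: chromosomes of 30-80 Mb with random genes.

    Gene expression baselines are log-normal, mimicking the broad dynamic
    range of transcript abundances. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chromosomes):
        length = int(rng.integers(300, 801)) * bin_size
        chroms.append((f"chr{i + 1}", length))
    genes: list[Gene] = []
    for name, length in chroms:
        starts = np.sort(rng.choice(length - 10_000, size=genes_per_chromosome, replace=False))
        for j, s in enumerate(starts):
            span = int(rng.integers(2_000, 50_000))
            end = min(int(s) + span, length)
            base = float(rng.lognormal(baseline_log_mean, baseline_log_sd))
            genes.append(Gene(f"{name}_g{j + 1}", name, int(s), end, base))
    return GenomeModel(chromosomes=chroms, bin_size=bin_size, genes=genes)
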