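"""Generators for complex rearrangement signatures.

Three classes of complex events are modeled, each confined to a single
homolog:

* chromothripsis -- one-off shattering: copy number oscillates between 2 or 3
  states in islands along the chromosome, with interspersed copy-neutral
  inversions;
* breakage-fusion-bridge (BFB) -- an inverted duplication adjacent to a
  terminal deletion on the same homolog, with the deletion length varying
  from cell to cell;
* seismic amplification -- multi-round amplification producing >= 4 distinct
  amplified copy-number levels interleaved with non-amplified (disomic or
  deleted) segments, emulating successive circular recombination.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeModel
from .karyotype import RearrangementEvent


def generate_chromothripsis(
    genome: GenomeModel,
    chrom: str,
    haplotype: str,
    n_breakpoints: int,
    n_states: int,
    seed: int,
    inversion_prob: float = 0.3,
) -> list[RearrangementEvent]:
    """Events whose replay yields an oscillating copy-number profile.

    The targeted homolog ends up with exactly ``n_states`` distinct copy
    numbers (from {0, 1, 2}) alternating between adjacent segments; copy-1
    segments may additionally be inverted. The other homolog is untouched.
    """
    if n_breakpoints < 4:
        raise ValueError("chromothripsis requires >= 4 breakpoints")
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    n = genome.n_bins(chrom)
    if n_breakpoints >= n:
        raise ValueError("more breakpoints than bin boundaries available")
    rng = np.random.default_rng(seed)
    bs = genome.bin_size

    states = [0, 1, 2] if n_states == 3 else ([1, 0] if rng.random() < 0.5 else [1, 2])
    for _ in range(1000):
        bounds = np.sort(rng.choice(np.arange(1, n), size=n_breakpoints, replace=False))
        edges = np.concatenate([[0], bounds, [n]])
        # random walk over states with adjacent segments forced to differ
        seq = [int(rng.choice(states))]
        for _seg in range(len(edges) - 2):
            choices = [s for s in states if s != seq[-1]]
            seq.append(int(rng.choice(choices)))
        if len(set(seq)) == n_states:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("failed to draw an oscillating state sequence")

    events: list[RearrangementEvent] = []
    for (b0, b1), cn in zip(zip(edges[:-1], edges[1:]), seq):
        start, end = int(b0) * bs, int(b1) * bs
        if cn == 0:
            events.append(RearrangementEvent(chrom, start, end, haplotype, "DEL"))
        elif cn == 2:
            ev = "INVDUP" if rng.random() < 0.5 else "DUP"
            events.append(RearrangementEvent(chrom, start, end, haplotype, ev))
        elif rng.random() < inversion_prob:
            events.append(RearrangementEvent(chrom, start, end, haplotype, "INV"))
    return events


def generate_bfb(
    genome: GenomeModel,
    chrom: str,
    haplotype: str,
    fold_point: int,
    deletion_jitter: tuple[int, int],
    seed: int,
    n_cells: int,
) -> list[list[RearrangementEvent]]:
    """Per-cell BFB signatures: inverted duplication + adjacent terminal loss.

    For each cell the deletion starts ``offset`` bp after ``fold_point``,
    with ``offset`` drawn uniformly (in whole bins) from ``deletion_jitter``
    = (lo, hi); the inverted duplication covers [fold_point, deletion start).
    With zero jitter (lo == hi) all cells are identical.
    """
    bs = genome.bin_size
    length = genome.chrom_length(chrom)
    fold_point = genome.snap(fold_point)
    if not (0 < fold_point < length):
        raise ValueError("fold_point must be interior to the chromosome")
    lo, hi = deletion_jitter
    if lo < 0 or hi < lo:
        raise ValueError("deletion_jitter must be (lo, hi) with 0 <= lo <= hi")
    lo_b, hi_b = max(1, lo // bs), max(1, hi // bs)
    if fold_point + hi_b * bs >= length:
        raise ValueError("jitter range exceeds the chromosome arm")
    rng = np.random.default_rng(seed)
    out: list[list[RearrangementEvent]] = []
    for _ in range(n_cells):
        off = int(rng.integers(lo_b, hi_b + 1)) * bs
        del_start = fold_point + off
        out.append(
            [
                RearrangementEvent(chrom, fold_point, del_start, haplotype, "INVDUP"),
                RearrangementEvent(chrom, del_start, length, haplotype, "DEL"),
            ]
        )
    return out


def generate_seismic(
    genome: GenomeModel,
    chrom: str,
    n_rounds: int,
    seed: int,
    haplotype: str = "H1",
) -> list[RearrangementEvent]:
    """Wave-like multi-level amplification on one homolog.

    A target profile over the homolog is drawn containing every copy level
    0..n_rounds+1, with amplified segments interleaved with disomic or
    deleted ones. Events are emitted in rounds: round r duplicates exactly
    the segments whose target level exceeds r, so each round amplifies a
    subset of the segments amplified in the previous round (emulating
    successive circular recombination); deletions are emitted last.
    """
    if n_rounds < 2:
        raise ValueError("n_rounds >= 2 required")
    n = genome.n_bins(chrom)
    n_segments = 3 * n_rounds + 2
    if n_segments >= n:
        raise ValueError("chromosome too small for requested rounds")
    rng = np.random.default_rng(seed)
    bs = genome.bin_size

    levels = list(range(n_rounds + 2))  # homolog copy levels 0 .. n_rounds+1
    for _ in range(1000):
        bounds = np.sort(rng.choice(np.arange(1, n), size=n_segments - 1, replace=False))
        edges = np.concatenate([[0], bounds, [n]])
        seq = [int(rng.choice(levels))]
        for _seg in range(len(edges) - 2):
            nxt = int(rng.choice([s for s in levels if s != seq[-1]]))
            seq.append(nxt)
        amplified = [s for s in seq if s >= 2]
        interleaved = any(
            seq[i] >= 2 and seq[i + 1] <= 1 for i in range(len(seq) - 1)
        )
        if set(seq) == set(levels) and len(set(amplified)) >= min(4, n_rounds) and interleaved:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw a seismic profile")

    events: list[RearrangementEvent] = []
    for r in range(1, n_rounds + 1):
        for (b0, b1), lvl in zip(zip(edges[:-1], edges[1:]), seq):
            if lvl > r:
                events.append(
                    RearrangementEvent(chrom, int(b0) * bs, int(b1) * bs, haplotype, "DUP")
                )
    for (b0, b1), lvl in zip(zip(edges[:-1], edges[1:]), seq):
        if lvl == 0:
            events.append(
                RearrangementEvent(chrom, int(b0) * bs, int(b1) * bs, haplotype, "DEL")
            )
    return events
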