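"""Haplotype-resolved karyotypes and rearrangement events.

A karyotype tracks, for every (chromosome, homolog) and every genomic bin, how
many copies of that bin are present in the original orientation and how many
in inverted orientation. This generalizes a per-segment (copy number,
inverted) description: an inverted duplication leaves one forward and one
inverted copy in the same interval, which a single flag cannot express.
Segment views are recovered by run-length encoding the per-bin states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel

HAPLOTYPES = ("H1", "H2")

EVENT_TYPES = {
    "DEL": -1,
    "DUP": +1,
    "INV": 0,
    "INVDUP": +1,
    "WC_GAIN": +1,
    "WC_LOSS": -1,
    "TRA_FOOTPRINT": 0,
}


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement on one homolog, with bin-aligned 0-based half-open span.

    ``copy_delta`` is fixed by the event type: deletions remove one copy,
    (inverted) duplications add one, inversions and translocation footprints
    are copy-neutral. ``partner`` labels the partner chromosome of a
    translocation footprint and is unused otherwise.
    """

    chrom: str
    start: int
    end: int
    haplotype: str
    ev_type: str
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.ev_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.ev_type!r}")
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"haplotype must be one of {HAPLOTYPES}")
        if not (0 <= self.start < self.end):
            raise ValueError("event requires 0 <= start < end")
        if self.ev_type == "TRA_FOOTPRINT" and self.partner is None:
            raise ValueError("TRA_FOOTPRINT requires a partner chromosome label")

    @property
    def copy_delta(self) -> int:
        return EVENT_TYPES[self.ev_type]

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.haplotype, self.ev_type)


class EventApplicationError(ValueError):
    """Raised when an event cannot be applied to a karyotype."""


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with constant per-homolog copy state."""

    chrom: str
    start: int
    end: int
    n_forward: int
    n_inverted: int

    @property
    def copy_number(self) -> int:
        return self.n_forward + self.n_inverted

    @property
    def inverted(self) -> bool:
        return self.n_inverted > 0


class HaplotypeKaryotype:
    """Per (chromosome, homolog) copy state of every genomic bin.

    Internally two integer arrays per homolog: forward-oriented and
    inverted-oriented copy counts per bin. The reference diploid state is one
    forward copy on each homolog everywhere.
    """

    def __init__(self, genome: GenomeModel):
        self.genome = genome
        self._fwd: dict[tuple[str, str], np.ndarray] = {}
        self._inv: dict[tuple[str, str], np.ndarray] = {}
        self.tra_labels: list[RearrangementEvent] = []
        for chrom in genome.chrom_names:
            n = genome.n_bins(chrom)
            for hap in HAPLOTYPES:
                self._fwd[(chrom, hap)] = np.ones(n, dtype=np.int64)
                self._inv[(chrom, hap)] = np.zeros(n, dtype=np.int64)

    @classmethod
    def diploid(cls, genome: GenomeModel) -> "HaplotypeKaryotype":
        return cls(genome)

    def copy(self) -> "HaplotypeKaryotype":
        new = HaplotypeKaryotype.__new__(HaplotypeKaryotype)
        new.genome = self.genome
        new._fwd = {k: v.copy() for k, v in self._fwd.items()}
        new._inv = {k: v.copy() for k, v in self._inv.items()}
        new.tra_labels = list(self.tra_labels)
        return new

    # -- accessors ---------------------------------------------------------

    def forward(self, chrom: str, hap: str) -> np.ndarray:
        return self._fwd[(chrom, hap)]

    def inverted(self, chrom: str, hap: str) -> np.ndarray:
        return self._inv[(chrom, hap)]

    def cn(self, chrom: str, hap: str) -> np.ndarray:
        """Per-bin copy number of one homolog."""
        return self._fwd[(chrom, hap)] + self._inv[(chrom, hap)]

    def total_cn(self, chrom: str) -> np.ndarray:
        """Per-bin copy number summed over both homologs."""
        return self.cn(chrom, "H1") + self.cn(chrom, "H2")

    def segments(self, chrom: str, hap: str) -> list[Segment]:
        """Run-length encoded per-homolog segments tiling the chromosome."""
        fwd = self._fwd[(chrom, hap)]
        inv = self._inv[(chrom, hap)]
        bs = self.genome.bin_size
        out: list[Segment] = []
        i = 0
        n = len(fwd)
        while i < n:
            j = i
            while j < n and fwd[j] == fwd[i] and inv[j] == inv[i]:
                j += 1
            out.append(Segment(chrom, i * bs, j * bs, int(fwd[i]), int(inv[i])))
            i = j
        return out

    def altered_segment_states(
        self,
    ) -> list[tuple[str, int, int, tuple[int, int], tuple[int, int]]]:
        """Maximal intervals where either homolog deviates from the reference,
        with the (forward, inverted) state of each homolog.

        Adjacent bins with identical state on both homologs are merged; this
        is the ground-truth unit for per-cell SV burden (one unit per altered
        segment, not per event).
        """
        out = []
        bs = self.genome.bin_size
        for chrom in self.genome.chrom_names:
            f1, i1 = self._fwd[(chrom, "H1")], self._inv[(chrom, "H1")]
            f2, i2 = self._fwd[(chrom, "H2")], self._inv[(chrom, "H2")]
            altered = (f1 != 1) | (i1 != 0) | (f2 != 1) | (i2 != 0)
            state = np.stack([f1, i1, f2, i2])
            i = 0
            n = len(f1)
            while i < n:
                if not altered[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and altered[j + 1] and np.array_equal(state[:, j + 1], state[:, i]):
                    j += 1
                out.append(
                    (
                        chrom,
                        i * bs,
                        (j + 1) * bs,
                        (int(f1[i]), int(i1[i])),
                        (int(f2[i]), int(i2[i])),
                    )
                )
                i = j + 1
        return out

    def altered_segments(self) -> list[tuple[str, int, int]]:
        """Intervals from ``altered_segment_states`` without the states."""
        return [(c, s, e) for c, s, e, _h1, _h2 in self.altered_segment_states()]

    # -- event application -------------------------------------------------

    def _bin_span(self, event: RearrangementEvent) -> tuple[int, int]:
        bs = self.genome.bin_size
        if event.start % bs or event.end % bs:
            raise EventApplicationError(f"event not bin-aligned: {event}")
        if event.end > self.genome.chrom_length(event.chrom):
            raise EventApplicationError(f"event past chromosome end: {event}")
        return event.start // bs, event.end // bs

    def apply(self, event: RearrangementEvent) -> None:
        """Apply one event in place. Raises EventApplicationError if invalid."""
        chrom, hap = event.chrom, event.haplotype
        b0, b1 = self._bin_span(event)
        fwd = self._fwd[(chrom, hap)]
        inv = self._inv[(chrom, hap)]
        ev = event.ev_type
        if ev == "DEL":
            if (fwd[b0:b1] + inv[b0:b1]).min() < 1:
                raise EventApplicationError(f"DEL on copy-number-0 interval: {event}")
            # remove one copy per bin, preferring a forward copy
            take_fwd = fwd[b0:b1] > 0
            fwd[b0:b1] -= take_fwd
            inv[b0:b1] -= ~take_fwd
        elif ev == "DUP":
            fwd[b0:b1] += 1
        elif ev == "INVDUP":
            if (fwd[b0:b1] + inv[b0:b1]).min() < 1:
                raise EventApplicationError(f"INVDUP of copy-number-0 interval: {event}")
            inv[b0:b1] += 1
        elif ev == "INV":
            if (fwd[b0:b1] + inv[b0:b1]).max() < 1:
                raise EventApplicationError(f"INV of copy-number-0 interval: {event}")
            fwd[b0:b1], inv[b0:b1] = inv[b0:b1].copy(), fwd[b0:b1].copy()
        elif ev in ("WC_GAIN", "WC_LOSS"):
            n = self.genome.n_bins(chrom)
            fwd = self._fwd[(chrom, hap)]
            inv = self._inv[(chrom, hap)]
            if ev == "WC_GAIN":
                fwd += 1
            else:
                cn = fwd + inv
                if cn.max() < 1:
                    raise EventApplicationError(f"WC_LOSS of absent homolog: {event}")
                take_fwd = fwd > 0
                present = cn > 0
                fwd -= take_fwd & present
                inv -= (~take_fwd) & present
        elif ev == "TRA_FOOTPRINT":
            n = self.genome.n_bins(chrom)
            if b0 != 0 and b1 != n:
                raise EventApplicationError("TRA_FOOTPRINT must cover a terminal segment")
            self.tra_labels.append(event)
        else:  # pragma: no cover
            raise AssertionError(ev)

    def can_apply(self, event: RearrangementEvent) -> bool:
        try:
            probe = self.copy()
            probe.apply(event)
            return True
        except EventApplicationError:
            return False


def apply_event(karyotype: HaplotypeKaryotype, event: RearrangementEvent) -> HaplotypeKaryotype:
    """Functional wrapper: return a new karyotype with ``event`` applied."""
    new = karyotype.copy()
    new.apply(event)
    return new


def apply_events(
    karyotype: HaplotypeKaryotype, events: list[RearrangementEvent]
) -> HaplotypeKaryotype:
    new = karyotype.copy()
    for ev in events:
        new.apply(ev)
    return new
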