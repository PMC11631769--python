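"""Clone trees: subclonal growth patterns with private rearrangement events.

Three growth patterns are modeled, mirroring the modes seen in complex
karyotypes: monoclonal (one dominant clone), linear (step-wise acquisition
along a single chain) and branched (>=2 sibling branches with mutually
exclusive private events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .karyotype import HAPLOTYPES, HaplotypeKaryotype, RearrangementEvent

GROWTH_PATTERNS = ("monoclonal", "linear", "branched")

# event types drawn for random private events, with sampling weights
_RANDOM_EVENTS = ["DEL", "DUP", "INV", "INVDUP", "WC_GAIN", "WC_LOSS"]
_RANDOM_WEIGHTS = np.array([0.28, 0.28, 0.18, 0.16, 0.05, 0.05])


class TreeConstructionError(RuntimeError):
    pass


@dataclass
class Clone:
    clone_id: str
    parent_id: str | None
    private_events: list[RearrangementEvent]
    cell_fraction: float


@dataclass
class CloneTree:
    """Rooted tree of clones; each node carries its private events only."""

    clones: list[Clone]
    growth_pattern: str
    genome: GenomeModel = field(repr=False)

    def __post_init__(self) -> None:
        total = sum(c.cell_fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell fractions sum to {total}, not 1")

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def root_path(self, clone_id: str) -> list[Clone]:
        path = []
        cur: str | None = clone_id
        while cur is not None:
            node = self.clone(cur)
            path.append(node)
            cur = node.parent_id
        return path[::-1]

    def events_for(self, clone_id: str) -> list[RearrangementEvent]:
        """Full event set of a clone: union of private events on its root path."""
        out: list[RearrangementEvent] = []
        for node in self.root_path(clone_id):
            out.extend(node.private_events)
        return out

    def karyotype_of(self, clone_id: str) -> HaplotypeKaryotype:
        kt = HaplotypeKaryotype.diploid(self.genome)
        for ev in self.events_for(clone_id):
            kt.apply(ev)
        return kt

    def leaves(self) -> list[Clone]:
        parents = {c.parent_id for c in self.clones}
        return [c for c in self.clones if c.clone_id not in parents]


def _random_event(
    genome: GenomeModel,
    karyotype: HaplotypeKaryotype,
    rng: np.random.Generator,
    max_tries: int = 50,
    min_bins: int = 10,
    max_bins: int = 40,
) -> RearrangementEvent:
    """Draw one random event applicable to ``karyotype``."""
    bs = genome.bin_size
    for _ in range(max_tries):
        ev_type = str(rng.choice(_RANDOM_EVENTS, p=_RANDOM_WEIGHTS))
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        hap = HAPLOTYPES[int(rng.integers(2))]
        n = genome.n_bins(chrom)
        if ev_type in ("WC_GAIN", "WC_LOSS"):
            event = RearrangementEvent(chrom, 0, n * bs, hap, ev_type)
        else:
            width = int(rng.integers(min_bins, max_bins + 1))
            if width >= n:
                continue
            b0 = int(rng.integers(0, n - width))
            event = RearrangementEvent(chrom, b0 * bs, (b0 + width) * bs, hap, ev_type)
        if karyotype.can_apply(event):
            return event
    raise TreeConstructionError("no applicable random event found")


def build_clone_tree(
    pattern: str,
    n_clones: int,
    events_per_clone: int,
    genome: GenomeModel,
    seed: int,
    fractions: list[float] | None = None,
    min_event_bins: int = 10,
    max_event_bins: int = 40,
) -> CloneTree:
    """Build a clone tree with random private events under a growth pattern.

    monoclonal: a single clone carrying ``events_per_clone`` trunk events.
    linear: a chain SC1 -> SC2 -> ... with step-wise private events.
    branched: SC1 is the root; later clones attach so that at least two
    sibling branches exist; sibling private events are mutually exclusive by
    construction (each event is drawn fresh and distinct intervals are
    enforced across branches).

    Cell fractions default to a deterministic decreasing profile; pass
    ``fractions`` to override.
    """
    if pattern not in GROWTH_PATTERNS:
        raise ValueError(f"pattern must be one of {GROWTH_PATTERNS}")
    if n_clones < 1:
        raise ValueError("n_clones >= 1 required")
    if pattern == "monoclonal" and n_clones != 1:
        raise ValueError("monoclonal growth implies a single clone")
    if pattern == "branched" and n_clones < 3:
        raise ValueError("branched growth requires >= 3 clones")
    rng = np.random.default_rng(seed)

    parents: list[str | None] = [None]
    if pattern == "linear":
        parents += [f"SC{i}" for i in range(1, n_clones)]
    elif pattern == "branched":
        # first two children attach to the root, guaranteeing >= 2 branches
        for i in range(2, n_clones + 1):
            if i <= 3:
                parents.append("SC1")
            else:
                parents.append(f"SC{int(rng.integers(1, i))}")

    clones: list[Clone] = []
    karyotypes: dict[str, HaplotypeKaryotype] = {}
    seen_keys: set[tuple] = set()
    for i in range(n_clones):
        cid = f"SC{i + 1}"
        parent = parents[i] if i < len(parents) else None
        base = (
            HaplotypeKaryotype.diploid(genome)
            if parent is None
            else karyotypes[parent].copy()
        )
        private: list[RearrangementEvent] = []
        for _ in range(events_per_clone):
            for _attempt in range(50):
                ev = _random_event(genome, base, rng, min_bins=min_event_bins, max_bins=max_event_bins)
                if ev.key() not in seen_keys:
                    break
            else:
                raise TreeConstructionError(f"could not place distinct event for {cid}")
            seen_keys.add(ev.key())
            base.apply(ev)
            private.append(ev)
        karyotypes[cid] = base
        clones.append(Clone(cid, parent, private, 0.0))

    if fractions is None:
        weights = np.array([2.0 ** (-0.5 * i) for i in range(n_clones)])
        fractions = list(weights / weights.sum())
    if len(fractions) != n_clones:
        raise ValueError("fractions length must equal n_clones")
    for c, f in zip(clones, fractions):
        c.cell_fraction = float(f)
    return CloneTree(clones=clones, growth_pattern=pattern, genome=genome)
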