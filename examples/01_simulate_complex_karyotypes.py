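"""Build a clone tree with complex rearrangements and inspect the karyotypes.

Generates a small genome, injects a chromothripsis and a seismic
amplification, and prints per-homolog copy-number summaries. The printed
"levels" are the distinct copy numbers along the chromosome: chromothripsis
oscillates between 2-3 states on one homolog, while seismic amplification
stacks many amplified levels interleaved with unamplified segments.
"""

import numpy as np

import karyoclone as kc
from karyoclone.karyotype import HaplotypeKaryotype, apply_events

genome = kc.toy_genome(seed=0)

ct = kc.generate_chromothripsis(genome, "chr1", "H1", n_breakpoints=15, n_states=3, seed=2)
kt = apply_events(HaplotypeKaryotype.diploid(genome), ct)
cn = kt.cn("chr1", "H1")
print(f"chromothripsis on chr1/H1: {len(ct)} events, "
      f"H1 levels {sorted(set(cn.tolist()))}, "
      f"breakpoints {int((np.diff(cn) != 0).sum())}, "
      f"H2 untouched: {bool(np.all(kt.cn('chr1', 'H2') == 1))}")

seismic = kc.generate_seismic(genome, "chr2", n_rounds=4, seed=1)
kt2 = apply_events(HaplotypeKaryotype.diploid(genome), seismic)
total = kt2.total_cn("chr2")
print(f"seismic amplification on chr2: total-CN levels {sorted(set(total.tolist()))} "
      f"(amplified levels = CN > 2, interleaved with disomic/deleted segments)")

bfb = kc.generate_bfb(genome, "chr3", "H1", fold_point=30_000_000,
                      deletion_jitter=(100_000, 3_000_000), seed=5, n_cells=8)
endpoints = sorted({cell[1].start for cell in bfb})
print(f"BFB across 8 cells: inverted duplication at a fixed fold point, "
      f"{len(endpoints)} distinct terminal-deletion start points "
      f"(cell-to-cell jitter of the breakage)")
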