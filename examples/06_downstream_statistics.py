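"""Downstream statistics: enrichment tests, coverage and signature scores.

Worked numbers on printed inputs: a Fisher exact test on a 2x2 cell-type
table, hypergeometric gene-set over-representation, subclone percentage
arithmetic, and the per-cell sequencing coverage implied by mapped read
pairs. Each line states the quantity and what it means.
"""

import numpy as np
import pandas as pd

import karyoclone as kc

# enrichment of an HSC-like cell state between two time points
odds, p = kc.fisher_2x2(15, 48, 23, 31)
print(f"Fisher exact test on 15/48 vs 23/31 cells: odds ratio {odds:.2f}, "
      f"p = {p:.3f} (two-sided)")

# subclone sizes as printed percentages
for k, n, d in [(81, 91, 0), (3, 76, 2), (5, 91, 1)]:
    print(f"{k}/{n} cells -> {kc.cell_fraction(k, n, d)}% of the sample")

# sequencing coverage from mapped nonduplicate read pairs
cov = kc.coverage_estimate(365_436, 75, 3.2e9)
print(f"365,436 read pairs x 2 x 75 bp over a 3.2-Gb genome = {cov:.3f}x per cell")

# gene-set over-representation of differentially expressed genes
universe = {f"g{i}" for i in range(500)}
de = {f"g{i}" for i in range(60)}
stem_set = {f"g{i}" for i in range(40, 90)}
pval, overlap = kc.hypergeom_enrichment(de, stem_set, universe)
print(f"gene-set overlap {overlap}/{len(stem_set)}: hypergeometric p = {pval:.2e}")

# per-cell signature score: mean normalized expression over signature genes
rng = np.random.default_rng(0)
values = pd.DataFrame(
    rng.lognormal(0, 0.5, size=(50, 6)), index=[f"g{i}" for i in range(50)]
)
score = kc.signature_score(values, {f"g{i}" for i in range(10)})
print("stemness-style score per cell:", np.round(score.to_numpy(), 2))
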