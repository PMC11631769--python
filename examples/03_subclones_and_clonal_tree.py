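"""Define subclones from shared SVs and reconstruct the clonal hierarchy.

Continues from the SV calls of a simulated branched tree: cells are
clustered on their binary SV genotypes (Ward linkage, Jaccard distance),
subclones are the resulting groups of >= 3 cells sharing a signature, and
the hierarchy follows from signature containment. The printed fractions are
the percentage of cells per subclone; the classification tells whether the
sample looks monoclonal, linear or branched.
"""

from sklearn.metrics import adjusted_rand_score

import karyoclone as kc
from karyoclone.scenarios import ck_branched_tree

genome, tree = ck_branched_tree()
config = kc.SimConfig(seed=11, n_strand_cells=150)
matrix = kc.simulate_strand_cells(tree, genome, config)

_, _, genotypes, calls = kc.call_svs(matrix)
subclones = kc.define_subclones(calls, list(matrix.cells.cell_id), genotypes=genotypes)
hierarchy = kc.build_hierarchy(subclones)

print(f"found {len(subclones.signatures)} subclones "
      f"({hierarchy.classification} growth)")
print("cell fractions (%):", subclones.fractions(1))
print("parent links:", hierarchy.parents)
print("trunk SVs (shared by all cells):", len(hierarchy.trunk))

ari = adjusted_rand_score(
    matrix.cells.clone_id, subclones.labels.loc[matrix.cells.cell_id]
)
print(f"agreement with simulated truth (adjusted Rand index): {ari:.2f}")
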