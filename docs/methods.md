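# Methods

## The problem

In chromosomally unstable leukemias, single-cell template-strand
sequencing reads out each cell's karyotype at ~100-kb resolution and very
low coverage, while droplet single-cell RNA profiling reads out tens of
thousands of transcriptomes without direct access to structure. This
package implements both sides and the bridge between them: call structural
variants per cell from strand-resolved binned counts, group cells into
subclones, recall the subclone-defining copy-number alterations in the
expression data, and assign expression cells to the genomic subclones.
Because the corresponding patient data are controlled-access, the package
ships a generative model of the whole experiment; every inference stage is
validated against that model's known ground truth.

## Simulation model

**Genome.** Chromosomes are tiled by fixed 100-kb bins; all event
boundaries snap to bin boundaries, matching the resolution of the count
matrix. The default toy genome has five chromosomes of 30–80 Mb and 150
genes per chromosome (~1 gene per 400 kb) with log-normal baseline
expression (log-mean 1.6, log-sd 1.0) — dense enough that a multi-megabase
region holds the >10 expressed genes the mixture filter requires, sparse
enough to keep runs at desk scale. Real chromosome lengths and gene tables
can be supplied instead.

**Karyotypes.** A karyotype stores, per homolog and bin, the number of
forward-oriented and inverted copies. This generalizes per-segment
(copy number, inverted) descriptions: an inverted duplication leaves one
forward and one inverted copy in the same interval, which one flag cannot
express. Deletions remove one copy (forward preferred), duplications add a
forward copy, inverted duplications add an inverted copy, inversions swap
the two orientation counts, and whole-chromosome events add or remove one
copy per bin. Translocations are represented only as copy-neutral labels
on terminal segments; derivative-chromosome dosage and co-segregation
evidence are out of scope.

**Clone trees.** Monoclonal, linear and branched trees attach private
events to nodes; a clone's karyotype is the replay of all events on its
root path, and sibling private events are disjoint by construction.
Random private events default to 10–40 bins (1–4 Mb) — the scale of
subclone-defining alterations in complex karyotypes, and comfortably above
the ~0.5-Mb practical detection floor of binned strand data at the
simulated depth. Default cell fractions decay geometrically
(weights 2^(−i/2)), giving one dominant clone and progressively smaller
subclones, as in patient samples.

**Complex events.** Chromothripsis draws a random alternating state
sequence over n breakpoints with copy levels {0,1,2} (or two of them),
emitting deletions, duplications/inverted duplications, and copy-neutral
inversions on one homolog. Breakage–fusion–bridge emits, per cell, an
inverted duplication at a shared fold point plus a terminal deletion whose
start jitters uniformly (in whole bins) within a configurable range.
Seismic amplification draws a target profile containing every level
0..n_rounds+1 and emits duplications in rounds, each round amplifying a
subset of the segments amplified before (emulating successive circular
recombination), then deletions; replaying the events reproduces the
profile exactly.

**Strand readout.** Per cell and chromosome, the template configuration is
WW/WC/CC with probability 1/4:1/2:1/4 (Mendelian segregation of template
strands; sister-chromatid exchange is not simulated — a documented
limitation). Forward copies of a homolog emit reads on its template
strand; inverted copies emit on the opposite strand. Counts per bin and
strand are negative binomial with mean depth_per_copy × copies and
dispersion φ (variance m + m²/φ; φ = 10 by default, Poisson as φ→∞). The
default depth of 5 reads per bin per copy defines the regime used
throughout the tests; it is a deliberately favorable desk-scale setting —
the real assay is far shallower per cell and compensates with more cells
and larger events.

**Expression readout.** Gene counts are negative binomial with mean
baseline × (CN/2)^α × library factor, with α = 1 by default and library
factors log-normal (sd 0.25). Genes lost on both homologs retain 1% of
baseline as background leakage so mixture fits never see exact zeros. The
simulator reproduces dosage, library-size variation and overdispersion; it
does not model dropout beyond NB sampling, ambient RNA, doublets, cell
types or transcriptional programs — so passing tests demonstrate correct
dosage-signal processing, not robustness to every artifact of real
droplet data.

Identical configurations and seeds give bit-identical outputs.

## SV calling

**Strand-state typing** classifies each (cell, chromosome) by its Watson
fraction (≥0.8 WW, ≤0.2 CC, else WC) in two passes: candidate SV bins
(pooled depth outliers, and bins where nominally one-strand cells show
>20% minor-strand reads) are masked before the second pass, so large SVs
do not distort the template call. Chromosomes under 20 reads are UNKNOWN.

**Segmentation** pools three standardized channels per chromosome — mean
cell-normalized total depth, the minor-strand fraction over WW/CC cells
(sensitive to balanced inversions), and mean |W−C| imbalance over WC
cells (sensitive to haplotype-confined copy changes) — and applies
recursive interval segmentation: at each step the interval whose removal
most reduces the squared error is split out, charging a BIC-style penalty
of 1.5·(channels+1)·ln(bins) per changepoint, minimum segment three bins.
Testing an interval (two breakpoints at once) rather than a single split
keeps short copy-number islands inside long flat chromosomes detectable;
the penalty factor was chosen so that null simulations produce no spurious
breakpoints while clonal and 20–30%-subclonal events are recovered.

**Genotyping** enumerates per-homolog (forward, inverted) copy pairs
(per-homolog total ≤ 4, joint total ≤ 6; beyond that segments are labeled
COMPLEX with clipped copy number). Expected strand totals over a segment
follow from the template configuration; the likelihood is negative
binomial on per-strand segment totals (the exact distribution of a sum of
i.i.d. per-bin NB terms), with 2% of per-copy depth as a mismapping floor
so zero-copy states never have −∞ likelihood. Per-copy depth and
dispersion are estimated from background bins (pooled depth within 15% of
the global median; method-of-moments dispersion floored at 2). The prior
puts 0.5 on the reference genotype and spreads 0.5 uniformly over
alternatives.

Genotypes that are indistinguishable within one cell — identical expected
strand signatures under its configuration, e.g. a duplication of the
Watson-template homolog versus an inverted duplication of the other
homolog in a WC chromosome — are collapsed into equivalence classes whose
prior is the sum over members; the MAP class is reported through its
simplest member (fewest altered homologs, then fewest inverted copies,
then smallest copy change). Orientation and homolog-split ambiguities are
then resolved across cells: WW/CC cells see orientation directly and
out-vote WC cells on DUP-vs-INVDUP, while WC cells see the per-homolog
split and out-vote on one-homolog-vs-both labels. In WW/CC chromosomes
haplotype-of-origin is reported as unphased; linking the altered homolog
across cells would require read-level phasing, which is out of scope.

Calls are compiled at posterior ≥ 0.8 with a minimum-effect filter (a copy
change or an orientation flag) — a reproducible stand-in for manual
inspection — and flagged as singletons when a (segment, label) combination
occurs in exactly one cell.

## Clonal structure

SV burden counts a cell's SV-altered segments, merging adjacent called
segments in the same genotype state so that one event spanning several
called segments counts once per state block; this matches the ground-truth
definition (maximal merged intervals deviating from the reference on
either homolog). Karyotype heterogeneity is the sample s.d. (n−1) of
burdens. Printed percentages round half-away-from-zero.

Subclones: cells are encoded as binary vectors and clustered with Ward
linkage on Jaccard distance. Three design choices matter here, all made
because per-cell calls at shallow depth drop out:

1. Clustering uses MAP genotypes rather than the 0.8-thresholded call
   table — a borderline call still carries grouping information — and
   collapses labels to the dosage direction (gain/loss/copy-neutral
   inversion), so ambiguity between adjacent copy states cannot split a
   clone. Singleton events are excluded: private events, real or
   spurious, say nothing about shared ancestry.
2. The dendrogram cut is the finest one whose post-processed cluster
   signatures (SVs in ≥ 2/3 of members; clusters under three cells merged
   into the most signature-similar cluster unless their signature strictly
   extends a retained one — the clear-progeny exception) are pairwise
   distinct.
3. Nested clusters are tested for dropout: if sig(A) ⊂ sig(B), cluster A
   is either a true ancestral clone or B-cells whose calls at the
   distinguishing segments fell below threshold. The mean non-reference
   posterior of A's cells at those segments separates the cases — near
   the ~0.05 background for true ancestors, several-fold higher for
   dropout. A merges into the best-evidence container when that mean
   exceeds max(0.15, 3× its own background). The 0.15 floor sits midway
   between the background level and the posterior mass typical of
   borderline carriers.

The hierarchy takes the trunk as the intersection of all signatures and
each node's parent as the largest signature strictly contained in its own
(ties to the larger clone); one subclone is monoclonal, a single chain is
linear, anything else branched.

## Expression-side recalling and assignment

Counts are normalized to log2(CPM/10 + 1). A region's per-cell score is
the mean over its expressed genes (nonzero in ≥5 cells) of the
gene-centered normalized values; regions with ≤10 expressed genes are
skipped. A one-component Gaussian (closed-form MLE) is compared with a
two-component mixture fit by EM (unequal variances, sd floored at 1e-3,
best of ~10 deterministic initializations from a median split, quantile
splits and one jittered start). The likelihood-ratio statistic is referred
to χ²(3) — mean, variance and weight; the mixture LRT is non-regular, so
this is a ranking/filtering approximation, not an exact test. BIC = k ln n
− 2 loglik with k = 2 and 5; "BIC improvement" means BIC1 − BIC2. A region
passes with BH-adjusted p < 0.01, ΔBIC > 200 and >10 expressed genes; the
joint filter holds the empirical null pass rate at or below 2%. Per-cell
responsibilities label the lower-mean component "low" (fewer copies under
the dosage assumption); 0.8 is the confidence cutoff.

Marker profiles give each subclone an expected component per passed
region, derived either from clone karyotypes (simulation route) or from
the subclone's own signature calls (fully inferred route); regions where
a clone is diploid expect the component occupied by non-carriers. A cell's
clone posterior is the normalized product of per-marker component
posteriors under a uniform clone prior (this reduces to the single-marker
0.8 rule when one marker separates the clones); clones identical over all
passed markers are merged into one assignment group and reported as
unresolvable. Pre-leukemic cells are those annotated as HSPCs whose
posterior of the non-aberrant component reaches 0.8 at every marker.
Cross-modal concordance is the Spearman correlation of subclone fractions
(mid-ranks, two-sided asymptotic p).

## Downstream statistics

All multiple testing goes through one BH step-up implementation. The
differential-expression routine removes a categorical cell-type covariate
by per-type centering (a deterministic reduction of "cell type as a
predictor in the linear model"), applies a two-sided Welch t per gene, and
flags upregulated genes at FDR ≤ 0.05 and a mean difference ≥ 0.1 on the
normalized log scale; because the threshold's log base is convention, the
unadjusted group-mean difference is also reported. The Wilcoxon rank-sum
test is exact for ≤25 untied observations per side, otherwise a normal
approximation with continuity correction. Fisher's two-sided p follows
the probability-mass convention (sum over tables no more probable than
the observed; p = 1 on a degenerate margin). Gene-set over-representation
is the upper-tail hypergeometric with BH across sets. Signature scores
are per-cell means of normalized expression over the signature genes.
Coverage is read_pairs × 2 × read_length / genome_length.

## Problem sizes and determinism

The shipped tests and the acceptance script run on the toy genome with
100–200 strand cells, 400–1,500 expression cells, depth 5 per copy and
200-region null batches — sizes chosen so the whole loop stays
desk-scale while every recovery metric is measured, not assumed. All
randomness flows through explicit seeds; inference itself contains no
randomness except the seeded EM initializations.

## Known limitations

Sister-chromatid exchange, translocation dosage, read-level phasing,
doublets, ambient RNA and cell-type structure are not modeled. Balanced
inversions are invisible without strand information (verified by a test
that collapses strands). Duplications are harder to recall from
expression than deletions (a 1.5× shift versus 0.5×), so gain-only
subclones can fail the strict ΔBIC filter and merge into their parent
assignment group. Per-cell genotype confidence at depth 5 is marginal for
events under ~1 Mb; the clustering layer compensates for call dropout but
single-cell calls near that scale should be read with their posteriors.
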