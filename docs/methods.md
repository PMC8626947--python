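# Methods

`peatvirome` implements the quantitative core of a soil/peat viromics
study: from viral contigs and read alignments to species-level viral
populations (vOTUs), breadth-gated abundance tables, genus-level
gene-sharing viral clusters (VCs), CRISPR-based virus–host links,
community-ecology statistics, and phylogenetic dispersion of binary
traits. A seeded synthetic community generator stands in for raw
sequencing data, so every stage is tested against planted truth.

## Species-level dereplication (vOTUs)

Two contigs belong to the same vOTU when they share ≥ 95% nucleotide
identity across ≥ 85% of the length of the shorter contig. Identity is
computed from a "fit" alignment: the shorter sequence is aligned
end-to-end against the longer with free terminal gaps on the longer only
(match +1, mismatch −1, gap −2). Identity is matches over alignment
columns; coverage of the shorter contig is the fraction of its bases
paired with a base of the longer. Both orientations are evaluated and
the better identity kept (`try_rc=False` disables this).

Clustering is greedy and longest-first (ties broken by id): the first
unassigned contig founds a cluster, and each subsequent contig joins the
first representative, in creation order, that it qualifies against —
the centroid semantics of the classic dereplication tools. The
canonical sort makes the partition independent of input order.

Numerics: problems up to ~2 kb × 2 kb run the full dynamic program
(numba-compiled); larger problems run a banded dynamic program whose
band spans all shared 15-mer diagonals plus a 48-column pad, which is
exact for substitution-dominated pairs. A k-mer containment prefilter
(≥ 25% shared 15-mers, either orientation) skips alignments that cannot
reach the species threshold; the test suite verifies both accelerations
against an independent full-DP oracle.

## Detection and abundance

A read supports a contig when its identity, 1 − NM / aligned read
length, is ≥ 0.90 (insertions count against identity; reference
deletions do not). A vOTU is detected in a sample when ≥ 75% of its
length is covered ≥ 1× by qualifying reads; both thresholds are
inclusive. Abundance is the trimmed mean of the per-base depth vector
(the ⌊0.1·L⌋ highest and lowest values dropped — the concrete reading
of "tpmean"), scaled by 10⁷ / library size. The fixed scale is
arbitrary; every downstream statistic is invariant to it. Fold
differences in per-sample richness print as the nearest integer at
ratios ≥ 10 and with one decimal below that, which reproduces the
published values from their reported means.

## Gene-sharing viral clusters (VCs)

Proteins are clustered greedily (longest-first centroids, global
amino-acid identity ≥ 0.60 over ≥ 0.80 of the shorter). Each genome is
profiled by its protein-cluster set; a genome pair sharing c clusters
from a universe of M is scored −log₁₀ of the Bonferroni-corrected
hypergeometric tail P(X ≥ c), and pairs scoring ≥ 1 form a similarity
graph. The graph is partitioned by Markov clustering (expansion 2,
inflation 2.0, prune 10⁻⁶), with clusters extracted as connected
components of the limit matrix's support — fully deterministic, unlike
the heuristic cluster-growing stage of the usual gene-sharing pipeline,
which it replaces here. Singleton VCs count as VCs throughout.
Taxonomy transfers to all members of any VC containing a reference
genome ("ambiguous" on conflict, still classified). A vOTU is
"aquatic-like" when its VC contains a marine or freshwater vOTU.
Within-VC AAI is the mean over genome pairs of mean best-reciprocal
protein identity, with reciprocal hits under 30% identity discarded as
non-homologous (the usual AAI homology floor). Summary percentages
round half away from zero to integers.

## CRISPR virus–host linkage

An array links a vOTU to a MAG when its repeat occurs exactly (100%
identity, either strand) in a MAG contig and one of its spacers matches
a vOTU with ≤ 1 mismatch — full-length Hamming distance, both strands,
no indels. For spacers ≥ 20 nt this substitution-only rule is the
equivalent of the 95%-identity short-BLAST convention; shorter spacers
are rejected because one mismatch would break it. Arrays anchoring to
several MAGs emit all linkages flagged `multi_host_anchor`. For vOTUs
linked to several hosts, the deepest shared rank of the GTDB-style
taxonomy strings is reported.

## Ecology statistics

Ordination follows the standard vegan-style workflow: Hellinger
standardization per sample, Bray–Curtis dissimilarity, principal
coordinates (negative eigenvalues reported, coordinates from positive
axes). Mantel (Pearson, one-sided upper) and one-way PERMANOVA use
seeded permutation machinery from scikit-bio with
p = (#{stat_perm ≥ stat_obs} + 1)/(n_perm + 1); the test suite
cross-checks both statistics against hand-rolled formulas and
permutation loops. Accumulation curves average cumulative distinct
detections over permutations of sample order.

Differential abundance across depth levels is a negative-binomial GLM
likelihood-ratio test: median-of-ratios size factors; per-vOTU
dispersion by Cox–Reid-adjusted profile maximum likelihood; a
parametric mean-dispersion trend α(μ) = a₀ + a₁/μ with a log-normal
empirical-Bayes prior shrinking gene-wise estimates toward it (MAP);
full model log μ = offset + β₀ + β_level against the intercept-only
reduced model; 2Δloglik referred to χ²(levels − 1);
Benjamini–Hochberg adjustment, significance at padj < 0.05. The
moderation step is deliberate: without it, dispersion-estimation noise
at five samples per level makes the χ² reference measurably
anti-conservative (empirical type-I ≈ 0.09 at nominal 0.05 in our
simulations) and costs power; with it the test calibrates at ≈ 0.07 and
detects 4-fold effects at dispersion 0.5 with ≥ 80% power. Outlier
replacement and independent filtering are not implemented;
`moderate=False` gives the plain gene-wise estimator.

Significant vOTUs are grouped by Z-transforming (population SD) their
size-factor-normalized mean abundance per depth level, complete-linkage
clustering on Euclidean distance, cutting at k = 3, and labeling groups
1..k by the depth of their peak mean Z (shallow→deep). Constant
profiles become zero vectors (logged). Trait enrichment per group is
the upper-tail hypergeometric test against the trait's frequency in the
full detected set.

## Fritz–Purvis D

Tips take their 0/1 state; internal nodes take the unweighted mean of
their two daughters (branch lengths ignored at this step, matching the
statistic's reference implementation); d is the sum over edges of
|child − parent|. D standardizes d_obs between two simulated nulls
sharing one seed stream: tip-label permutation (D calibrated to 1) and
Brownian motion along branches (variance ∝ length, root 0) thresholded
at the observed prevalence (D calibrated to 0). D < 0 indicates
phylogenetic clustering stronger than Brownian expectation.
Multifurcating or unrooted input trees are deterministically
bifurcated with zero-length edges by the Newick reader; absent branch
lengths default to 1.0 (the least-informative choice, needed by the
Brownian null). Monomorphic traits and degenerate trees (random null
not exceeding the Brownian null) are errors, not numbers.

## Synthetic community generator

The generator's defaults are the study design the tests run against:
25 viral genera × 6 species × 2 sequence variants (genomes 10–12 kb),
per-genus pangenomes of 30 proteins (40% core, accessory carried with
probability 0.5, within-family amino-acid divergence 0.15), habitat
weights (soil 0.45, peat 0.40, marine 0.10, freshwater 0.05) with a
0.2 chance that a terrestrial genus harbors one aquatic species, 12
hosts × 4 spacers (32 nt, one planted substitution with probability
0.15), 20 samples over four depth levels, negative-binomial counts
(baseline means log-uniform on [5, 50], dispersion 0.3, library sizes
8–12k), three planted depth-differential groups of sizes (32, 15, 15)
with a 4-fold effect, aquatic-like selection odds 4 for the surface
group, and 150 bp reads at 0.5% substitution error.

Design choices that make the planted structure exactly checkable:

* Substitutions only (no indels), so every planted identity is a
  computable Hamming fraction.
* Each species draws one set of "variable positions"; all variants
  mutate exactly those positions. Independently mutated variants would
  sit at ~2× the intended divergence from each other and cross the 95%
  species boundary; sharing the positions pins every same-species pair
  at or above `within_species_ani`.
* Species founders diverge from a genus backbone at
  1 − `between_species_ani` (pairwise ≈ 0.72, safely below 0.90).
* Habitat labels attach at the species (vOTU) level; a genus's habitat
  set is the union over its species, which defines the aquatic-like
  truth flag.
* Protospacer windows are rejection-sampled to lie ≥ 4 substitutions
  from every other same-genus representative on both strands, so a
  planted spacer identifies its source vOTU uniquely — mirroring the
  specificity of real spacer–protospacer matches and making the
  zero-false-positive linkage check meaningful.
* Aquatic-habitat vOTUs receive zero counts in the peat abundance
  design (they exist only as reference relatives), as in a terrestrial
  community referenced against a cross-ecosystem database.
* One root seed; each stage (community, hosts, abundance, reads) draws
  from a child stream with a fixed spawn key, so later stages can be
  replicated without disturbing earlier ones and identical seeds give
  byte-identical outputs.

What the generator does not emulate: indels and rearrangements,
quality-score and GC biases, proviruses and plasmids, assembly
artifacts, uneven genome recovery, or real phylogenetic depth in the
protein families. Passing the planted-recovery tests therefore shows
the algorithms implement their definitions correctly at realistic
signal strengths — not that the pipeline is robust to every failure
mode of real sequencing data.

## Problem sizes used in tests

The acceptance-style checks run the default design above (300 contigs,
150 vOTUs, ~3,200 representative proteins, 20 samples, ~200k reads);
statistical calibration uses 20 simulations × 200 vOTUs for the null
error rate, 10 abundance replicates for power (dispersion 0.5), 200
null simulations for Mantel/PERMANOVA, 20 replicates for the
enrichment flag rates, and 50 replicates × 300 null draws on a 128-tip
tree for D. These sizes put Monte-Carlo error comfortably below the
asserted tolerances while keeping the whole suite at desk scale.

## Known limitations

* The aligner's identity for unrelated sequences reflects the optimal
  gapped alignment (~0.5 for random DNA), not the gapless expectation
  (~0.25); decisions only ever compare identity against the 0.95
  threshold, where the distinction is immaterial.
* The NB-LRT is calibrated for the moderate sample sizes it is tested
  at; at very small n (< 3 per level) the χ² reference degrades.
* MCL with connected-component extraction cannot split a connected
  component into overlapping clusters; at the edge-score threshold used
  here that situation did not arise in any planted design.
* PERMANOVA is one-way only; the study's other covariates enter through
  Mantel tests.
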