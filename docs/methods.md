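# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the
known limitations. Problem sizes quoted here are the defaults the tests
and the acceptance script use.

## Coordinates and interchange formats

GFF3 and VCF are 1-based inclusive on disk; all in-memory coordinates are
0-based half-open; written outputs restore the on-disk convention. Every
stage exchanges plain text (TSV, FASTA, Newick, BED, VCF) so any stage can
be re-run or inspected in isolation.

## Family catalog

A locus belongs to the family iff at least one transcript (i) has hits to
all required domains, each with E ≤ 10⁻⁵ (configurable), and (ii) carries
a complete ORF, operationalized as: starts with ATG, ends with a stop, no
internal stop, length divisible by 3. Among several qualifying transcripts
the longest peptide is kept; ties break to the lexicographically smallest
transcript id (the choice is arbitrary but fixed — determinism over
fidelity to any particular legacy tool). Domain hits are consumed as a
generic one-row-per-hit table; running the HMM/BLAST search itself is out
of scope.

Protein properties use standard average residue masses (MW = Σ residue
masses + one water) and a bisection solve of the Henderson–Hasselbalch net
charge for pI, with the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1). pKa tables differ between
tools, so pI values are comparable only within one table; tests therefore
check ranges and convergence (|net charge| < 10⁻⁴ within 100 iterations),
not third-party equality. `X` residues count toward length but are
excluded from mass and charge.

## Phylogeny

Distances are uncorrected p-distances; "conserved sites" means
complete-deletion columns (no gap in any row), with pairwise deletion and
a Poisson correction available as options. The distance model mainly
rescales branches; the class assignment depends on topology.

Neighbor joining follows the Q-criterion agglomeration. All ties (in Q and
in the final three-taxon join) break lexicographically on cluster labels,
a cluster's label being its smallest leaf name, so a matrix has exactly
one output tree. Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge of the join, preserving the joined
pair's path length; on additive input no clamping triggers and the tree's
path-length matrix equals the input exactly (tested to 1e-9 on 200 random
additive matrices of up to 12 taxa).

Bootstrap resamples alignment columns with replacement; supports are the
percentage of replicates containing the same bipartition. The resampling
stream depends only on the seed and the number of columns, never on taxon
order, so supports are invariant under taxon permutation.

Class assignment midpoint-roots a copy of the tree, then gives each
unlabeled leaf the class of its smallest ancestral clade that contains at
least one reference taxon — provided all references in that clade agree;
otherwise "unresolved". A leaf can never receive a class absent from the
reference set.

## Duplication

Collinearity works in gene-rank space (base-pair spans are irrelevant to
anchor chaining). Hits at E ≤ 10⁻⁵, deduplicated per gene pair by best bit
score, are chained per chromosome pair by dynamic programming: strictly
monotone in both genomes (same or inverted orientation), consecutive rank
gaps ≤ 25 (the common default of collinearity tools), chains of ≥ 5
anchors reported. When chains compete for anchors, the longest chain wins
(ties by summed bit score), its anchors are retired, and chaining repeats —
an anchor belongs to at most one block. Exact reproduction of MCScanX's
scoring is a non-goal; the chainer is validated against a brute-force
longest-monotone-chain oracle on small instances.

Tandem: two members are linked iff they share a chromosome with at most
one intervening (non-family) gene; clusters of ≥ 2 linked members are
tandem. Segmental: a member anchored in a block to another member; the
matched anchor pairs are the collinear family pairs.

Ka/Ks is the NG86 estimator: per-codon synonymous site fractions
(mutations creating stops count as nonsynonymous), averaged between the
two sequences; differences averaged with equal weight over all minimal
mutational pathways, excluding pathways through stop codons (if every
ordering is blocked, all orderings are used); Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). Codons containing gaps, ambiguity codes or stops
in either sequence are skipped pairwise. A saturated proportion
(p ≥ 3/4) yields an infinite distance with a warning rather than an
exception, so a pure-synonymous toy pair still reports Ka = 0, ω = 0.
The estimator is symmetric in its arguments and is checked codon-by-codon
against an independently written pathway-enumeration oracle over all
61 × 61 sense-codon pairs.

Ks bins for the three soybean-lineage WGD events are half-open with
boundaries assigned to the older event: [0, 0.3) *Glycine*, [0.3, 1.5)
legume, [1.5, ∞) γ. Dating uses T = Ks/(2λ), λ = 6.1 × 10⁻⁹ interpreted as
synonymous substitutions per site per year, reported in Mya. Summary
percentages are rounded half-to-even to one decimal; note that 42/93 =
45.16% therefore prints as 45.2.

## Expression

The grand mean for the high-expression rule is the mean over every
gene × sample entry (an external baseline can be supplied when only a
subset of the matrix is at hand). Tissue specificity is formalized as
τ = Σ(1 − xᵢ/x_max)/(n − 1); "specific" requires τ ≥ 0.85 **and** a peak
of ≥ 10 FPKM, a combination that reproduces loose organ-specific calls
(secondary signal in a second tissue) where a max/second-max ratio rule
fails. Inactive means every sample < 1 FPKM.

Infection response uses L_t = log₂((FPKM_t + 0.001)/(FPKM₀ + 0.001)) with
induced iff max L ≥ +1 and min L > −1, suppressed symmetric, both → mixed.
Threshold comparisons carry a 10⁻³ tolerance because the pseudocount
slightly deflates exact round-number folds (10 → 20 FPKM gives
L = 0.99993). Genes never reaching 0.5 FPKM are "unchanged" regardless —
the pseudocount would otherwise manufacture large ratios on silent genes.
Collinear-pair divergence is Pearson r on log₂(FPKM + 1) with
"similar" iff r ≥ 0.5; a constant profile is "similar" only to an equal
constant profile. These numeric rules are this package's formalization of
qualitative published criteria; the thresholds are configurable.

## Selection scan

Filters (missingness ≤ 10% of allele calls, MAF ≥ 5% of called alleles)
are computed on the combined two-population panel before splitting; the
published order of operations is ambiguous and this choice is fixed and
documented. Per-site diversity is the unbiased h = n/(n−1)·(1 − p² − q²)
over called alleles; diploid genotypes contribute both alleles and
half-missing calls contribute their called allele. Window π divides the
summed h by the full (truncated at chromosome end) window span, so
monomorphic positions count as zero diversity — the common windowed-π
convention. Windows are [k·step, k·step + size); size < step is rejected
because it would drop SNPs between windows. Every interior SNP falls in
exactly size/step = 2 windows at the 20-kb/10-kb default.

The sweep statistic is the per-window ratio π_cultivated/π_wild; low
ratios mark candidate sweeps (diversity lost under domestication).
Windows with π_wild = 0 carry a null ratio and are excluded from ranking.
A gene's region ratio is the mean over its overlapping windows and is
compared to the arithmetic mean ratio of its chromosome. The sweep
threshold is the k-th smallest defined ratio genome-wide with
k = ⌊0.05·n⌋ (at least 1) — literally the "lowest 5% of windows" — and
ties at the threshold are included; a gene is selected iff it overlaps at
least one such window. The window-π implementation is verified to 1e-12
against a brute-force average-pairwise-differences oracle.

The accession tree uses 1 − IBS distances (identity-by-state proportion
over sites where both accessions are fully called), restricted to the
selected gene regions, fed to the same NJ implementation.

## Synthetic data

The generators are pure functions of (config, seed); reruns are
byte-identical and every emitted file round-trips through the package's
readers. Defaults mirror the study conditions where these are stated:
a 93-member family, nine tissues, time points 0/0.5/3/6/12 h, 11
constitutive / 8 specific / 11 inactive / 9 induced / 12 suppressed
planted genes, a 62-wild + 240-cultivated panel, 20-kb/10-kb windows,
three sweep regions at 10-fold diversity reduction. Desk-scale choices
made here: 1000 genes on 4 chromosomes, 300-codon family CDS, 4 × 2 Mb
panel chromosomes at ~1 SNP / 250 bp, 100-kb sweep spans.

*Genome*: family loci are laid out deterministically — tandem clusters
(with and without the one allowed spacer), duplicated segments of 8
anchors with family pairs interleaved at every third anchor (so segmental
pairs are never also tandem), and isolated singletons; non-family genes
fill the remaining ranks. Five deeply diverged class-ancestor sequences
provide both the reference taxa for classification and the within-class
structure. Decoy loci carry partial domain signatures, above-threshold
E-values, or broken start codons, exercising each arm of the membership
rule; one locus carries two qualifying transcripts to exercise
deduplication. Family peptides are equal-length by construction, so the
emitted "alignment" is exact and the out-of-scope aligner is not needed.

*Codon evolution* applies uniform per-site nucleotide proposals, accepting
synonymous changes always and nonsynonymous ones with probability ω
(acceptance thinning), never introducing stops; the total synonymous
event count is Poisson with mean Ks·(synonymous sites), split evenly
between lineages. This matches NG86's uniform-mutation assumptions by
design — it validates estimator correctness, not robustness to transition
bias or codon-usage skew. At the study conditions (500 codons, Ks 0.5,
ω 0.3) the mean recovered ω over 20 seeds is ~0.30.

*Population panel*: allele frequencies, not genealogies. Wild frequencies
are Beta(0.3, 0.3) (U-shaped spectrum); cultivated frequencies follow a
Beta drift kernel with effective size parameter k = 30 (the bottleneck),
and inside sweep regions a fraction 1 − 1/reduction of sites is pushed to
fixation, cutting expected heterozygosity by the reduction factor.
Genotypes are binomial draws; 2% of calls are missing, with 2% of sites
at 30% missingness to exercise the missingness filter. There is no
linkage disequilibrium, recombination map or realistic demography — the
panel produces the diversity-ratio signal the scanner consumes, nothing
more. Sweep recovery at defaults: sensitivity 1.0, gene-level false
positives ~2% over 10 seeds.

*Expression*: multiplicative lognormal noise (σ = 0.2) over planted
structure; the constitutive level is solved against the final grand mean
so every planted tissue value exceeds 3.5× it before noise. Label
recovery at default noise is ~99.5%; what passing shows is that the
classifiers invert the generator's construction under moderate noise, not
that the thresholds are optimal for any real RNA-Seq dataset.

## Pipeline

Stages run in dependency order, each writing its outputs before the next
starts; errors carry the stage name. The effective configuration is
dumped to JSON at the start of each run. One global seed drives the
bootstrap (seed + 1) and the synthetic sub-generators (seed + 1, + 2);
identical inputs and seed give byte-identical outputs. The default
synthetic end-to-end run (93-member family, 1000-replicate bootstrap,
~30k-SNP panel) completes in well under five minutes on one CPU.

## Known limitations

- p-distance NJ reproduces published tree *topology* behavior, not any
  specific legacy implementation's branch lengths or tie handling.
- NG86 is deliberately the simplest fully specified Ka/Ks estimator;
  model-averaged calculators will differ numerically, especially at high
  divergence where the Jukes–Cantor correction is unstable (Ks ≳ 2
  estimates are noisy and can saturate).
- The expression thresholds (τ ≥ 0.85, |log₂| ≥ 1, r ≥ 0.5, 1 FPKM floor)
  formalize qualitative criteria; published per-gene counts that depend on
  unstated rules are not claimed reproducible.
- The frequency-level population model cannot support haplotype statistics
  (XP-EHH etc.); only diversity-ratio scans are meaningful on it.
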