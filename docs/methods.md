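# Methods

`cgrmap` implements the computational workflow with which a phenotype-linked
gene cluster — the cardiac glycoside reductase (*cgr*) locus of *Eggerthella
lenta*, whose Cgr2 enzyme inactivates the cardiac drug digoxin — is located
in a strain collection, its conservation quantified, its bi-allelic codon
(Y333N) typed directly from metagenomic reads, and its prevalence measured
across human gut microbiomes. This note describes the models and procedures,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Pairwise identity and ANI

All percent identities use one formula:

    identity = 100 · identical / (aligned + internal gaps)

computed on an optimal global (Needleman–Wunsch) alignment with affine gaps
(a gap of length L costs `gap_open + L·gap_extend`). *Aligned* columns carry
a residue in both rows; gap columns inside the alignment count in the
denominator, terminal gap runs do not — so a full-length self-comparison is
100% and a short gene aligned to a longer homolog is not penalised for its
tails. Defaults: nucleotide match/mismatch +1/−1, gaps −5/−2; amino acids
BLOSUM62 with gaps −11/−1. The aligner's parameters are configurable because
printed identities can shift in the second decimal under different schemes.
Ambiguity codes (N, X) score as mismatches and never count as identical.
Deterministic DP and traceback make all results reproducible.

Genome-level average nucleotide identity (ANI) is fragment-based: the query
genome is cut into 1020-nt windows, each placed at its best edit-distance
location in the subject (both strands, infix alignment), and ANI is the mean
fragment identity over fragments passing filters, symmetrised over both
directions. Two numerical choices matter here. First, an edit-distance
alignment is global over the fragment, so a fragment only partly homologous
to the subject drags a non-homologous stretch along; each fragment alignment
is therefore trimmed to its best-scoring local block (maximum-sum over
columns at +2 per match, −3 per mismatch or gap column) before the filters
are applied. Second, unrelated DNA shows ≈55% nominal identity under edit
distance (gaps chain chance matches), so the fragment identity floor is 70%
— clearly above that baseline and clearly below genuine same-species
homology; the coverage floor is 70% of fragment bases inside the trimmed
block. Under these rules a genome against itself is 100.0, a 1%-substituted
copy is 99.0 ± 0.2, and simulated conspecific strains with gene-content
differences land near 98 — the range reported for real *E. lenta* strain
collections. Strain dereplication links pairs with ANI strictly above
99.99% and keeps one representative per single-linkage group (longest
assembly, ties by id).

## Pan-genome construction

Protein-coding genes are clustered into ortholog groups by single linkage
over pairs with global amino-acid identity ≥ 60% and aligned span covering
≥ 80% of *both* sequences (bidirectional coverage is the conservative
reading where tools differ). All-vs-all alignment is pruned by an 8-mer
inverted index (two shared protein 8-mers propose a candidate pair) with
union-find short-circuiting; on families separated by more than the
threshold this is exact for the connected components. Compared with
reciprocal-best-hit + partitioning tools, plain single linkage can chain
clusters through intermediate sequences in dense homology landscapes; on
well-separated families (and in the simulations here) the partitions agree.
Cluster ids are assigned deterministically from sorted member ids.

A presence/absence matrix over genomes × clusters classifies clusters as
core (all genomes), singleton (one genome) or accessory. Paralogs do not
change presence. Conservation of a cluster is the mean pairwise amino-acid
identity over its members (undefined for singletons), and a cluster of
interest is ranked as a percentile — 100 · (# clusters with conservation ≤
query)/n, the "≤" convention — within the pan, core or non-singleton
accessory distribution.

## Trait mapping

Metabolizer status is called from replicate product measurements by one-way
ANOVA followed by Dunnett many-to-one comparisons against vehicle controls
(scipy's exact multivariate-t integration; a Monte-Carlo evaluation of the
same null is kept as a test oracle), flagging strains with adjusted p <
0.05 and mean above control.

Columns of the presence/absence matrix with identical patterns are collapsed
into single features (the locus is discovered as a unit — co-occurring genes
are indistinguishable to any classifier). A random forest (500 CART trees on
bootstrap samples, ⌊√p⌋ features per split, Gini impurity, seeded) ranks
features by mean decrease in Gini impurity, computed as the per-tree
*unnormalised* total impurity decrease averaged over trees — the convention
of the classical R implementation, monotone-equivalent to scikit-learn's
normalised importances but on the familiar scale. Features whose pattern
equals the phenotype vector or its complement (absence is equally
informative) are flagged perfect discriminators, each with a two-sided
Fisher exact p; for the canonical 8-metabolizer/17-non-metabolizer design a
perfect pattern gives p = 1/C(25,8).

## Phylogenetic signal (Blomberg's K)

For a trait x on a tree with Brownian covariance structure V (V_ij = shared
root-to-tip branch length),

    â   = (1ᵀV⁻¹x)/(1ᵀV⁻¹1)
    MSE0 = (x−â1)ᵀ(x−â1)/(n−1)
    MSE  = (x−â1)ᵀV⁻¹(x−â1)/(n−1)
    K    = (MSE0/MSE) / { [tr(V) − n/(1ᵀV⁻¹1)] / (n−1) }

K ≈ 1 under Brownian evolution and → 0 when trait values are independent of
the phylogeny. Significance comes from permuting trait values across tips,
comparing on MSE (lower = more signal) with the observed configuration
counted among the permutations, so p ∈ [1/n_perm, 1]; comparing on K is
exposed as an option. Implementation agrees with the R package picante's
`Kcalc` to 12 decimals on fixed inputs, and the mean K over 1000 Brownian
simulations on a fixed 24-tip tree falls in [0.9, 1.1]. Requirements: n ≥ 4,
non-constant trait, non-singular V (condition number < 1e12).

## Metagenome quantification and variant calling

Reads are recruited to gene references by best edit-distance placement over
references and strands, requiring ≥ 90% nucleotide identity and ≥ 90% of the
read aligned. Internally generated alignments get MAPQ 60 for a unique best
placement and 0 for ties, so the standard MAPQ ≥ 10 pileup filter removes
multi-mapped reads; SAM input keeps the aligner's own MAPQ. Per-position
base counts (1-based coordinates throughout) feed a majority-rule caller: a
variant is called iff depth ≥ 1 and strictly more than 50% of reads support
one alternative base; a tie between two top alternatives is flagged
ambiguous, no call. The caller matches a literal rule oracle over every
count configuration with depth ≤ 6. Calls are written as minimal VCF
(CHROM/POS/REF/ALT with DP and AF in INFO).

Protein-level allele typing aligns a candidate to the reference window
focal ± 60 residues; candidates with identity strictly above 80% report the
residue aligned to the focal column (gap → unalignable).

Gene abundance in a metagenome is *copies per cell*: gene depth divided by
the median depth of universal single-copy marker genes. How the original
abundance service normalises (marker panel, mean vs median) is not public;
the median-of-markers rule is this package's operationalisation and can
shift absolute abundances, not detection calls. Cohort statistics:
prevalence is the percent of individuals detected, using the per-individual
*median* over repeat samples (detection: abundance > 0 in copies-per-cell
mode, ≥ the detection limit — default 1e3 copies/g — in qPCR mode); the
cgr-ratio is log10(cgr2/elnmrk1) for individuals with both genes
quantifiable; its asymmetry is tested with D'Agostino's skewness test
(g1 = m3/m2^{3/2} on biased central moments, the standard
normal-approximation transform, two-sided p; n ≥ 8); marker association uses
Spearman's rho on midranks with a t-approximation p, or the exhaustive
permutation null for n ≤ 10. Reconstruction eligibility of a metagenome is
proportional abundance > 0.001 OR fold coverage > 1 (strict).

## Synthetic data: what it emulates, what it does not

`simulate_pangenome` builds a clonal-frame strain collection: ancestral gene
sequences (codon-aware, no internal stops) diverge by independent per-site
substitutions (default 1%); intergenic spacers and gene orientations are
ancestral and diverge the same way. Defaults emulate a 24-strain collection
with a planted 8-gene cluster carried by the 8 metabolizer strains only; the
focal planted gene carries Y (TAT) or N (AAT) at protein position 333, with
the N allele in 5/8 of metabolizers. `simulate_trait_on_tree` draws Brownian
(covariance σ²V) or white-noise traits. `simulate_reads` draws uniform
fragment starts from a strain mixture with substitution-only errors
(constant Q30 qualities; indel rate exposed, default 0 — the caller is
substitution-oriented). `simulate_qpcr_cohort` gives each individual a
log-normal total-population marker (mean log10 = 4.8, sd = 2.0 copies/g) and
a Beta(2, 0.8) carrier sub-population fraction, so the true log-ratio is ≤ 0
and left-skewed; with the 1e3 copies/g detection limit this lands marker
prevalence near 80% and observed ratio skew near −0.7, the regime reported
for real qPCR cohorts; 44% of individuals contribute a repeat sample.

Not emulated: recombination and rearrangement, indel/structural variation,
GC and amplification bias, chimeric reads, paralog birth, non-uniform
coverage. Nor gene-specific selective constraint: every family diverges at
the same rate, so a cluster's conservation percentile is exchangeable across
clusters in simulation (in real collections percentiles carry information
because purifying selection varies between genes). Passing tests therefore demonstrate correctness of the
computations under a substitution-dominated, colinear model — not robustness
to assembly artefacts or complex strain mixtures in real data.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic given
it. The test suite and the acceptance script run simulations at desk scale
as the package's own standard configurations: 24-genome collections
(~250 ortholog clusters), 100 replicate 20 × 500 presence/absence matrices
for planted-locus recovery, 1000 Brownian replicates for K calibration,
2000 replicates for skewness type-I error, 2000-read mixtures for allele
recovery, and 158-individual cohorts.

## Known limitations

Single-linkage clustering can chain distinct families through intermediates;
the ANI mode is fragment/edit-distance based rather than BLAST-based and can
deviate from published ANI values in the second decimal; Dunnett p-values
assume equal variances across groups; the exact Spearman option is
exhaustive and limited to n ≤ 10; copies-per-cell values depend on the
chosen marker panel.
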