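# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `twinmag`, in the order the pipeline runs them.

## Synthetic study conditions

The generator exists so that every downstream stage can be validated
against known ground truth. It emulates the statistical structure the
analysis assumes, not any particular cohort's biology.

**Genomes.** Each genome is sampled from a first-order Markov chain over
{A, C, G, T}. A genome-specific random (or user-supplied) transition
matrix is adjusted by iterative proportional fitting until its stationary
base composition matches the GC target (tolerance 1e−6 on the stationary
distribution; observed GC lands within ±0.01 of target). Distinct
transition matrices give distinct dinucleotide — and hence 5-mer —
signatures even at equal GC, mirroring the compositional separation that
makes real k-mer binning work. Defaults: length 1 Mb, GC targets spanning
0.30–0.70 (real oral MAGs span roughly 0.25–0.72).

**Contigs.** Genomes are cut sequentially into non-overlapping fragments
with log-normal lengths (median 1.5 kb, σ_log = 0.8, hard minimum 300 nt),
which populates both the seed class (≥ 2,500 nt, ~25% of contigs) and the
recruitment class (300–2,500 nt). A fixed-tiling mode supports exact
unit tests. Trailing fragments below the minimum are discarded, so contig
lengths never exceed the genome length.

**Twin-structured abundance.** For each genome, subject latent
log-abundance is z = √a²·G + √c²·C + √e²·E with unit marginal variance:
G identical within MZ pairs and correlated 0.5 within DZ pairs
(G₂ = ½G₁ + √¾·G′), C shared within every pair, E independent. A caries
effect is a fixed log₂ shift added to selected genomes in caries-positive
subjects, giving the enrichment stages a planted truth. Relative
abundances are softmax-normalized exp(latents); counts for contig *j* in
subject *i* are Poisson with mean depth · (length_j/1000) ·
relabund · n_genomes (default depth 50 reads per contig-kb — deep enough
that counting noise does not dominate the latent structure). Poisson was
chosen as the simplest adequate noise model; overdispersed alternatives
can be added behind the same interface. Metadata: co-twins share sex and
age (ages 5–11, a juvenile cohort); caries status is drawn independently
per subject at prevalence 0.568 (the proportion in the motivating cohort)
and split between enamel and dentin classes. Sex and age are drawn
independently of abundance, so covariate adjustment should be a no-op on
average.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error, chimeric/misassembled contigs,
strain mixtures within a genome, compositional coupling beyond the softmax
normalization, shared-environment correlation of caries status within
pairs, and genuinely confounded covariates.

**KO annotations.** Each genome carries a KO set; the ground-truth MCR
table is computed with the *same* evaluator the analysis stage uses, so
annotation tests exercise label plumbing, while the evaluator itself is
validated separately against brute-force truth tables.

## Genome binning

Canonical k-mers (512 features at k = 5; the lexicographic minimum of each
k-mer and its reverse complement) are counted per contig; windows touching
non-ACGT characters are skipped. Counts are CLR-transformed,
log(x + pc) − row mean, with pseudocount 1 count (rows sum to zero; the
transform is row-scale-invariant in the pc → 0 limit). Canonical counting
is used because assembly strand is arbitrary; the full 1,024-feature
variant is a parameter away.

**Seeding.** Contigs ≥ 2,500 nt are embedded in 2-D (PCA by default; the
embedding function is pluggable, so t-SNE/UMAP can be dropped in) and
clustered density-based (DBSCAN) with a data-driven radius — three times
the median distance to the `min_cluster_size`-th neighbor (default
min_cluster_size 10). Clusters below the minimum size and density outliers
stay unassigned. This replaces manual visual bin identification with a
reproducible procedure.

**Signatures.** Each bin is summarized by the leading right singular
vector of its contigs' profile matrix in coverage space and in CLR k-mer
space — the PC1 of the *uncentered* second-moment matrix, which for a
coherent bin approximates its normalized mean profile. This is a
deliberate choice: the PC1 of the *centered* covariance is the within-bin
scatter direction, which for a pure bin's k-mer profiles is essentially
noise (measured explained-variance fraction ≈ 0.06 on the three-genome
fixture) and correlates with nothing; recruitment against it assigns zero
contigs, while the uncentered representative recruits the entire candidate
set at purity 1.0. `center=True` is available for analyses of within-bin
variance structure. Signatures are unit-norm with the largest-magnitude
entry positive; degenerate bins (one contig, zero spread) fall back to the
normalized mean profile and are flagged.

**Recruitment and iteration.** Each 300–2,500 nt candidate is scored
against each bin by the unweighted mean of two Pearson correlations —
coverage profile vs. pc1_coverage and CLR k-mer profile vs. pc1_kmer. The
merge rule is not dictated by the binning literature; the unweighted mean
treats both information sources equally and is the simplest symmetric
choice. A candidate joins its argmax bin if the score reaches r_min
(default 0.5); each bin accepts at most top_n = 500 recruits per
iteration (the cap is per iteration, not cumulative), highest scores
first, ties broken lexicographically by contig id. Signatures are then
recomputed on the merged bins and recruitment repeats until fewer than 1%
of assignments change or 10 iterations elapse ("convergence" is otherwise
unspecified in this family of methods; both knobs are configurable).
Excluded contigs (e.g. a lineage with promiscuous k-mer usage set aside by
the analyst, as oral *Streptococcus* typically is) never enter clustering
or recruitment.

## Abundance

TPM adapted to contigs: rate_ij = count_ij / (length_j/1000), rescaled so
each subject's rates sum to 10⁶. Counts-based rates were chosen over
per-base depth; with uniform read length the two differ by a constant that
TPM's renormalization cancels. Bin abundance is the sum of member-contig
TPM; unassigned contigs pool into an `unbinned` column so the per-subject
total is conserved exactly. Standardization is proportion → log →
per-feature z-score, with pseudocount 1e−4 added before the log when zeros
are present and the sample (n−1) standard deviation (the mainstream
statistics-stack default; both configurable). Zero-variance features are
dropped with a warning rather than propagating NaNs.

## Functional potential

The module grammar: top-level space-separated tokens are steps (all
required); within a step, commas separate alternatives (OR), `+` joins
obligatory complex subunits (AND), spaces inside parentheses are AND,
`-`-prefixed components and `--` gap markers are optional and ignored
(their treatment by upstream completion evaluators is not documented; a
step consisting only of optional parts counts as complete). MCR is
completed steps / total steps — monotone in the KO set and exhaustively
checked against truth tables. PBFP is the plain matrix product A = X·C
with strict bin-label alignment; X is the TPM-summed abundance matrix, not
the z-scored one, so A inherits nonnegativity and linearity.

## Cohort statistics

Effect size is the mean of log₂((a + pc)/(b + pc)) over all cross-cohort
pairs (antisymmetric; within-cohort pairs excluded; twin co-membership is
ignored, a known non-independence of the cross pairs). Significance is
the two-sided Mann–Whitney U: exact null distribution when both groups
have ≤ 8 observations, tie-corrected normal approximation otherwise;
fully tied data report p = 1 with a warning. No multiplicity correction is
applied by default (an inclusive screen at α = 0.05; Benjamini–Hochberg
can be layered on by the caller). Shannon entropy uses base 2 (bounded by
log₂ of the feature count; the base is a parameter). KDE modes use a
Gaussian kernel with Scott's rule on a 512-point grid spanning the data
± 3 bandwidths; a constant sample returns that constant.

Enrichment contexts: (1) per-bin tests on abundance; (2) "anchored"
per-module tests on the full PBFP; (3) "unanchored" per-module tests on
the PBFP recomputed from only the context-1-significant bins. The
anchored ∩ unanchored module set is reported with Venn counts.

## Cooccurrence network

Spearman ρ between features after dropping those present in fewer than
10% of samples (presence judged on the raw abundances when the input is
z-scored). Adjacency is unsigned, a_ij = |ρ_ij|^β with zero diagonal;
β defaults to 1 because the network is consumed as a fully connected
weighted graph rather than thresholded into modules (6 is the conventional
soft-threshold default if module detection is the goal). TOM similarity:

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1

— the standard unsigned variant; the variant name is recorded in the
network output. Taxa are clustered by ward linkage on 1 − TOM. PageRank
(damping 0.85, L1 tolerance 1e−10) is computed by power iteration on the
row-normalized walk with uniform teleport and dangling-mass
redistribution; it sums to 1 and is invariant to global weight scaling,
and is cross-checked in tests against a direct linear-system solution.

## Twin ACE model

Features are pre-residualized against sex, age, and phenotype by OLS
(dummy-coded categoricals, minimum-norm least squares under collinearity
with a warning) and re-standardized; adjusting inside the likelihood would
also be defensible, but pre-residualization keeps the likelihood a pure
two-parameter problem. The likelihood is bivariate normal per pair with
unit variances and correlations r_MZ = a² + c², r_DZ = ½a² + c²,
maximized by SLSQP over the simplex (a², c² ≥ 0, a² + c² ≤ 1), started
from — and falling back to, if the optimizer fails — Falconer's moments
a² = 2(r_MZ − r_DZ), c² = r_MZ − a², e² = 1 − r_MZ, clipped to the simplex
and renormalized (boundary estimates are flagged). Intraclass correlations
use the pairwise double-entry estimator. Estimates always lie exactly on
the 2-simplex.

At the validation design point (500 MZ + 500 DZ pairs), a single feature's
estimate has Monte-Carlo standard error ≈ 0.075 on a², so parameter
recovery is assessed on the mean over 12 independent features simulated in
one cohort (standard error ≈ 0.022); components recover within ±0.05.
ADE/sex-limitation models and likelihood-based confidence intervals are
out of scope.

## Orchestration and determinism

One master seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn` in a fixed order, recorded in the run
manifest together with package version, parameters, and SHA-256 checksums
of every output; identical config + seed reproduces byte-identical
outputs. The bundled fixture (3 × 200 kb genomes, 10 twin pairs) runs all
stages in about a second; the validation suite's larger problems
(3 × 1 Mb binning mixture, 500 + 500-pair twin cohorts, 2,000-feature null
calibration) were sized to give stable statistics while keeping a full run
interactive on one CPU.

## Known limitations

- Recruitment accuracy for very short contigs degrades with shallow
  coverage designs (few subjects) since the coverage correlation carries
  most of the signal at that scale.
- The DBSCAN radius heuristic assumes seed clusters are denser than the
  between-cluster gaps; extremely unbalanced genome mixtures may need an
  explicit `eps`.
- The Mann–Whitney exact method is used for small samples even with ties
  (the tie-less null distribution); the asymptotic branch applies the
  usual tie correction.
- ACE assumes no dominance, no gene–environment interaction, equal
  environments across zygosity, and residualized-out covariates — the
  classical twin-model caveats apply.
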