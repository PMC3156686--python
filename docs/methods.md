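# Methods

`gwasnet` re-implements, as a tested pipeline on synthetic data with known
truth, an analysis strategy for dissecting conditionally expressed
quantitative traits in a structured panel of inbred accessions: mixed-model
genome-wide association, empirical-percentile significance with gene-level
aggregation, genomic hotspot scanning, cross-condition overlap testing, and
co-expression-network filtering of candidates against known "bait" genes.

## The synthetic study

The generator (`gwasnet.simulate`) emulates a panel of 96 fully inbred
*Arabidopsis*-like accessions drawn from 8 subpopulations, phenotyped in 4
replicate blocks under 2 contexts (control vs. treated, or two tissues),
with ~40 correlated metabolite-like traits.

**Genotypes.** Balding–Nichols draw: per SNP an ancestral frequency
p ~ U(0.1, 0.9); each subpopulation's frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) with F = `fst` (default 0.3); each accession draws a single
allele, so dosages are {0, 1} and heterozygotes never occur. SNPs with
minor-allele count < 2 are discarded and replaced, avoiding monomorphic
markers that would break the scan. A frequency-variance estimator with
finite-sample correction recovers the target F to within ±0.05 in the test
suite. No linkage-disequilibrium decay or recombination map is simulated:
SNPs are exchangeable given their subpopulation frequencies. Consequently
the hotspot clustering that LD produces in real data never arises here
except where planted.

**Annotation.** Genes of length 2 kb are tiled deterministically with 5 kb
gaps (gene *i* starts at 1 + i·7000, 1-based inclusive); 90% of SNPs are
re-placed uniformly inside a random gene's ±1 kb window, the rest in
intergenic space. Real gene-length and SNP-density heterogeneity is absent,
so per-gene window SNP counts are narrowly distributed — convenient for
testing criterion logic, unrepresentative of a real genome.

**Phenotypes.** Each trait is a sum of components following the nested
two-context ANOVA design: structure S, accession-within-structure A(S)
(planted causal-SNP effects plus a polygenic normal draw), context T,
replicate-within-context R(T), and the two interactions T:S and T:A(S),
plus i.i.d. residual noise. Every component is empirically standardized to
its target variance fraction **and orthogonalized to the nested design**
(accession values centered within subpopulation; interaction matrices
double-centered), so a sequential sums-of-squares decomposition recovers
the targets up to the fixed-effects noise floor (≈ df/N per term). Default
fractions — structure 0.12, accession 0.35, context 0.05, replicate 0.03,
T:S 0.02, T:A(S) 0.10, residual 0.33 — mirror the regime reported for
defense-metabolite panels: roughly a third of variance stably genetic,
structure ~10–15%, interaction with context ~10%, context-by-structure
small.

Context-specific causal effects are added to the second context only, with
the scale chosen so the interaction component meets the T:A(S) budget; the
accession main effect then absorbs an equal extra share (recorded in the
realized fractions the truth object reports). This construction makes the
planted SNP's marginal effect in the first context exactly zero.

The default planted architecture (`default_causal_spec`) is 10 causal
genes, two traits each, with per-allele effects of 2.5 polygenic standard
deviations — the major-effect-locus regime (AOP/MAM-like biosynthetic
polymorphisms) that dominates natural variation in this kind of pathway.
With weak polygenic-scale effects the desk-scale panel (hundreds to a few
thousand SNPs, ≤ 96 accessions) has essentially no single-SNP power, and a
passing pipeline would be untestable end to end.

**Co-expression.** A gene × gene correlation matrix with near-zero
background (N(0, 0.02) entries) and planted modules at a specified
correlation level (default 0.8 ± 0.05). Positive semi-definiteness is
enforced by eigenvalue clipping at 1e−8 followed by diagonal
renormalization; the clip moves within-module means by far less than the
test band [0.6, 0.9]. The matrix stands in for a transcriptome-wide
co-expression resource; at 300–600 genes the mutual-rank graph of the pure
background is already connected with diameter ~3 (rank thresholds are
scale-relative), which a 22k-gene resource would not be — see the distance
test below.

## Association scan

Genetic means per accession are least-squares estimates from the additive
accession + replicate-block model (sum-to-zero block coding), which equal
raw accession means in a balanced design and correct block bias under
missingness (no imputation; fits use available cells).

The scan is the EMMA scheme: y = Xβ + u + ε with u ~ N(0, σ²_g K), K the
identity-by-state allele-sharing matrix (diagonal exactly 1; ridge-repaired
if numerically non-PSD). K is eigendecomposed once; δ = σ²_e/σ²_g is
estimated by full maximum likelihood under the intercept-only null on a
100-point grid over ln δ ∈ [−10, 10] with bounded local refinement, then
reused for every SNP test of that trait (the "population parameters
previously determined" approximation; refitting per SNP would change
p-values marginally at ~100× the cost). Per-SNP tests are vectorized
2-parameter GLS fits in the eigenbasis with p from F(1, n−2). SNPs with
minor-allele count < 2 among phenotyped accessions are skipped (p = NaN)
and logged. With K = I the tests reduce to OLS exactly (verified to 1e−6);
under a structured null the genomic inflation factor is ~1.0 versus ~1.9
for naive OLS.

Significance is an empirical-percentile rule per trait: the threshold is
the k-th smallest p-value with k = ⌈qN⌉ (q = 0.001 at genome-wide SNP
counts, giving 230 of 229,940), and all SNPs with p ≤ threshold are
flagged, so ties err toward inclusion. The pipeline's desk-scale default is
q = 0.01: at 3,000 SNPs the genome-wide q would flag ~3 SNPs per trait and
the ≥2-SNPs-per-gene criterion would be vacuous; q = 0.01 keeps the
flagged-SNPs-per-gene-window regime comparable.

## Gene calling and recovery

SNPs map to every gene whose window [start − 1 kb, end + 1 kb] contains
them (1-based inclusive boundaries; overlapping windows map a SNP to
multiple genes). "Coding region" is the annotated gene span, as the
synthetic annotation has no exon structure. A gene-trait association is
called under `min1` (≥1 significant window SNP), `min2` (≥2), or `frac20`
(significant/total window SNPs ≥ 0.20, genes with zero window SNPs
uncalled). Recovery statistics score any boolean per-gene indicator —
including a printed table — against bait and validated gene sets; the
empirical false-negative rate is 1 − recovered/validated, a gene counting
as recovered if called for ≥ 1 trait.

Variance explained by candidates: a standardized-genotype GRM
G = ZZᵀ/m from the candidate SNPs, the polygenic model y = μ + g + ε with
g ~ N(0, σ²_g G) fitted by the same ML machinery, returning
σ²_g/(σ²_g + σ²_e). Monomorphic candidates are dropped; single-SNP or
non-PSD G is ridge-repaired (1e−6) and logged. Recovery of a true
candidate-SNP h² of 0.5 is unbiased to within ±0.02 with SD ≈ 0.09 at
n = 96 / 50 SNPs.

## Hotspots and overlap

Per-gene counts of called traits are smoothed by a 25-gene sliding mean in
genome order; windows never span chromosomes (physical adjacency is
chromosome-local). The null shuffles the observed per-gene counts across
genome positions (a permutation, preserving the count distribution),
recomputes all window means per replicate, and pools them over 1,000
replicates; the threshold is the pooled distribution's 95th percentile — a
single genome-wide line — and observed windows strictly above it are
flagged. Under exchangeable counts ~5% of windows are flagged; the
threshold's coefficient of variation over seeds is < 5% at 1,000
replicates. The pooled-percentile choice (rather than per-replicate maxima)
matches drawing one horizontal reference line; a maxima-based threshold
would be family-wise-error controlling and strictly higher.

Cross-dataset overlap treats a gene called for ≥ 1 trait as a dataset's
candidate. An exclusion set (e.g. genes inside known LD blocks around
large-effect loci, which co-associate without being causal) is removed from
all sets and the universe. Expected sector probabilities are products of
per-dataset marginal candidate frequencies; χ² sums over all 2³ membership
cells with df = 2³ − 1 − 3 = 4 since the marginals are estimated.

## Network filtering

Mutual rank: rank_a(b) is b's rank among a's partners by descending
correlation, self excluded, average ranks on ties;
MR = √(rank_a(b)·rank_b(a)), minimum 1 for a mutually top pair. Candidate
networks restrict nodes to GWA candidates plus bait genes, draw edges at
MR ≤ 15, and rank connected components by size (ties broken by
lexicographically smallest member) — relative component size, not a
significance rank, is the interest signal. Graphs export to Pajek .net
(quoted labels, 1-based ids, MR edge weights) and round-trip through the
package's own reader.

The distance test runs on the full (all-gene) network at the same
threshold: BFS shortest paths from every candidate and every control gene
to every bait gene, controls drawn uniformly without replacement from
non-candidate non-bait nodes, size-matched to the candidates by default.
Unreachable pairs are excluded (rank tests on mixed finite/infinite values
are ill-defined) and their fraction reported. A two-sided Wilcoxon rank-sum
test assesses location shift, an Ansari–Bradley test dispersion; both can
be repeated per pathway label. All candidate–bait pairs enter the
distributions (per-candidate minima available as an option). Because the
desk-scale background graph is connected with diameter ~3, distances
saturate quickly: the planted-signal validation therefore places all baits
and candidates in one module (so no cross-module pairs dilute the shift),
under which the rank-sum test rejects at p < 0.01 in ≥ 18/20 seeds while
staying calibrated (≤ α + 0.03) under a structureless matrix.

## Trait relationships

Trait trees use d = 1 − Spearman ρ across accessions (pairwise-complete;
constant traits excluded with a warning) and neighbor joining with negative
branch lengths clamped to zero. The 1 − ρ transform (rather than (1 − ρ)/2
or 1 − |ρ|) is the simplest distance consistent with rank correlation and
is invariant to monotone transforms of any trait; anti-correlated traits
land near distance 2, which NJ handles as an additive (non-metric-safe)
dissimilarity, as is standard for correlation-based trees.

## Pipeline

One YAML config drives all stages in dependency order (simulate → means →
varpart → gwa → call-genes → hotspots/overlap → network → distance-test);
each context plus the pooled data forms one GWA "dataset", so three-way
overlap testing falls out of a single run. Every stochastic stage has its
own named seed; reruns are byte-identical, and the manifest records seeds,
output SHA-256 hashes and per-stage summaries. Stage toggles are validated
against the dependency graph before anything runs. Exit codes: 0 success,
1 configuration/data error, 2 internal error.

## Problem sizes

Default pipeline run: 96 accessions, 3,000 SNPs, 600 genes, 10 traits,
2 contexts × 4 replicates — seconds on one CPU. Test-suite simulations use
96 accessions / 2,000 SNPs for scan calibration, 20 traits × 8 replicates
for variance-partition recovery, 200-gene layouts for hotspot checks and
300-gene matrices for network checks; these sizes give the Monte-Carlo
error the assertions assume while keeping the whole suite under a minute.

## Known limitations

- No LD, recombination or coalescent genealogy; hotspot structure exists
  only where planted.
- Fixed-effects η² partitioning inherits the classical upward noise bias
  of df/N per term; the generator's orthogonalization removes attribution
  bias but not this floor.
- The mutual-rank background graph is unrealistically dense relative to a
  transcriptome-scale resource (rank thresholds are scale-relative).
- Variance components use full ML (not REML), the classical EMMA
  formulation; σ²_g is biased low by O(1/n).
- Two contexts only; no third tissue/treatment level.
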