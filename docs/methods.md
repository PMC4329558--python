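# Methods

This note documents the statistical model behind `pathartp`, the
conventions and defaults it fixes where the method leaves choices open, and
what the synthetic-data calibration does and does not demonstrate.

## Data model and coordinates

Genotypes are minor-allele dosages in {0, 1, 2} with `nan` for missing
calls, stored densely (samples x SNPs). On load, every column is oriented so
it counts the minor allele, with the allele frequency computed on cases and
controls combined; ties at frequency 0.5 are left as read. Genomic
coordinates are 1-based inclusive (the PLINK `.bim` convention) everywhere.

## Quality control

Filters run in a fixed order, each with a strict inequality:

1. **sample completion** < 0.94 removes the sample — applied first, so all
   SNP statistics are computed on retained samples only;
2. **SNP call rate** < 0.90;
3. **MAF** < 0.05, cases and controls combined;
4. **Hardy-Weinberg** exact-test p < 1e-4, in controls only.

Each removed item records exactly one primary reason (the first filter it
fails), and the report's stage counts always sum back to the input counts.
Filtering is idempotent. The HWE test is the exact conditional test: given
the control allele counts, the probability of each possible heterozygote
count h is proportional to `2^h / (h! n_AA(h)! n_aa(h)!)`, and the two-sided
p-value sums the probabilities of all counts no more probable than the
observed one. The exact test was chosen over the chi-square approximation
because it remains calibrated at the rare-allele boundary where the MAF
filter operates, and is cheap at any realistic control count. Gender
discordance and duplicate-pair exclusions are accepted as a precomputed
sample exclusion list, not inferred.

## SNP-to-gene assignment

A SNP belongs to a gene when it lies on the same chromosome within the gene
body extended by 20 kb upstream and 10 kb downstream (defaults,
configurable), both ends inclusive, lower bound clipped at position 1.
Upstream/downstream are interpreted against the transcription direction:
for a minus-strand gene the 20 kb flank extends beyond the annotated end.
The asymmetric flank rule is only meaningful relative to transcription, but
since some pipelines apply it left/right regardless of strand,
`strand_aware=False` reproduces that behaviour. A SNP inside two genes'
windows is assigned to **both** genes: it contributes to each gene's ARTP
combination independently, but is counted once in the pathway SNP tally and
once in the SNP-level Bonferroni family. Pathway genes can be excluded by
name before mapping (e.g. X-chromosome members when sex-chromosome dosage
is out of scope), and genes left without SNPs after QC are dropped from the
analysis pathway and logged.

## Per-SNP association

The reported statistic is the Wald test from an unconditional logistic
regression of status on minor-allele dosage (additive model) plus
covariates, fitted by Newton/IRLS maximum likelihood (statsmodels), on
complete cases for that SNP. Odds ratios are per minor allele; the 95% CI
uses z = 1.959964. Categorical covariates (study, sex, age stratum) get
reference-level indicator encoding; a rank-deficient design is an error
rather than a silent drop. Degenerate fits (monomorphic dosage, one outcome
class, separation/non-convergence within 25 Newton iterations) return
flagged rows, never exceptions.

Population stratification is adjusted with principal components of the
standardized genotype matrix, `(g - 2f) / sqrt(2 f (1-f))` with missing
dosages mean-imputed; components are unit-norm sample eigenvectors ordered
by eigenvalue, with a deterministic sign convention. Outlier-removal
iterations and LD pruning before PCA are not implemented; the number of PCs
is a per-analysis configuration value.

## The permutation ensemble and the score-test fast path

Gene- and pathway-level inference shares one ensemble: a (B+1) x n_SNPs
matrix of per-SNP p-values, row 0 for the observed labels and rows 1..B for
case/control labels shuffled **within study strata** (preserving each
study's case/control ratio under the null). Inside the ensemble, per-SNP
p-values come from the Rao score test: with the covariates-only logistic
null fitted to give probabilities mu, the statistic is `U^2/V` with
`U = g'(y - mu)` and V the efficient score variance after projecting the
dosage on the covariates under weights `mu(1-mu)`; p from chi-square with
1 df. Missing dosages are mean-imputed inside this fast path only — a
documented, tolerance-tested discrepancy against the complete-case Wald
scan (Spearman correlation of the two p-value streams > 0.99 at n = 500).
Refitting the full per-SNP model 20,000 x n_SNPs times would buy nothing
asymptotically.

When the null design matrix is constant within each permutation stratum
(intercept-only, or study indicators with study-stratified shuffling), the
null fitted probabilities are invariant under relabeling, so the null model
and V are computed once and the whole ensemble reduces to one matrix
product. Otherwise the null logistic is refit per permutation with a small
dedicated IRLS (convergence: max |score| < 1e-8 or 25 iterations, with step
halving).

## ARTP conventions

With `S_j(b)` the negative log product of the j smallest p-values in row b:

* per-truncation estimated p: `#{b' : S_j(b') >= S_j(b)} / (B+1)`;
* adaptive statistic: `MinP(b) = min_j` of the above over the candidate set;
* adjusted p: `#{b : MinP(b) <= MinP(0)} / (B+1)`.

Ties count via >= / <= exactly as written, and the observed row is pooled
into the denominator. These conventions make the estimator floor exactly
`1/(B+1)` — attained precisely when the observed MinP is the unique strict
minimum — i.e. `5.00e-05` at B = 20,000. Candidate truncation sets default
to `{1, ..., min(L, 10)}` at gene level (L SNPs in the gene) and
`{1, ..., min(G, 10)}` at pathway level (G genes); both are configurable,
and a configured set is clipped to the unit's size. The cap at 10 bounds
compute for large genes while letting the adaptive minimum range from
"single best SNP" to "ten-SNP burden".

The pathway test is two-stage **on the same ensemble**: every row b is
converted into a per-gene estimated p (counting `MinP_g(b') <= MinP_g(b)`
over the pool), and the RTP/MinP machinery is applied across genes. The
gene-level adjusted p-values are the b = 0 entries of that intermediate
matrix, so gene and pathway results are mutually consistent by
construction. Leave-gene-out sensitivity analysis removes the named genes
*and every SNP mapped to them* (including SNPs shared with retained genes)
and recomputes the pathway statistic on the remaining ensemble columns —
other genes' p-values are untouched.

Everything is deterministic given the configured seed; for cohorts of at
most ~10 samples an exhaustive mode replaces random shuffles with all
`C(n, n_cases)` relabelings, which the test suite checks against an
independent brute-force enumeration for exact equality.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosages over pairwise-complete
observations, computed among controls (composite, phase-free LD). This was
chosen over EM-phased haplotype r² because it is deterministic and
phase-free, which is adequate for grouping significant SNPs into
independent signals by single-linkage clustering of the r² >= 0.8 graph
(the boundary value counts as linked). EM-based r² would be a natural
extension.

## Multiple testing and reporting

Bonferroni thresholds are exact quotients `fwer / family_size`, displayed
at 3 significant figures in scientific notation (round-half-even): 0.05 /
1421 = 3.52e-05, 0.05 / 72 = 6.94e-04, 0.05 / 69 = 7.25e-04. The SNP family
counts distinct SNPs (a double-mapped SNP once); the gene family counts
genes in the analysis pathway after exclusions and after dropping SNP-less
genes. Three flags are attached: nominal (gene/pathway p < 0.05), SNP
report cut (p < 0.001), and Bonferroni — all strict.

## Synthetic cohorts

The generator produces what the pipeline assumes, not human genomes:

* **Haplotype-Markov LD blocks.** Two haplotypes per individual, paired
  independently, so Hardy-Weinberg proportions hold by construction. Within
  a block, locus i+1 copies locus i with probability rho, else draws fresh;
  all SNPs in a block share the block's allele frequency (drawn once from
  the configured range), which keeps the copy mechanism marginal-preserving
  and gives allele correlation `rho^|i-j|` (dosage r² `rho^2|i-j|`). This
  was chosen over multivariate-normal thresholding for exact HWE and cheap
  sampling.
* **Retrospective phenotype.** Disease probability is
  `logistic(alpha + sum beta_s g_s + covariate terms + subpopulation
  offset)` with `beta_s = ln(OR_s)`; alpha is tuned by bisection so the
  expected case fraction matches the design, then cases and controls are
  sampled to exact per-study quotas from a virtual population (4x the
  cohort by default, doubling on shortfall). Case-control sampling of a
  logistic model biases only the intercept, so planted ORs remain the
  estimands of the logistic fit.
* **Stratification scenario.** Two subpopulations with per-SNP allele
  frequency divergence +/- delta and a subpopulation disease offset — the
  canonical confounding that genotype PCs should absorb.

What this does **not** emulate: realistic human LD maps and recombination,
allele-frequency spectra, genotyping batch artefacts, imputation
uncertainty, relatedness. Calibration results on these cohorts therefore
demonstrate the correctness of the statistics under the model's own
assumptions, not robustness to real-data pathologies.

## Calibration checks (computed by the test suite)

* Pathway- and gene-level type-I error at nominal 0.05 within the 95%
  binomial band [0.032, 0.072] over 500 null cohorts (n = 400, 10 genes x
  5 SNPs, B = 200).
* Planted OR 1.5 at n = 2000 + 2000: mean log-OR within 0.05 of ln 1.5 and
  Wald 95% CI coverage within [0.91, 0.98] over 200 replicates.
* Exact equality of gene and pathway ARTP with brute-force enumeration on
  the 70-relabeling, 8-sample fixture.
* Exact HWE p equal to rational-arithmetic enumeration for every genotype
  triple with total <= 30.
* Confounded two-subpopulation null: SNP-level rejection inflated without
  adjustment and restored to the nominal band by 2 PCs.

Problem sizes were picked so each property is measured with useful
precision at desk scale; they are the package's own test design, and larger
runs only sharpen the same comparisons.

## Known limitations

* The score test's mean imputation differs from the Wald scan's
  complete-case handling; at high missingness the two p-value streams can
  diverge more than the tested tolerance.
* PCA lacks EIGENSTRAT's outlier-removal iterations; extreme outliers can
  rotate leading components.
* No Firth correction: near-separated SNPs are flagged rather than
  penalised.
* The permutation ensemble is held in memory ((B+1) x n_SNPs doubles);
  B = 20,000 with ~1,500 SNPs needs ~250 MB, fine on a workstation but the
  matrix is not chunked.
* `leave_gene_out` reuses the original ensemble columns; this matches the
  sensitivity-analysis semantics but means the removed SNPs still
  influenced nothing beyond their own columns (no re-QC is performed).
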