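# Methods

This note documents the models, parameter choices, and numerical
decisions behind `genomerisk`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Demographic history

PSMC-format text is parsed from the final iteration block (`TR` →
scaled mutation parameter θ₀; `RS` lines → interval boundaries *t*ₖ in
units of 2*N*₀ generations and relative sizes λₖ). Rescaling to years
and diploid individuals requires a per-species generation time *g*
(years) and mutation rate μ (per site per generation); neither has a
universal value, so both are required inputs (the synthetic pipeline
uses a generic mammalian μ = 1 × 10⁻⁸ and *g* = 5 y). The input bin size
*s* defaults to 100, the conventional binning of the tool's input.

The harmonic mean of *N*ₑ over epochs older than 10 kya is
**duration-weighted in years**. PSMC's atomic intervals have unequal,
discretization-dependent durations, so an unweighted mean over intervals
would depend on an arbitrary grid; weighting by years makes the summary
invariant to splitting an epoch into sub-epochs of equal *N*ₑ (a tested
property). An unweighted variant is available behind `weighted=False`
for comparison. The open-ended oldest interval is truncated at its start
time and excluded: its *N*ₑ estimate has unbounded temporal support and
would otherwise dominate any duration weighting.

## Runs of homozygosity

Windowed heterozygosity (heterozygous biallelic SNVs / callable sites,
non-overlapping 50-kb windows by default) is fitted with a 1-D
two-component Gaussian mixture by EM. Numerical choices:

- initialization from the 10th-percentile split of the pooled ratios
  (the RoH mode sits in the low tail), making the fit deterministic;
- convergence when the log-likelihood improves by < 1e-8; the
  per-iteration log-likelihood trace is retained and its monotonicity is
  a tested invariant;
- a variance floor of 1e-8 × the data variance guards collapse onto a
  single point;
- the fit is flagged **degenerate** when the component means are closer
  than one pooled standard deviation; degenerate fits produce no RoH
  calls (fRoH = 0 with a warning) rather than arbitrary ones;
- hard assignment at posterior 0.5, with exact ties going to non-RoH;
- windows with less than 50% callable sequence are unassessed and enter
  neither the fRoH numerator nor denominator. The pooled 1-D
  distribution of ratios is the fitted quantity.

The Gaussian approximation needs tens of expected heterozygotes per
window. With very small windows or very low rates, RoH windows carry 0–2
counts, the low component collapses onto the zero spike, and fRoH is
underestimated; window size should be chosen so the background mode has
mean count ≳ 10 (at 50 kb and typical mammalian heterozygosity this is
comfortably satisfied).

## Genetic load

Derived substitutions are positions where the focal reference and a
coordinate-matched ancestral sequence carry distinct unambiguous bases;
N/ambiguity sites are skipped and counted. Consequences are classified
at the codon level with the standard genetic code: synonymous, missense,
or LOF ∈ {stop-gained, stop-lost, start-lost}. Only single-nucleotide
substitutions are modeled, so splice and frameshift classes are out of
scope by construction. Variants hitting several genes keep the most
severe consequence (LOF > missense > synonymous), ties resolved by
lexicographic gene id. For heterozygous variants the ALT allele is
treated as derived only when REF matches the ancestral base; other sites
are flagged unpolarized.

Load proportions use coding point mutations (synonymous + missense +
LOF) as the denominator, per zygosity and per IMPC viability class;
empty cells are reported as undefined (NaN), never as 0. The
conserved-site proportion uses a **strict** inequality at the phyloP
threshold 2.27 and scored sites as its denominator (both counts are
reported, since a genome-wide denominator is also defensible). Kurtosis
of scores at substitutions is the Pearson (non-excess) m₄/m₂² with
population moments — Normal data give 3 — with an `excess` flag.

## Phylogenetic statistics

`tree_to_covariance` gives C[i,j] = shared root-to-MRCA branch length;
trees are rooted at the first split (a stem edge would add a constant to
every entry and carry no contrast information).

**PGLS.** For fixed λ, V(λ) = λC + (1−λ)diag(C) and
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky solves; σ² is profiled by ML and λ̂
maximizes the profile likelihood on [0, 1] by bounded scalar
minimization (endpoints checked explicitly, since the bounded optimizer
approaches boundaries only asymptotically). Coefficient tests are t
with df = n − p using the bias-corrected σ̂². Rank-deficient designs
raise an error naming the aliased columns (pivoted QR).

**Phylogenetic logistic regression.** Point estimates are
Firth-penalized (Jeffreys prior), guaranteeing finiteness under
separation. Inference is by parametric bootstrap under a Brownian
threshold-liability null: liabilities ~ MVN(0, C/height), thresholded to
match the observed prevalence exactly, model refit, two-sided tail
probability of the Wald statistic reported with the (1+k)/(B+1)
estimator. This replaces the Ives–Garland estimating equations with a
fully specifiable procedure whose size is directly testable (the null
rejection rate at α = 0.05 sits in the binomial band over 200 simulated
datasets). The null simulates a *fully* Brownian liability; when the
real outcome is less phylogenetically structured than BM the test is
conservative, which is the safe direction for comparative claims.

**Ordinal regression** is a proportional-odds cumulative-logit ML fit
(cutpoints parameterized as first cutpoint plus positive increments,
enforcing order). It ignores the tree by design; phylogenetic structure
is absorbed by taxonomic-order dummy columns supplied in the design
matrix. With two observed categories it collapses to binary logistic
regression (tested to 1e-6). Unobserved categories get probability 0.

**PC regression** median-imputes, z-scores, and eigendecomposes the
feature correlation matrix; retained scores (≤ min(n−1, p)) enter a
Firth logistic regression on the binary outcome. Median imputation here
is descriptive and deliberately simple; predictive imputation is the
random-forest module's job, where leakage matters.

## Risk prediction

The protocol is: stratified 75/25 train/test split; median imputation
fitted on training rows only (inside the CV folds as well, via the
pipeline); 5-fold cross-validated grid search over number of trees
{100, 300, 500}, maximum depth {3, 5, 10, ∞}, and features-per-split
{√p, 0.3p, 0.5p}, selecting by AUROC (robust to the class imbalance of
threat status); final refit on the full training set and AUROC on the
untouched test set. Splits are stratified because the threatened class
is a minority. Feature-set comparisons share a single split on the
common species subset so differences reflect features, not species.
Data-deficient species get forest vote fractions; a species missing an
entire feature group the model requires is refused rather than silently
imputed. An optional variance filter caps the number of window columns,
which otherwise swamp the forest with weakly informative features.

## Synthetic cohorts: what they emulate

The generator's defaults are the study conditions every end-to-end test
runs under, chosen once:

- 240 species on a pure-birth (Yule) tree, birth rate 1;
- log *N*ₑ Brownian with mean log 25,000 and SD 0.6, so harmonic-mean
  *N*ₑ spans roughly 8,000–80,000;
- load proportions = intercept + β·log*N*ₑ + BM noise (SD 0.02), with
  β = −0.05: smaller populations carry proportionally more missense and
  conserved-site substitutions (drift load). LOF-heterozygote proportion
  has slope 0 — that class shows no consistent *N*ₑ relationship;
- IMPC lethal-gene intercepts sit below viable-gene intercepts
  (0.35 vs 0.55), reflecting stronger purifying selection in essential
  genes;
- threat liability = −0.45·z(log *N*ₑ) + 0.6·z(eco) + BM residual,
  cut by quantiles to 35% threatened (NT/VU/EN/CR at 0.4/0.3/0.2/0.1 of
  the threatened mass; threatened = any category above LC). The
  ecological factor is deliberately the stronger predictor, so
  ecological-only models out-rank genomic-only models, with the combined
  model best — the ordering the real-data analyses report;
- phylogenetic signal λ = 0.5; 39 ecological columns with loadings
  0.3–0.8 on the latent factor and 10% missing-at-random cells; diet and
  taxonomic order assigned to whole clades so order-level factors have
  realistic structure.

Toy genomes plant every record they emit (substitutions with ancestral/
derived bases, heterozygous variants with consequence classes, RoH
tracts, conservation scores from the mixture 0.7·N(0,1) + 0.3·N(4,1),
whose conserved component puts ~96% of its mass above 2.27) and retain
them as ground truth, so reader/caller round trips are exact-equality
tests. Coordinates follow each format's convention: VCF 1-based, BED
0-based half-open, GFF3 1-based closed; internal coordinates are 0-based
half-open.

What passing these tests does **not** show: real genomes have assembly
gaps correlated with repeats, reference bias in variant calls,
alignment-dependent ancestral reconstruction error, intron/splice
structure, recombination-rate variation shaping RoH lengths, and
non-Yule, fossil-calibrated phylogenies. The synthetic cohort tests the
statistical machinery, not those data pathologies.

## Problem sizes

Tests run the stated experiments at these sizes: PGLS recovery with 500
Brownian replicates at 200 tips; logistic calibration with 200 datasets
of 100 tips at 200 bootstrap draws; the end-to-end direction check with
20 seeds of 240 species at the trait level (the per-species genome stage
is exercised separately on megabase-scale toy genomes, where windows
hold enough heterozygotes for the mixture to be well-posed); generator
round trips over 50 seeds. The acceptance script uses the default
240-species cohort with the full hyperparameter grid and 500 bootstrap
draws, plus a 3-Mb measured genome.

## Known limitations

- The phylogenetic logistic bootstrap fixes the liability's
  phylogenetic structure at full BM rather than estimating it; see
  above for the direction of the resulting conservatism.
- Ordinal fits drop unobserved categories from the likelihood; sparse
  extreme categories (CR) in small cohorts can make order-dummy designs
  ill-conditioned, in which case the pipeline logs and skips the
  ordinal stage rather than failing the run.
- The consequence annotator handles single-nucleotide changes on
  arbitrary multi-interval CDS models, but no isoform resolution: one
  gene model per gene id.
- *N*ₑ/*N*c uses point census estimates; no uncertainty propagation.
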