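# Methods

This note documents the statistical model, the algorithms, the
synthetic-data generator and the numerical choices behind `gbsimpute`,
in the spirit of the methods documentation of packages like msprime or
statsmodels: what is computed, under which assumptions, and where the
design was genuinely open.

## Genotype likelihoods, posteriors and dosages

At a biallelic SNP, the observed data for individual *d* at site *v*
are the allele counts X = (n_A, n_B) taken from the VCF AD subfield
(allele A = REF, allele B = ALT). Conditional on genotype
g ∈ {AA, AB, BB} and a fixed per-read error rate *e*, each read is an
independent Bernoulli draw of allele B with probability

    p_B = e (g = AA),  0.5 (g = AB),  1 − e (g = BB),

so the likelihood is the binomial pmf
C(n_A+n_B, n_B)·(1−p_B)^{n_A}·p_B^{n_B}. Assumptions: reads are
independent given the genotype, the error rate is symmetric
(A→B as likely as B→A) and shared across sites and individuals, and
mapping/alignment artifacts are not modelled. GT/DP/GQ/PL subfields of
input VCFs are deliberately ignored so likelihoods are always computed
consistently from AD.

Posteriors use a uniform prior over the three genotypes by default
(`posterior_triple` accepts any prior, but the pipeline never supplies
one); the genotype **dosage** is the posterior mean count of allele B,
0·P(AA) + 1·P(AB) + 2·P(BB) ∈ [0, 2]. An entry is *missing* iff its
total depth is zero — there is no separate no-call state — in which
case the likelihood triple is flat and the dosage is NA.

Numerics: likelihoods are evaluated in log space (log-gamma for the
binomial coefficient) so depths in the thousands do not underflow;
tests pin agreement with naive arithmetic to 1e−12 relative for counts
up to 20 and binomial normalization at fixed depth to the same
tolerance. Phred-scaled values are PL_g = −10·log10(L_g / max L),
rounded to nearest integer with ties up and capped at 255 — the cap
only ever binds for exactly-zero likelihoods, whose ratio is infinite.
Internal computation always keeps full precision; rounding happens only
at the VCF boundary.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `e` (ErrorModel) | 0.01 | per-read sequencing error probability; (0, 0.5) |
| Caller A `min_depth` | 7 reads | minimum total depth for a validation genotype |
| Caller B `ratio` | 10 | required likelihood ratio best/second-best genotype |
| `n_folds` | 10 | masking cross-validation folds |
| `min_L` | 30 | minimum masked genotypes per site-fold record for site summaries |
| `k_markers` | 60 | preselected predictors per target site |
| `n_lambda` | 10 | penalty values on the λ path |
| `cv_folds` | 5 | inner CV folds for λ selection |
| `lambda_min_ratio` | 0.01 | λ_min / λ_max of the path |
| `max_missing` (site filter) | 0.9 | drop sites with > 90 % zero-depth individuals |

The defaults for e, the callers, folds, min_L, k_markers, n_lambda and
cv_folds are the method's canonical operating point; all are exposed
because other datasets (deeper assays, different error profiles) will
want different trade-offs.

## LASSO imputation

The imputer treats each target site as a regression problem on other
markers of the same chromosome, ignoring marker order and distance: it
models statistical correlation only, and succeeds exactly insofar as
the sample carries LD (from linkage, family structure, or breeding
history).

Procedure, per site with missing entries:

1. **Initialization.** Every missing dosage on the chromosome is set to
   its site mean (a site with no observed genotype at all is filled
   with the overall mean and flagged — it carries no signal).
2. **Preselection.** All other sites are ranked by |Pearson r| with the
   target, computed on the mean-filled matrix, and the top 60 kept.
   Mean-filling (rather than pairwise-complete correlation) keeps a
   fixed n for every pair; zero-variance sites are excluded, ties break
   toward the smaller site index so the ranking is deterministic.
3. **Fit.** Rows are restricted to individuals with an *observed*
   target dosage (predictor values at those rows may still be
   mean-filled). Predictors are standardized; the L1-penalized least
   squares path runs over 10 log-spaced λ values from λ_max — the
   smallest penalty with all coefficients zero, max_j |⟨standardized
   x_j, centered y⟩|/n — down to λ_max/100. λ is chosen by minimum
   mean squared error in 5-fold CV (ties go to the larger λ, i.e. the
   sparser model). Coefficients are returned on the original scale.
4. **Prediction.** Missing entries are predicted from the mean-filled
   predictor values and clipped to [0, 2]. Observed entries are never
   modified; the procedure is a single pass (no re-impute/refit
   iteration).

λ is expressed on the per-observation objective (1/2n)·RSS + λ·Σ|β|,
the convention of glmnet and scikit-learn, under which the λ_max
formula above is exact. The coordinate-descent path solver is
scikit-learn's `lasso_path` with its default duality-gap tolerance
1e−4, which the tests rely on for the OLS limit (an exact affine signal
is recovered to 1e−3 at tiny λ). Selection uses the minimum-CV-error
rule, not the 1-SE rule. Reference-panel individuals enter as
additional training rows — the model has no explicit reference-panel
concept, matching how a regression imputer actually consumes extra
individuals. Sites are processed independently: each fit reads only
observed or mean-filled values, never another site's imputations, so
processing order cannot affect the output. The only randomness is the
inner CV fold assignment; per-site generators are derived from
(seed, site index), making results reproducible and independent of
which sites happen to need imputation.

Degenerate inputs: a constant target or no usable predictor yields an
intercept-only model (the site mean); fewer observed individuals than
CV folds triggers a logged fallback to mean imputation rather than an
abort.

## Masking cross-validation

Validation genotypes are observed entries confident enough to act as
truth: Caller A keeps entries surveyed at least 7 times; Caller B keeps
entries whose best genotype is ≥ 10× as likely as the second best
(computed on raw likelihoods; zero-depth entries have flat likelihoods
and can never qualify). The validation dosage is the posterior-mean
dosage, not a hard 0/1/2 call — accuracy is defined on dosages
throughout the pipeline, and hard-calling would discard the calibrated
uncertainty the likelihood model provides.

The validation set is permuted uniformly at random and dealt
round-robin into 10 disjoint folds (sizes within 1). Per fold, exactly
those coordinates are set missing, the matrix is re-imputed, and the
sample Pearson r between validation and imputed dosages is recorded per
site and per individual together with L, the number of masked
genotypes at that unit. r is undefined (NaN) when L < 2 or either
vector is invariant; per-unit accuracy is the median of *defined* r
values across folds, and units with no defined fold are reported as
not-estimable rather than dropped, so every exclusion is countable.
Site-level summaries first drop records with L < 30, where r estimates
are dominated by sampling noise; individual-level summaries apply no L
filter (individuals accumulate masked genotypes across thousands of
sites, so their L is rarely small — the filter is a site-level device).

Because accuracy is measured against *observed* dosages rather than
unknowable true genotypes, it underestimates true accuracy: the
observed dosage carries its own sampling and sequencing noise, and it
uses only single-individual information while the imputer pools the
sample.

Supporting analyses: MAF is estimated as min(p̂, 1−p̂) with p̂ = mean
observed dosage / 2 (the minor allele may be REF or ALT); binned
summaries use left-open right-closed bins over a fixed covariate range
(e.g. MAF bins (0, 0.1], …, (0.4, 0.5]), with values at or below the
lower edge falling outside all bins and empty bins reported rather than
erroring. The realized additive relationship matrix is the VanRaden
form A = WWᵀ / (2Σp_k(1−p_k)) on mean-imputed dosages after dropping
sites with > 50 % missing data; mean imputation stands in for model-
based dosage imputation here because the matrix serves QC/structure
exploration, not prediction. A `freqs` argument supplies
base-population allele frequencies, against which pedigree expectations
(full sibs: 0.5) are defined; by default the sample's own frequencies
are used, which slightly deflates within-family values when the sample
is dominated by close relatives. PCA is the eigen-decomposition of A
with scores scaled by √eigenvalue and a deterministic sign convention
(largest-magnitude loading positive).

## The synthetic-data generator

The generator produces populations with the structural features the
analysis assumes, at desk scale. The default preset: 200 founders, 134
crosses among 82 parents with 8 offspring each (1072 progeny — so the
study sample holds full sibs, half sibs and unrelated pairs), 2000
biallelic SNPs on one 30 Mbp chromosome, mean read depth 4, error rate
0.01.

* **Site-frequency spectrum.** Allele-B frequencies are Beta(0.3, 1.7)
  draws — mean 0.15, strongly overrepresenting low-frequency variants,
  the hallmark of sequencing-discovered (as opposed to array-
  ascertained) markers.
* **Founder LD.** Each founder haplotype is a mosaic of k ancestral
  haplotypes with a geometric switch process (probability 0.008 per
  site; mean segment 125 sites ≈ 1.9 Mb), k = 6 by default. Sites on a
  shared segment co-inherit their ancestral source, giving LD that
  decays with distance; k and the segment length were calibrated so a
  faithful implementation of the imputer reproduces the qualitative
  accuracy regime of real breeding-program GBS data (site-level
  accuracy high for common variants and bimodal overall,
  individual-level accuracy well above site-level; adjacent-site r²
  median ≈ 0.14). A small k also makes founders weakly related
  (F ≈ 1/k), as breeding-program founders are.
* **Meiosis.** Gametes carry Poisson(genetic length) crossovers, 1
  Morgan by default, at positions uniform on the genetic map (taken
  proportional to physical position).
* **Read depth.** D ~ Poisson(λ · s_d · r_v) with unit-mean Gamma
  multipliers per individual (shape 4) and per site (shape 2); the
  small site shape gives the long-tailed per-site depth distribution
  characteristic of restriction-enzyme GBS libraries without modelling
  fragments explicitly. D = 0 entries are the missing data; at λ·s·r =
  1 the zero class is e^−1 ≈ 37 %. A `fixed` depth option supports
  deep-genotyping calibration tests.
* **Reads.** Given depth and true genotype, N_B ~ Binomial(D, p_B(g))
  with exactly the p_B of the inference likelihood. This
  generative/inference symmetry is deliberate (standard
  simulation-based-calibration practice): posterior dosages provably
  converge to true genotypes as depth grows, making
  parameter-recovery tests well-posed.

What the generator does **not** emulate: alignment and variant-calling
artifacts, allelic mapping bias, batch effects, multi-generation
pedigrees, ascertainment of markers, and any quantitatively fitted LD
or depth distribution — the preset is shape-matched, not fitted, to
real data. Passing tests therefore demonstrate correctness and
qualitative behaviour of the *method*, not expected accuracy on any
particular real dataset.

All stages draw from independently spawned seed streams (founders,
crossing plan, meiosis, reads; partitioning and inner CV likewise), so
each stage is separately reproducible and two runs from one seed are
byte-identical.

## Evaluation scale and runtime

The full default-preset experiment (2000 sites × 1272 individuals,
Caller B ≈ 1.0 M validation genotypes, 10 folds, ≈ 20 000 per-site
LASSO fits) runs in about five minutes on one CPU; the problem sizes
were chosen as the smallest at which the qualitative accuracy patterns
(accuracy vs. MAF, vs. missingness, site- vs. individual-level) are
stable across seeds. Smaller configurations in the test suite exercise
every code path in seconds.

## Known limitations

* The error model is a single symmetric per-read rate; base-quality-
  aware or per-read error models are out of scope.
* Multi-allelic sites, indels and structural variants are rejected at
  the VCF boundary; only biallelic SNPs are handled.
* The Beagle bridge is file-level only: it writes GL/PL inputs, emits
  the command line and parses DS/GP output, but never runs or models
  Beagle itself (documented external defaults: five burn-in plus five
  sampling iterations, four sampled haplotype pairs).
* `pearson_r` is the plain sample correlation; no Fisher-z intervals
  or shrinkage are applied to small-L records beyond the L filter.
* Mean imputation inside the relationship matrix biases A slightly
  toward zero for high-missingness data; for structure exploration
  (its purpose here) this is immaterial.
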