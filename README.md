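# gbsimpute

Genotype likelihoods, LASSO imputation and masking cross-validation for
low-depth genotyping-by-sequencing (GBS) data.

GBS and similar reduced-representation sequencing assays genotype many
individuals cheaply, at the cost of low, uneven read depth: at a typical
site many individuals have a handful of reads and some have none at all.
Downstream analyses (GWAS, genomic selection) need complete dosage
matrices, so missing genotypes must be imputed, and the imputation must
be *evaluated* — on data where the truth is never observed directly.
`gbsimpute` is a toolkit for that workflow, aimed at breeding programs
and population geneticists working with non-model species:

* **Genotype likelihoods from allelic depths.** For observed allele
  counts (n_A, n_B) at a biallelic SNP and a per-read error rate *e*,
  the likelihood of genotype *g* ∈ {AA, AB, BB} is binomial,

      P(n_A, n_B | g, e) = C(n_A + n_B, n_B) · (1 − p_B)^{n_A} · p_B^{n_B},
      p_B = e (AA), 0.5 (AB), 1 − e (BB),

  with a uniform genotype prior giving posterior probabilities and the
  posterior-mean **dosage** in [0, 2]. Zero depth means missing (NA).
* **LASSO imputation (`impute_matrix`).** Each site with missing
  entries is regressed on the 60 markers most correlated with it, with
  an L1 penalty: β̂ = argmin Σᵢ(yᵢ − β₀ − Σⱼxᵢⱼβⱼ)² + λΣⱼ|βⱼ|. Missing
  genotypes are initialized to site means, λ is chosen by 5-fold
  cross-validation over 10 log-spaced penalty values, and predictions
  are clipped to [0, 2]. Reference-panel individuals can be pooled in
  as extra training rows.
* **Masking cross-validation (`run_cv`).** High-confidence *validation
  genotypes* — depth ≥ 7 (Caller A) or best genotype ≥ 10× more likely
  than the runner-up (Caller B) — are split into 10 disjoint folds;
  each fold is masked, re-imputed, and scored with the sample Pearson
  correlation r between observed and imputed dosages, per site and per
  individual, summarized as the median over folds. Site summaries drop
  fold records with fewer than 30 masked genotypes.
* **Synthetic GBS populations (`synth_gbs`).** A founder panel with a
  rare-variant-skewed site-frequency spectrum and mosaic-haplotype LD,
  one generation of crosses giving large full-sib families, and a
  Poisson–Gamma read-depth model whose error process mirrors the
  inference likelihood exactly.
* **Side analyses**: MAF estimation, binned accuracy summaries, the
  VanRaden realized additive relationship matrix and its PCA, and a
  file-level bridge that prepares inputs for (and parses dosages from)
  external Beagle v.4.

## Worked example

Likelihoods for one genotype observation — 3 reference and 5 alternate
reads, e = 0.01:

```python
import numpy as np
from gbsimpute import (ErrorModel, genotype_likelihoods, posterior_triple,
                       dosage_from_posterior, phred_normalize)

L = genotype_likelihoods(3, 5, ErrorModel(e=0.01))
print("likelihoods (AA, AB, BB):", np.round(L, 6))
P = posterior_triple(L)
print("dosage:", round(float(dosage_from_posterior(P)), 4))
print("PL:", phred_normalize(L))
```

```
likelihoods (AA, AB, BB): [0.0000e+00 2.1875e-01 5.3000e-05]
dosage: 1.0002
PL: [76  0 36]
```

The data overwhelmingly favor the heterozygote (dosage ≈ 1; PL of 0 for
AB), as expected for a roughly balanced read split.

A small end-to-end experiment — simulate a population (40 founders, 20
crosses, 100 offspring, 300 sites, mean depth 4), then run Caller B +
10-fold masking cross-validation with the LASSO imputer:

```python
from gbsimpute import synth_gbs, eval_cv

cfg = synth_gbs.breeding_program_preset(
    seed=7, n_founders=40, n_parents=16, n_crosses=20,
    offspring_per_cross=5, n_sites=300)
ds = synth_gbs.generate_dataset(cfg)
res = eval_cv.run_cv(ds.adm, caller="B", n_folds=10, min_L=5, seed=7)
print(res.summary)
```

```
n_validation: 17019
median_per_site_r: 0.43631805975983945
median_per_individual_r: 0.9237840913854966
n_sites_estimable: 220
n_sites_excluded_small_L: 948
```

Per-individual accuracy (0.92) far exceeds per-site accuracy (0.44):
each individual is scored across many mostly-common sites, while the
per-site median is dragged down by rare variants, which are inherently
hard to impute. The MAF-binned means from the same run show that
directly:

```
 bin_left  bin_right   n  mean  median
      0.0        0.1 124 0.247   0.276
      0.1        0.2  30 0.578   0.828
      0.2        0.3  25 0.770   0.788
      0.3        0.4  21 0.730   0.783
      0.4        0.5  20 0.653   0.756
```

The same pipeline is available from the shell:

```bash
gbsimpute simulate --seed 7 --out-dir synthetic
gbsimpute evaluate --input-vcf synthetic/study.vcf --folds 10 --seed 7 \
    --out-dir run1   # writes per_site.tsv, per_individual.tsv, bins, summary
```

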