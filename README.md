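# credset

Statistical fine-mapping of GWAS association signals with functional
priors, plus the two companion analyses used to validate a localized
regulatory variant: allele-specific chromatin accessibility testing and
covariate-adjusted cis-eQTL modelling.

## Who this is for

A common situation in complex-trait genetics: a disease-associated
locus contains dozens of highly correlated variants, and genetic
evidence alone cannot say which one is causal. `credset` implements
the standard desk workflow for narrowing such a signal:

1. **Fine-mapping.** For each variant of a signal, Wakefield's
   approximate Bayes factor is computed from its z-score (or beta and
   standard error). With shrinkage ratio r = W/(V+W),

       ABF = sqrt(1 − r) · exp(z²·r/2),

   where V is the sampling variance of the effect estimate and W the
   prior effect-size variance. Under a single-causal-variant
   assumption the posterior causal probability of variant *j* is
   π_j = prior_j·ABF_j / Σ_k prior_k·ABF_k, and the **99% credible
   set** is the smallest set of variants whose π sum to ≥ 0.99.
2. **Functional priors.** Binary chromatin annotations — one column
   per (cell type, state) from chromatin-state segmentations, plus
   derived *stretch enhancers* (merged active-enhancer runs > 3 kb) —
   are tested for enrichment among causal variants across many
   signals with a hierarchical model: within each signal,
   prior_j ∝ exp(Σ_a γ_a·A_ja). Annotations are chosen by greedy
   forward selection, a ridge penalty by cross-validation over
   signals, and the model pruned by backward elimination. The fitted
   γ reweight a target signal's posteriors, typically shrinking its
   credible set.
3. **Allelic imbalance.** At heterozygous variants inside accessible
   chromatin, reads carrying each allele should split 50:50. Counts
   are pooled over heterozygote samples (a variant is testable with
   ≥ 5 reads in each of ≥ 3 het samples) and tested with an exact
   two-sided binomial test; direction is reported relative to the
   designated risk allele.
4. **cis-eQTL.** OLS of expression on dosage with covariates (age,
   sex, …), under either a 100 kb cis window or a 1 Mb TSS flank,
   with library-size scaling, a low-expression filter and a
   rank-based inverse-normal transform as preprocessing, and an
   analytic power calculator (noncentral chi-square with
   NCP = n·β²·2·maf·(1−maf)).

Because the consortium-scale inputs such analyses consume are not
redistributable, the package ships a first-class synthetic-data
generator (`credset.simulate`) that produces every input with known
ground truth — causal indices, true log-enrichments, true allelic
ratios, true eQTL betas — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from credset import (SimConfig, simulate_signals, finemap_signals, ABFConfig,
                     AnnotationEnrichment, FitConfig, PowerSpec, eqtl_power)

cfg = SimConfig(n_signals=200, seed=7)           # one ln(4)-enriched annotation
stats, annotations, truth = simulate_signals(cfg)
posteriors, credsets = finemap_signals(stats, ABFConfig(W=25.0))
print(f"mean 99% credible-set size: {np.mean([len(c) for c in credsets.values()]):.2f}")

results = AnnotationEnrichment(posteriors, annotations, FitConfig()).fit()
print(results.summary())

target = posteriors[posteriors.signal_id == "signal_000"].reset_index(drop=True)
rw, cs = results.reweight(target, annotations, ABFConfig(W=25.0))
print(f"signal_000: baseline set {len(credsets['signal_000'])} -> reweighted {len(cs)} variants")
print(f"power = {eqtl_power(PowerSpec(100, 0.3, 0.5, 0.05)):.4f}")
```

prints

```
mean 99% credible-set size: 7.20
Annotation enrichment model
==============================================
signals:               200
penalty (lambda):      0.05
log-likelihood:        1500.16
CV log-likelihood:     1499.75
----------------------------------------------
annotation                      log-enrichment
A0                                      1.3552
signal_000: baseline set 46 -> reweighted 36 variants
power = 0.8998
```

The fitted log-enrichment 1.355 recovers the generator's true value
ln 4 ≈ 1.386; the reweighted credible set of the (here, diffuse)
first signal shrinks from 46 to 36 variants because the annotation
carries real information about causal placement. The power value is
the probability of detecting a 0.5 SD-per-allele effect at MAF 0.3
with n = 100 at α = 0.05.

Note on W: when only z-scores are supplied, V = 1 and W is a prior
variance **on the z scale** — here 25 (prior z-SD 5, matching the
simulated causal z mean). For beta/se input the conventional
W = 0.04 (prior SD 0.2 on the log-odds scale) is the default.

A command-line interface mirrors the library:

```sh
credset sim --seed 1 --out-dir work
credset finemap --summary work/summary_stats.tsv -W 25 --out work
credset enrich --posteriors work/posteriors.tsv --annotations work/annotations.tsv --out work
credset imbalance --counts work/allele_counts.tsv --variants work/summary_stats.tsv --out work/imbalance.tsv
credset eqtl --expression work/expression.tsv --genotypes work/genotypes.vcf \
        --covariates work/covariates.tsv --window tss1mb --out work/eqtl.tsv
credset power --n 100 --maf 0.3 --beta 0.5 --alpha 0.05
credset run --seed 1 --out-dir work        # the whole pipeline + report
```

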