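# Methods

This note documents the statistical models implemented in `credset`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Fine-mapping model

Each association signal is assumed to harbour exactly one causal
variant. For variant *j* with effect estimate β̂_j and sampling
variance V_j (z_j = β̂_j/√V_j), the approximate Bayes factor under a
Gaussian effect prior N(0, W) is, with r = W/(V+W),

    ABF_j = √(1−r) · exp(z_j²·r/2).

Posterior causal probabilities are π_j ∝ prior_j·ABF_j, normalised
within the signal; the level-α credible set is the shortest prefix of
variants ordered by descending π whose cumulative probability reaches
α (ties broken by chromosome, position, then variant id, so output is
deterministic; a cumulative sum exactly at the level is included).

All Bayes-factor and posterior arithmetic is done in log space with
log-sum-exp normalisation, so z-scores in the hundreds cannot
overflow, and the ABF is validated against numerical quadrature of
∫N(β̂; β, V)·N(β; 0, W)dβ / N(β̂; 0, V) to a relative tolerance of
1e-6.

**Choice of W.** With beta/se input, V = se² and the default
W = 0.04 (prior SD 0.2 on the log-odds scale) is the conventional
choice for binary-trait GWAS. With z-only input V = 1, so W becomes a
prior variance on the *z scale* and must be of order the expected
squared causal z-score; the synthetic study design centres causal
z-scores at 5, so all z-scale analyses here use W = 25 (prior z-SD
5). Using the log-odds default on the z scale would make all Bayes
factors ≈ 1 and every credible set span the whole signal. W is a
constructor argument everywhere.

## Annotation model and selection procedure

Binary annotations A (variant × annotation) enter a multinomial-
logistic prior within each signal: prior_j ∝ exp(Σ_a γ_a·A_ja).
Integrating over the unknown causal variant, each signal contributes

    log Σ_j prior_j · ABF_j

to the marginal log-likelihood; the fitted objective subtracts a
ridge penalty λ‖γ‖². The gradient is the difference between the
ABF-weighted and the prior-only softmax expectations of A, so the
objective is smooth and is maximised with L-BFGS-B (gradient norm
tolerance 1e-8, |γ| capped at 30 — prior odds of e³⁰ are effectively
infinite and the cap only prevents numerical drift in the
no-penalty, perfectly-separable corner). Correctness of the
optimiser is asserted against a 1-D grid-search oracle, not against
a specific algorithm.

The selection procedure has three stages:

1. **Forward selection**: greedily add the annotation with the
   largest log-likelihood gain, refitting jointly after each
   addition, until the best gain falls below `forward_tolerance`
   (default 2 log-units, an AIC-like rule: under the null the gain is
   asymptotically χ²₁/2, so the per-annotation false-inclusion rate
   is ≈ 4.6%, measured at ≈ 6% at 400 signals). Ties go to the
   earlier column, so duplicated annotations select exactly one copy.
   By default forward selection is unpenalized; `penalize_forward`
   applies the first grid λ during selection instead.
2. **Penalty selection**: k-fold cross-validation over *signals*
   (signals are the independent units; default 10 folds). For each λ
   in the grid {0.01, 0.05, 0.1, 0.25, 0.5, 1} the model is fitted on
   k−1 folds and scored by unpenalized held-out log-likelihood; the
   best λ wins, with ties going to the larger (more shrinkage).
   Fold assignment is a deterministic function of the seed and the
   sorted signal ids only, so shuffling input rows cannot change it.
3. **Backward elimination** at the selected λ: iteratively drop the
   annotation whose removal most increases the cross-validation
   likelihood, stopping when no removal helps; then refit on all
   signals.

Reweighting a target signal replaces the flat prior with
prior_j ∝ exp(Σ γ_a A_ja) and renormalises. With γ = 0 (or an empty
model) the computation reduces to the identical floating-point path
as the flat-prior posterior, so baseline results are reproduced
bitwise. An option exists to exclude the target signal from the
enrichment fit (leave-one-out) before reweighting it; the default
fits on all signals.

## Stretch enhancers and annotation matrices

Chromatin-state segmentations are BED-style 0-based half-open
intervals labelled with a state and a cell type. Adjacent or
book-ended same-state records are merged before any length test, so
stretch-enhancer calls are invariant to how a segmentation tool
fragments a run. A stretch enhancer is a merged active-enhancer
(EnhA) run strictly longer than 3,000 bp. Variants are 1-based
(VCF convention): position p overlaps [start, end) iff
start < p ≤ end; indels are anchored at their 1-based start
position only. Stretch columns are appended alongside the per-state
columns by default (`stretch="replace"` substitutes them for EnhA,
`"none"` omits them).

## Allelic imbalance

A variant is testable when at least `min_het_samples` (default 3)
heterozygote samples each carry at least `min_reads` (default 5)
reads at the variant base; an alternative pooled reading (total
reads ≥ threshold across ≥ 3 covered het samples) is selectable
because the retention rule's phrasing is ambiguous in common usage.
Counts from passing samples are pooled and tested against
Binomial(n, 0.5) with the exact two-sided convention that sums the
probabilities of all outcomes no more likely than the one observed
(`scipy.stats.binomtest`); a double-one-sided variant capped at 1 is
available. The test is exact, hence conservative on discrete
totals; with pooled depths of several hundred reads the null
rejection rate at α = 0.05 is within Monte-Carlo error of nominal.
Direction is `risk_lower` when the risk allele has the smaller
pooled count. Indels are excluded by default since their allelic
read assignment is unreliable; mapping-bias correction is assumed
to have happened upstream and is out of scope.

## cis-eQTL model

For each (feature, variant) pair within the chosen window — 100 kb
around the feature anchor, or 1 Mb either side of the TSS, both
boundaries inclusive, chromosome equality required — expression is
regressed on dosage with an intercept and any supplied covariates
(OLS via statsmodels; validated against a from-scratch
normal-equations solver to 1e-10). The dosage term's two-sided t
p-value is reported; an exact fit reports p at the smallest positive
float. Collinear designs are rejected with the offending column
named. Preprocessing utilities follow common eQTL practice:
library-size scaling to a fixed total, removal of features with
values < 1 in strictly more than 20% of samples, and a per-feature
rank-based inverse-normal transform mapping rank r of n to
Φ⁻¹((r−0.5)/n) with average ranks for ties. Hidden-factor inference
(PEER and similar) is not implemented; any precomputed covariate
table can be passed instead. The only built-in multiplicity option
is a per-feature Bonferroni column, off by default.

**Power.** The single-variant power calculation uses a noncentral
chi-square with 1 df and NCP = n·β²·2·maf·(1−maf), β in
phenotype-SD units per allele. Under this convention a β of 0.15 at
MAF 0.15 and α = 2.5e-7 has essentially no power at n = 186 or 600;
published power figures for such designs evidently use a different
(unstated) effect-size convention, so they are not comparable and
the implementation is validated against its own Monte-Carlo oracle
(n = 100, maf = 0.3, β = 0.5, α = 0.05 → 0.90) instead.

## Synthetic-data generator

The generator's defaults describe one fixed study design: 49
association signals × 50 variants; one binary annotation hit with
frequency 0.1 and true log-enrichment ln 4; causal z ~ N(5, 1) and
null z ~ N(0, 1); 12 cell types segmented into EnhA/EnhWk/TssA/Quies
with exponential segment lengths (mean 1.8 kb, floor 200 bp, optional
cap) over a 200 kb region; 23 heterozygote samples with
Poisson(20) read depth and a true allelic ratio of 0.3 on the risk
allele; and an eQTL cohort of 174 individuals at MAF 0.15 with a
0.15 SD-per-allele effect plus age (0.02 SD/year) and sex (0.5 SD)
covariate effects on unit-variance noise. Every operation draws
from its own seeded substream, so datasets are reproducible
individually and jointly.

What it deliberately does **not** emulate: linkage disequilibrium
(an optional AR(1) correlation on null z-scores, default off, is a
stress-test knob, not an LD model), read-level sequencing artefacts
or mapping bias, genotype uncertainty/imputation, expression count
overdispersion, or the correlation structure of real chromatin
states across cell types. Passing tests therefore demonstrate the
statistical machinery is correct under its stated assumptions, not
that those assumptions hold in any particular real dataset; in
particular, with strong LD the single-causal credible set covers a
haplotype, not a variant, and coverage claims apply to the signal's
representative.

Simulation sizes used by the test suite and the acceptance script —
2,000 signals for coverage, 50 replicates of 400 signals for
enrichment recovery, 1,000 signals for shrinkage, 2,000 variants/
regressions for the null calibrations, 500 replicates for
effect-size bias — were chosen to make Monte-Carlo error small
relative to each property's tolerance while keeping a full run in
the minutes range on one CPU.

## Numerical and design choices

- All probability arithmetic in log space; posteriors via
  log-sum-exp; posterior sums asserted to 1e-12.
- Credible-set boundary uses ≥ level; deterministic tie-breaks.
- The forward-selection tie epsilon (1e-12 log-units) only guards
  against floating-point ties; scientific ties resolve to the
  earlier column.
- Zero-depth allele-count rows are generated and must be survived by
  the filter (they are: depth 0 < 5 never counts toward retention).
- Empty enrichment models are first-class: they reproduce the
  baseline pipeline exactly and serialise/deserialise like any other.
- TSVs carry explicit headers and full-precision floats so every
  writer/reader pair round-trips losslessly; BED is 0-based
  half-open; VCF is 1-based with GT only.

## Known limitations

- Single-causal-variant assumption per signal; no conditional or
  multi-causal decomposition, no LD-matrix fine-mapping.
- Enrichment coefficients are maximum-penalized-likelihood point
  estimates; no standard errors or credible intervals are reported.
- The exact binomial imbalance test ignores overdispersion between
  heterozygote samples (no beta-binomial option).
- The eQTL module fits one pair at a time; it is not optimised for
  transcriptome-scale scans.
- The power calculator's convention is stated above; figures
  computed under other conventions are not comparable.
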