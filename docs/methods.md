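# Methods

`gdmomics` reimplements, over fully synthetic data with recorded ground
truth, an integrated epigenome-wide + transcriptome-wide case-control
analysis of gestational diabetes mellitus (GDM) in placental tissue: robust
sitewise/genewise association models, bump-hunting detection of
differentially methylated regions (DMRs), mixed-model validation of
pyrosequenced regions with effect-modification tests, permutation-based
methylation-expression correlation networks within a genomic window, and a
gene-ontology enrichment test whose null distribution corrects for the
non-random probe design of CpG arrays.

## The synthetic study

The generator emulates the structure of a matched birth-cohort study rather
than any particular dataset.

**Cohort.** `n_pairs` case-control pairs (default 10 at desk scale; the
emulated study design has 41). Within a pair, infant sex, maternal smoking
and ethnicity are identical and maternal age differs by at most 5 years;
pre-pregnancy BMI is matched closely. Samples are plated onto 12-sample
chips (6 rows x 2 columns); a mixing parameter (default 0.5) controls how
strongly plating order tracks ethnicity, so that batch and an error-prone
biological covariate are genuinely confounded — the situation surrogate
adjustment exists for.

**Genome layout.** Five 30-Mb autosome analogs plus X and Y. Genes are
scattered uniformly; ~35 % of genes receive a dense "CpG island" burst of
3-12 probes with 50-300 bp gaps near the TSS, the rest of the probes are
uniform background. This yields (a) the run structure bump hunting needs,
and (b) strong probe-count-per-gene imbalance (roughly 1-40 probes/gene),
the design bias the resampling enrichment null corrects. A 5-Mb window on
chr5 is the coordinated-regulation block (the MHC analog): its genes share a
latent per-sample co-regulation factor (sd 0.35 on log2 scale) and a common
expression down-shift in cases, while its methylation effects are scattered
and site-specific — coordinated expression, incoherent regional methylation.

**Methylation intensities.** Per-probe baseline betas are drawn from a
bimodal beta mixture. Injected GDM effects (site, region, block) shift the
case betas; out-of-range values are clipped into (0,1) and counted in the
truth ledger. Type II probe betas are compressed toward 0.5 (factor 0.8)
relative to type I, mimicking the two Infinium chemistries. Intensities are
`M = beta * total * exp(s/2 + e_M)`, `U = (1-beta) * total * exp(-s/2 + e_U)`
with log-normal channel noise (`noise_sd` 0.15) and a chip/row/column batch
shift `s` modulated by a per-probe loading. The multiplicative noise makes
beta-scale noise heteroscedastic (~`noise_sd * beta(1-beta) * sqrt(2)`,
largest mid-range) — the pattern that motivates sandwich standard errors.
Batch shifts must be probe-specific: a uniform per-sample shift is removed
exactly by quantile normalization, leaving nothing for surrogate estimation
to find; probe-specific position effects are also what real arrays show.

**Expression.** Probe-level intensities are additive on the log2 scale
(gene level + probe affinity + chip batch x gene loading + noise), with an
additive linear-scale background on top, so the preprocessing chain
(background subtraction, log2, quantile normalization, median polish) can
recover gene signal. Probes per gene follow 1 + Poisson(mean-1), default
mean 21.

**Term universe.** A rooted `is_a` DAG with log-normally skewed term
popularity (sizes from <20 to the full universe), three explicit tiny leaf
terms below the 20-gene floor, planted near-duplicate clusters (a leaf term
plus two children carrying 95 % of its genes), and an optional term whose
genes carry 10x probe density.

**What the generator does not emulate** (so what passing tests do not
show): bisulfite-conversion chemistry, dye bias, detection p-values,
copy-number artifacts, sex-chromosome dosage, cell-type composition, linkage
between neighboring probes' baseline methylation, and realistic GO topology
depth. Results on real arrays additionally depend on all of these.

## Preprocessing

Betas are `M/(M+U+100)`; the +100 offset regularizes low-intensity probes
and keeps beta < 1. Note that the offset attenuates beta-scale contrasts by
a factor `total/(total+100)` (~3 % at the default intensity scale): this is
a property of the published estimator itself, and the recovery tests bound
estimation error accordingly (|mean error| <= 0.005 on a +0.10 effect)
rather than expecting exact unbiasedness through the transform.

Quantile normalization forces every sample's intensity distribution onto
the cross-sample mean of order statistics (ties averaged); it is applied per
channel, globally over probe types (whether the original processing was
within-type is not determinable; global is the simpler default and the
within-type question only matters jointly with the type adjustment that
follows). Probe-type adjustment maps each sample's type II betas onto its
own type I empirical distribution by direct quantile mapping — rank-
preserving, type I untouched; this realizes the contract of model-based
beta-mixture normalization (distributional alignment of the two chemistries)
and is exactly testable; the function is the hook point if a three-state
beta-mixture EM is wanted. Probe filtering retains autosomal probes without
SNP-at-target or X-cross-hybridization flags, reporting removals per
criterion.

Expression background correction subtracts a per-sample 2.5th-percentile
baseline (floored at 1 before log2) — an order-preserving additive
background removal standing in for a convolution background model; the
contract downstream stages need (background removed, order preserved) is
identical. Median polish sweeps rows then columns (fixed order for
determinism, tolerance 1e-6, <= 20 iterations); the gene value is overall +
sample effect. qRT-PCR expression is delta-Ct (target minus GAPDH, replicate
Cts averaged first).

## Surrogate variables

The residual of the feature matrix on the full primary design (exposure
included, so exposure signal cannot leak into a surrogate) is decomposed
into up to `min(10, n/5)` sample-space components. The default decomposition
is the leading right singular vectors; a FastICA rotation of that subspace
is available (`method="ica"`, with PCA fallback on non-convergence) but is
not the default because at these sample sizes the ICA rotation splits a
single batch axis across components (measured max correlation with an
injected chip shift 0.71 vs 0.998 for the singular vectors) and the
confounder screen then misses it. Components are screened against chip, row,
column and ethnicity by a *permutation* one-way ANOVA (1999 label
permutations): ICA components are non-Gaussian by construction, and even
principal components of noise gave a mildly anti-conservative parametric F
(8 % null any-selection over 150 runs vs 5.3 % with the permutation
reference). Components with Benjamini-Hochberg q < 0.05 against any
confounder are selected; under the global null this selection has
family-wise error ~ alpha exactly (Simes), so "no false selections" is a
boundary property, not a conservative one.

## Association models

Each feature is fit by OLS on GDM + age + BMI + sex + smoking (+ selected
surrogates; ethnicity enters through the surrogates in the main models). The
design is shared across features, so coefficients and sandwich variances are
computed for all features in one pass; the implementation is checked against
statsmodels' per-feature HC estimators in the tests. The default sandwich is
**HC2 with a t reference on residual df**: on null synthetic data at n=82
(~20k features pooled), HC2+t rejects at 0.050, HC3+t at 0.042 (EWAS) /
0.039 (TWAS), HC0+t at 0.058; HC3, HC0 and a normal reference remain
options. Significance conventions follow the study design: alpha 0.001 for
methylation, 0.01 for expression (coding genes only by default). Matched
pairs are not modeled as pairs; matching factors are adjusted as covariates.

## Bump hunting

The threshold is the 99th percentile of |t| over all retained probes.
Candidates chain into a region while consecutive candidates are <= 500 bp
apart; in the default strict mode an intervening retained sub-threshold
probe breaks the run ("contiguous" read literally; a permissive mode chains
across). Runs are split at effect sign changes (a DMR is directionally
coherent) and summarized by the mean per-probe effect (`summary="area"`
gives the sum). Runs of >= 2 probes are regions; singletons are reported
separately as site-level hits. Validation candidates must have an unflagged
peak probe significant at 0.001 and are ranked by |summary effect|. The
implementation is equivalence-tested against a brute-force maximal-run
enumeration on 500 random instances.

## Regional mixed models

Pyrosequencing percent methylation is `100*C/(C+T)`. The regional model is
a linear mixed model on all CpG x sample observations with a random
intercept per sample and fixed adjustment for age, BMI, sex, smoking and
ethnicity, fit by REML; Wald 95 % CIs use a normal reference. A singular
random-intercept fit falls back to fixed-effects OLS with cluster-robust
(by sample) standard errors, flagged in the output. Effect modification is
a Wald test of the GDM x modifier interaction (modifiers dichotomized at the
discovery-cohort median), with stratum-specific effects reported; both
strata must contain >= 3 cases and >= 3 controls.

## Window correlation networks

Within a window (the block, by default), CpGs within a closed +/-10 kb
flank and genes with TSS strictly inside are selected. Spearman rho is the
Pearson correlation of average ranks; two-sided significance comes from
permuting the expression member of each pair with one shared permutation
stream per seed (edge p-values are independent of testing order), default
10,000 permutations (1000 at desk scale), and a permutation p of exactly 0
is floored at 1e-6. Benjamini-Hochberg FDR is applied separately within the
methylation-expression and co-expression families; the significant
co-expression network is truncated to the 100 strongest |rho|. Regional
methylation summaries collapse CpGs greedily left-to-right within 5 kb,
capping cluster width at 10 kb; every CpG lands in exactly one cluster.
Group difference profiles (unadjusted case-minus-control means per cluster
and per gene at its TSS) can be compared against the same profile over
random same-width autosomal control windows.

## Enrichment

Terms are restricted to 20-1500 annotated genes (annotation propagated up
the DAG; IC(t) = -log(annotated(t)/annotated(root))). Jiang-Conrath
distance is IC(a)+IC(b)-2 IC(MICA), scaled to similarity by 1/(1+d)
(a 1-min(1,d) scaling is available; the 0.7 cutoff applies to whichever is
configured); terms with identical propagated gene sets are assigned
distance 0 (each subsumes the other informationally) even when neither is a
DAG ancestor of the other. Pairs at similarity >= 0.7 are linked and each
connected component keeps its largest-annotation term (ties:
lexicographically smallest id).

The methylation arm maps significant CpGs to closest genes (distance 0
inside a gene body; ties to the smaller gene id) and compares each term's
odds ratio (Haldane-Anscombe 0.5 correction for zero cells, applied
identically to observed and null tables) against a null built by drawing the
same number of probes *without replacement* from the retained array,
re-mapping, and recomputing the OR; p = (#{OR_null >= OR_obs}+1)/(R+1)
(upper tail = enrichment, never exactly 0), default R = 10,000 (1000 at desk
scale). This corrects the design bias: probe-dense genes enter random CpG
sets more often, so the naive gene-level hypergeometric is anti-conservative
for terms whose genes carry many probes (measured: with a planted 10x
imbalance, hypergeometric false-positive rate ~1.0 at nominal 0.05 while the
resampling p stays uniform). The expression arm uses the exact one-sided
hypergeometric upper tail over the expression gene universe. Both arms are
BH-corrected.

## Pipeline

Stages (simulate, preprocess, surrogates, EWAS, TWAS, bumps, pyro
validation, window network, enrichment, recovery report) communicate only
through files in the run directory, each seeded by a child of the master
seed, so a rerun with the same configuration is bit-identical and any stage
can be rerun alone. The recovery report scores every stage against the
truth ledger (sensitivity, empirical FDR, region overlap). Desk-scale
defaults (10 pairs, 2500 probes, 300 genes, 1000 permutations/resamples)
complete in a few seconds on one CPU.

## Calibration battery

`gdmomics.calibration` measures the operating characteristics the tests
assert: null rejection rates at alpha 0.05 over ~2000 features (n = 41
pairs); permutation-p uniformity over 200 null pairs; sensitivity and bias
over 200 simulations of +0.10 effects at 20 of 300 probes with 40 pairs;
bump recovery over 100 simulations of a 5-probe +0.08 region; surrogate
variance removal (squared projection of the injected shift onto the selected
component span) and null selection over 300 noise runs; mixed-model bias and
coverage over 200 simulations of a -9 % regional effect at n = 80 with
random-intercept sd 3 % and residual sd 4 %; interaction power for +/-6 %
opposite-sign stratum effects; enrichment calibration over 150 random
significant sets; and window FDR over 50 null networks. Problem sizes keep
Monte-Carlo standard errors several-fold inside each tolerance while the
whole battery runs in about a minute.

## Known limitations

- The probe-type quantile mapping aligns distributions but, unlike a
  mixture-model fit, does not preserve a probe's absolute beta when the two
  type distributions differ for biological rather than technical reasons.
- The regional mixed model omits CpG fixed effects (the emulated analysis
  describes only a random intercept for sample); with CpGs of very
  different baselines the residual absorbs the CpG means, and on such data
  the random-intercept variance can hit zero, triggering the flagged
  cluster-robust fallback.
- The resampling enrichment null conditions on the significant-set *size*
  in probes, not on its chromosomal layout; spatial correlation of
  significant CpGs is not emulated or corrected.
- Quantile normalization slightly distorts case-control contrasts when many
  features shift in one direction; the zero-noise recovery tests quantify
  this at the percent level.
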