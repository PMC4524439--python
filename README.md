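# gdmomics

Integrated epigenome-wide and transcriptome-wide association analysis of
gestational diabetes mellitus (GDM) in placenta, reimplemented as a tested,
fully synthetic-data-driven pipeline.

The scientific setting: a matched case-control birth cohort measures
genome-wide DNA methylation (450K-style two-channel arrays) and gene
expression (transcriptome arrays) in placental tissue, asks which CpG sites,
regions and genes shift with GDM, whether methylation and expression are
coordinated within an immune-gene window (the MHC), and which biological
processes the changes are enriched for. This package implements every
statistical step of that analysis and a synthetic-study generator with a
recorded ground-truth ledger, so sensitivity, bias, type-I error and FDR of
each stage can be measured rather than assumed. It is aimed at
epigenetics/statistical-genomics researchers who want the analysis machinery
with verifiable operating characteristics, without any data download.

## Methods at a glance

- **Beta values** β = M/(M + U + 100) from methylated/unmethylated channel
  intensities, after per-channel quantile normalization; type II probes
  quantile-mapped onto the type I distribution; analysis restricted to
  autosomal probes without SNP-at-target or X-cross-hybridization flags.
- **Association models** (EWAS per CpG, TWAS per gene): OLS of the feature
  on GDM + maternal age + pre-pregnancy BMI + infant sex + smoking +
  data-driven surrogate variables, with sandwich (heteroscedasticity-
  consistent, HC2 default) standard errors and Wald t tests;
  α = 0.001 (methylation), 0.01 (expression).
- **Surrogate variables**: sample-space components of the design-residualized
  feature matrix, screened against chip/row/column/ethnicity by permutation
  ANOVA, selected at BH q < 0.05.
- **Bump hunting**: DMRs as maximal runs of probes with |t| above the 99th
  genome-wide percentile and inter-probe gaps ≤ 500 bp, summarized by mean
  effect; brute-force-equivalence tested.
- **Regional validation**: percent methylation 100·C/(C+T) from
  pyrosequencing counts; linear mixed model with a random intercept per
  sample; GDM × modifier interaction Wald tests.
- **Window networks**: Spearman correlations of every CpG within ±10 kb of
  the window with every gene inside it (and all gene pairs), significance by
  10,000 permutations (p = 0 imputed as 1e−6), BH FDR per edge family;
  methylation collapsed over 5 kb clusters capped at 10 kb width.
- **GO enrichment**: terms with 20–1500 genes, de-redundified by
  Jiang–Conrath similarity (d = IC(a)+IC(b)−2·IC(MICA), sim = 1/(1+d),
  cutoff 0.7, largest term kept per cluster); methylation arm tested against
  a resampling null (significant-set-sized probe draws mapped to closest
  genes, odds-ratio tail over 10,000 resamples) that corrects the array's
  probe-count-per-gene design bias; expression arm by exact hypergeometric
  tail; q-values by Benjamini–Hochberg.

## Worked example

The numbered drivers under `analysis/` run the study end to end at desk
scale (10 matched pairs, 2500 probes, 300 genes) and write all tables under
`results/run/`:

```bash
cd analysis
python 01_simulate.py --seed 1          # cohort, intensities, truth ledger
python 02_preprocess.py --seed 1        # betas + gene-level expression
python 03_surrogates.py --seed 1
python 04_association.py --seed 1       # EWAS + TWAS
python 05_bumps_and_pyro.py --seed 1    # DMRs + mixed-model validation
python 06_window_network.py --seed 1
python 07_enrichment_and_report.py --seed 1
```

With seed 1 this prints, among other lines:

```
cohort: 20 samples (10 GDM cases), 2 chips
injected CpG effects: 30; regions: 2
meth: 1 surrogate(s) selected; strongest association: component 0 vs chip (q=0.032)
EWAS: 25 probes at alpha=0.001; top hit cg0001136 (effect +0.122)
TWAS: 16 genes at alpha=0.01; top hit G0016 (effect -1.16 log2)
1 DMRs above the 99% |t| threshold
  region chr1:7120519-7120877: regional effect +10.42% (95% CI +1.16, +19.69), mixed
methylation-expression edges at q<0.05: 2
recovery[ewas]: sensitivity=0.4473684210526316, fdr=0.32
```

Reading this: the generator injected 30 site effects and 2 regions; the
surrogate screen found the (deliberately confounded) chip axis; the EWAS
top hit is a +0.122 beta-scale increase in cases; one injected region was
re-detected by bump hunting, and its simulated pyrosequencing reads give a
+10.4 percentage-point regional effect under the mixed model, consistent
with the injected +0.08 beta shift. Sensitivity is limited at 10 pairs by
design — the calibration battery (below) measures it at the full 40-pair
scale, where site sensitivity reaches ~1.0. The same pipeline is available
as a CLI (`gdmomics run-all --seed 1 --run-dir results/run`, with per-stage
verbs `simulate`, `preprocess`, `ewas`, `twas`, `bumps`, `network`,
`enrich`, `report`) and rerunning with the same seed is bit-identical.

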