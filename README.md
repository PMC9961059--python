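# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` implements a complete two-sample Mendelian randomization (MR)
analysis for epidemiologists working from published GWAS summary
statistics: the motivating application is estimating the causal effect
of fine particulate air pollution (PM2.5, per SD) on gestational
diabetes mellitus (GDM), where the exposure GWAS (n = 423,796) and the
binary-outcome GWAS (6,033 cases / 123,000 controls) come from separate
cohorts and only per-SNP association tables are available.

The package covers every stage of that workflow as a tested library:

- **instrument selection** — p-value screen (default p < 1e-5), greedy
  LD clumping (r² = 0.001 within 10,000 kb), offline exclusion lists
  for phenome-screen hits, proxy lookup (r² ≥ 0.8), per-SNP F
  statistics and total variance explained;
- **harmonization** — expressing exposure and outcome effects on the
  same effect allele, with strand-complement resolution and the
  MAF < 0.3 frequency rule for palindromic (A/T, C/G) variants;
- **five causal estimators** — IVW, MR-Egger, weighted median, and
  weighted/simple mode;
- **sensitivity diagnostics** — Cochran's Q and I², the Egger
  intercept (directional pleiotropy), leave-one-out, and the tables
  behind forest and funnel plots;
- **multivariable MR** (MVMR-IVW) for direct effects adjusted for
  correlated exposures such as BMI and smoking;
- **binary-outcome power** (non-centrality approximation) and minimum
  detectable OR;
- **a synthetic-data generator** producing two-sample summary datasets
  with known causal effect, instrument strengths, planted palindromes,
  swapped allele codings and optional pleiotropy, so the whole pipeline
  is testable without any data download.

## The statistics

For SNP j, let γ̂ⱼ (SE σ_{Xj}) be its effect on the exposure and Γ̂ⱼ
(SE σ_{Yj}) its effect on the outcome after harmonization. The per-SNP
Wald ratio is b̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE sⱼ = σ_{Yj}/|γ̂ⱼ|.

- **IVW**: weighted regression of Γ̂ on γ̂ through the origin with
  weights σ_{Yj}⁻², i.e. β̂ = Σwⱼγ̂ⱼΓ̂ⱼ / Σwⱼγ̂ⱼ²; multiplicative
  random effects scale the SE by max(1, σ̂) on J−1 df.
- **MR-Egger**: the same regression with a free intercept after
  orienting γ̂ⱼ ≥ 0; the intercept estimates the mean directional
  pleiotropic effect, inference on t(J−2).
- **Weighted median**: the 50th weighted percentile of the b̂ⱼ
  (mid-cumulative convention), SE by parametric bootstrap.
- **Mode estimators**: argmax of a Gaussian-kernel density of the b̂ⱼ
  with Silverman-type bandwidth, inverse-variance (weighted) or uniform
  (simple) point masses.
- **Cochran's Q** = Σ sⱼ⁻²(b̂ⱼ − β̂)², χ²(J−1) under homogeneity.
- **Power** (binary outcome): Φ(|ln OR|·√(n·R²·p(1−p)) − z_{1−α/2}).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (all outputs land under `results/`):

```sh
python analysis/01_simulate_gwas.py     # two-sample GWAS with known truth
python analysis/02_run_mr_pipeline.py   # selection → harmonization → MR
python analysis/03_mvmr.py              # multivariable adjustment
python analysis/04_power.py             # power curve
```

With the generating truth being a causal log-OR of 0.551 (OR 1.735) and
85 instruments explaining 5.85% of exposure variance, step 02 prints:

```
instruments: 85 passed p-threshold → 82 after clumping → 79 harmonized (3 dropped)
         method  n_snp     beta       se       or   ci_low  ci_high       pvalue
            IVW     79 0.526549 0.028158 1.693080 1.602172 1.789146 4.978592e-78
       MR-Egger     79 0.379081 0.127075 1.460941 1.138850 1.874125 3.820289e-03
Weighted median     79 0.509340 0.040345 1.664193 1.537664 1.801133 1.547483e-36
  Weighted mode     79 0.494700 0.100691 1.640006 1.346285 1.997810 8.967737e-07
    Simple mode     79 0.520720 0.104514 1.683239 1.371461 2.065895 6.283066e-07
Cochran's Q p = 0.474; Egger intercept p = 0.238; power = 100%
```

Reading this: three SNPs in the planted LD block are clumped away and
three intermediate-frequency palindromes are dropped in harmonization;
all five estimators recover the true OR within their confidence
intervals; Q finds no heterogeneity and the Egger intercept no
directional pleiotropy (none was planted); and at the realized
instrument strength the binary-outcome design has essentially full
power. Step 03 shows univariable IVW inflated to 0.649 by a shared
genetic pathway while MVMR recovers the direct effects (0.488 and 0.258
vs true 0.55 and 0.20), and step 04 puts the minimum detectable OR at
80% power at 1.165.

To analyse real summary statistics instead, point
`tsmr.pipeline.PipelineConfig` at your own TSV files (one row per SNP:
rsid, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue,
n; `column_map` handles other headers) and call `run_pipeline`.

## Layout

- `src/tsmr/` — the library (`summary_io`, `instruments`, `harmonize`,
  `estimators`, `sensitivity`, `mvmr`, `power`, `synthdata`,
  `pipeline`)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — modelling assumptions, numerical choices and
  known limitations
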