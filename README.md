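# ildsc

Interaction-LD score regression (i-LDSC): heritability estimation from GWAS
summary statistics that accounts for pairwise *cis*-interaction variance
tagged by additive effect estimates.

The regression model is

```
E[chi^2_j] = intercept + ell_j * tau + f_j * theta
```

where `ell_j` is the familiar additive LD score of variant *j* (windowed sum
of squared correlations with its neighbours) and `f_j` is the
*cis*-interaction LD score: the sum of squared correlations between the
variant's genotype and the element-wise products of that genotype with each
window neighbour.  A significantly positive `theta` indicates pairwise
interaction variance recovered by additive summary statistics; `tau + theta`
is the interaction-aware heritability estimate.

## Package layout

| module            | contents |
|-------------------|----------|
| `ildsc.genio`     | PLINK 1 bed/bim/fam reader/writer, genotype standardization, summary-statistic and score-table I/O |
| `ildsc.scores`    | additive and cis-interaction LD scores over SNP/kb/cM windows, MAF-alpha weighting, small-sample bias correction, brute-force oracles |
| `ildsc.regress`   | iteratively re-weighted chi^2 regression, block-jackknife SEs and theta test, stratified (multi-annotation) fits, model averaging across window sizes |
| `ildsc.simulate`  | Gaussian-copula AR(1) genotype panels (optionally with haplotype-block LD), hub/partner interaction maps, polygenic/GxE/GxAncestry/sparse trait generators, marginal GWAS, closed-form additive-variance oracle |
| `ildsc.replicate` | embedded 25-trait biobank result tables and their cross-table correlation / range statistics |

## CLI

```bash
# compute scores from a PLINK panel
ildsc scores --bfile panel --win-snps 5,10,25,50 --ell-cm 1.0 \
      --alpha -1.0 --min-maf 0.01 --out scores.tsv

# fit the regression
ildsc regress --sumstats sumstats.tsv --scores scores.tsv --window 50 \
      --n-blocks 200 --out fit.json

# model averaging over window sizes
ildsc regress --sumstats sumstats.tsv --scores scores.tsv \
      --windows 5,10,25,50 --model-average --out fit.json

# simulate a synthetic trait + GWAS
ildsc simulate --synthetic 2000,2000,0.9 --h2 0.6 --rho 0.5 \
      --group1 0.1 --win-kb 10 --seed 1 --out trait.tsv,sumstats.tsv

# recompute the embedded-table statistics
ildsc replicate --out fig4.json
```

## Conventions worth knowing

- Genotype columns are standardized with the divide-by-N variance
  convention; missing calls are mean-imputed per column.
- Interaction pairs are counted once per focal variant, so `M = sum_j M_j`
  counts each unordered pair twice; regressors are pre-scaled by `N/J` and
  `N/M` so fitted coefficients sit directly on the variance-explained scale.
- MAF weighting uses `(2 p q)^(1 + alpha)` per neighbour, normalised to unit
  mean (`alpha = -1` is unweighted; a `schoech_exponent=False` flag switches
  to the `1 - alpha` convention).
- The self pair (a variant interacting with itself) is excluded from `f` by
  default (`include_self=True` to change).
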