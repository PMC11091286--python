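# mrmediate

Two-sample Mendelian randomization (MR) and two-step mediation analysis
from GWAS summary statistics, with a ground-truth synthetic generator for
testing every stage of the pipeline.

## Who this is for

Genetic epidemiologists asking: does an exposure causally affect an
outcome, and how much of that effect runs through an intermediate trait?
The motivating analysis is intrahepatic cholestasis of pregnancy (ICP)
and cardiovascular outcomes, with blood lipids as candidate mediators;
the machinery is generic to any summary-statistic MR study.

## What it computes

Given per-SNP association summaries (beta, SE, allele frequency) from an
exposure GWAS and an outcome GWAS, each instrument j yields a Wald ratio
θ_j = Γ_j/γ_j. The package pools them with the standard estimators:

- **IVW** — β̂ = Σw_jθ_j / Σw_j with w_j = 1/se(θ_j)², multiplicative
  random effects by default;
- **MR-Egger** — weighted regression with intercept (the intercept tests
  directional pleiotropy);
- **weighted median** and **weighted mode** — robust to up to 50% / a
  minority of invalid instruments, bootstrap SEs;
- **multivariable IVW** — conditional direct effects of several exposures.

Around the estimates: instrument selection (P < 5e-8, LD clumping,
F ≥ 10, risk-locus blocklist), allele harmonization (strand flips,
frequency-resolved palindromes), Cochran's Q, MR-PRESSO outlier
detection, leave-one-out influence, reverse MR, and two-step mediation

    IE = βa·βb,  DE = TE − IE,  prop = IE/TE

with delta-method (Sobel) uncertainty. See `docs/methods.md` for the
full model description.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_mediation_chain.py` simulates an
exposure → mediator → outcome chain with βa = 0.3, βb = 0.4 and direct
effect 0.05, then recovers the decomposition:

```
total effect (IVW): 0.1632 +/- 0.0179 (truth 0.17)
beta_a = 0.2751 (truth 0.30), beta_b = 0.4008 (truth 0.40, exposure-adjusted MVMR)
IE = 0.1103, DE = 0.0530, TE = 0.1632 (IE + DE = TE exactly)
proportion mediated = 0.676 +/- 0.088 (truth 0.706); indirect-effect p = 3.82e-46
passes the P < 0.05 screen: True
```

The total effect 0.163 estimates the implied truth
direct + βa·βb = 0.05 + 0.12 = 0.17; the proportion mediated 0.676 ± 0.088
covers the generating value 0.12/0.17 ≈ 0.706; and the identity
IE + DE = TE holds exactly in every emitted result.

The orchestrated study (selection → harmonization → four estimators →
sensitivity suite → reverse MR) runs from a YAML config:

```bash
mrmediate run examples/icp_like_study.yaml --out-dir scratch/study
```

which prints, for the packaged ICP-like synthetic config (true OR 1.004):

```
         method  beta    or     or_95ci      pval  n_snp
            ivw 0.005 1.005 1.002-1.008     0.002     11
    egger_slope 0.004 1.004 0.999-1.009     0.133     11
weighted_median 0.005 1.005 1.002-1.009 9.017E-04     11
  weighted_mode 0.006 1.006 1.002-1.009 4.977E-04     11
```

together with heterogeneity, MR-PRESSO, leave-one-out and
reverse-direction blocks (here: no reverse instruments, as expected for
a one-way causal simulation).

Two small published reference tables ship with the package
(`mrmediate.datasets`): the 11-SNP ICP instrument table and the
mediation-effect decompositions for the lipid/blood-pressure mediators.

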