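# usualintake

Estimation of **usual dietary intake distributions** for daily-consumed
nutrients, and a Monte-Carlo harness for evaluating the estimators.

Short-term dietary measurements such as repeated 24-hour recalls mix two
sources of variation: true differences between people and day-to-day noise
within a person. Reading population percentiles straight off observed
two-day means overstates the spread of *usual* (long-term average) intake;
the statistical task is to strip the within-person variance out before
computing percentiles. This package is for nutrition researchers and
biostatisticians who want transparent, reproducible implementations of
three widely used estimators of this kind, plus the machinery to study
their bias on synthetic data.

## The model

Intakes are modelled on a Box-Cox transformed scale. With
`g(x) = (x^λ − 1)/λ` (and `g = log` at λ = 0),

```
g(x_ij) = y_ij,   y_ij = b_i + ε_ij,
b_i  ~ N(μ, σu²)      (person-level usual intake, transformed scale)
ε_ij ~ N(0, σε²)      (day-to-day noise, j = 1..k days)
```

A person's usual intake on the original scale integrates the noise out:

```
U(b) = E[ g⁻¹(b + ε) ],   ε ~ N(0, σε²),
```

evaluated by Gauss–Hermite quadrature (for λ = 1/r with integer r the
integrand is a degree-r polynomial and the quadrature is exact). The
percentile p of the usual-intake distribution is `U(μ + z_p·σu)`; the mean
back-transforms μ over the total variance σu² + σε².

Three estimators of the distribution from data are provided:

* **SPADE-style** (`estimate_spade`): free maximum-likelihood λ, one-way
  ANOVA variance components, direct quadrature back-transform of the
  transformed-scale percentiles.
* **NCI-style** (`estimate_nci`): same first stages, then simulates k
  pseudo-persons from `N(μ̂, σ̂u²)` and back-transforms each with a fixed
  9-node rule; mean and percentiles are read off the simulated sample.
* **MSM-style** (`estimate_msm`): restricted λ (1/λ a small integer, with a
  shift if needed), shrinks each person's transformed mean toward the grand
  mean by the reliability factor `σ̂u²/(σ̂u² + σ̂ε²/k)`, back-transforms each
  with a closed moment formula, and uses the n shrunken persons as the
  estimated distribution.

The evaluation harness generates samples under 12 built-in scenarios
(n ∈ {150, 300, 500} crossed with within/between variance ratios 4 and 9,
μ = 7.5, λ = 0.2), runs all estimators on every sample, excludes any sample
for which some method estimated the between-person variance as zero, and
scores each method with bias `B = Σ(θ̂ⱼ − θ)/N`, relative bias
`RB = |B/θ|·100`, MSE `Σ(θ̂ⱼ − θ)²/N`, and Bonferroni-corrected t
confidence intervals for the mean bias, against the exact quadrature truth.

## Worked example

Print the true distribution of scenario I (n = 150, σε² = 1, σu² = 0.25):

```sh
$ usualintake truth --scenario I
{
  "scenario": "I",
  "mean": 105.56250000000001,
  "percentiles": {
    "P5": 74.64030320994982,
    "P10": 80.45813388339009,
    ...
    "P90": 132.71207211316099,
    "P95": 141.92765260479914
  }
}
```

The mean 105.5625 is exact: with m = λμ + 1 = 2.5 and s² = λ²(σu² + σε²),
`E[(m + sZ)⁵] = m⁵ + 10m³s² + 15ms⁴ = 105.5625`.

Estimate the usual-intake distribution from a two-day intake table
(`person,day,amount`; here one synthetic scenario-I sample):

```sh
$ usualintake estimate intakes.csv --method all --seed 7
method,statistic,value
spade,mean,104.3955636680956
spade,P10,83.03267473163933
spade,P90,127.05607293029264
...
msm,P10,93.44208919552665
msm,P90,115.16793193324588
```

On this sample SPADE's P10/P90 (83.0 / 127.1) sit slightly inside the true
values (80.5 / 132.7) — the mild over-shrinkage typical at n = 150 — while
the MSM-style estimator, whose distribution is built from shrunken
person-level means, is markedly narrower (93.4 / 115.2). A full study run:

```sh
usualintake run --scenarios I,II --reps 500 --seed 0 --out study_out/
```

writes `summary.csv` (bias/RB/MSE/CI per method × statistic, with the
zero-variance exclusion rule applied), `summary_all.csv` (no exclusions),
`replicates.csv` (tidy per-replicate biases, boxplot-ready),
`exclusions.csv`, and a `manifest.json` with the seed and configuration.

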