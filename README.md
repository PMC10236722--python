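# bvpart

Partitioning trends in genetic mean **and genetic variance** by selection
paths, for pedigreed populations under selection.

Breeding programmes change a population's genetic mean and variance through
several routes at once — sire selection, dam use, dissemination of selected
material. `bvpart` quantifies how much of the observed change each
analyst-defined group of individuals ("path") is responsible for, works with
true breeding values, point estimates, or posterior samples, and ships the
Bayesian machinery (a Gibbs sampler for the pedigree animal model) needed to
attach honest uncertainty to every partitioned trend. It is aimed at
quantitative geneticists analysing breeding-programme data or simulations.

## The method

Every breeding value obeys the recursion
`a_k = ½·a_sire(k) + ½·a_dam(k) + w_k`, where `w_k` is the Mendelian
sampling term. In matrix form `a = T w`, with `T` the lower-triangular
gene-flow matrix and `w ~ N(0, W σ²_a)`. Splitting individuals into `p`
paths with 0/1 diagonal selectors `P_j` (`Σ_j P_j = I`) gives

```
a = (T P_1 + … + T P_p) w = a_1 + … + a_p ,
```

so each individual's breeding value decomposes exactly into streams of
Mendelian terms contributed by each path. Aggregating the `a_j` by a
grouping variable (generation, year) with population-denominator moments
yields per-category path contributions to the genetic mean and, new here,
to the genetic variance:

```
Var(a_t) = Σ_j Var(a_j,t) + 2 ΣΣ_{j<j'} Cov(a_j,t , a_j',t)
```

— an exact identity, with the covariance terms revealing that path
contributions to variance are *not* independent. Because estimated breeding
values are shrunken, their sample variance is biased for the genetic
variance; the package therefore partitions **posterior samples** of
breeding values (from its Gibbs sampler for
`y = Xb + Za + e`, `a ~ N(0, A σ²_a)`) and summarises the per-sample
statistics into posterior means with equal-tailed or HPD intervals.
Supporting machinery: Meuwissen–Luo inbreeding, Henderson's sparse `A⁻¹`
with inbreeding, an infinitesimal-model breeding-programme simulator, and
Lin's concordance correlation (`ρc = ρ·C_b`) plus RMSD for calibration
checks.

## Worked example

Simulate a reduced breeding programme (10 + 10 generations of 200
candidates, 5 sires selected on true breeding value), partition true
breeding values by sex and selection status, and summarise by generation:

```python
from bvpart import (SimConfig, simulate_programme, assign_paths,
                    partition_breeding_values, summarize_partitions,
                    correlation_between_paths)

cfg = SimConfig(n_generations_burnin=10, n_generations_selection=10,
                n_per_generation=200, selection_criterion="true_bv", seed=1)
sim = simulate_programme(cfg)
paths = assign_paths(sim, "by_sex_and_selection")
part = partition_breeding_values(sim.ped, sim.true_bv, paths)

means = summarize_partitions(part, by=sim.generation, statistic="mean")
print(means.tail(3).round(3).to_string(index=False))
var = summarize_partitions(part, by=sim.generation, statistic="var")
print(var.tail(3).round(3).to_string(index=False))
corr = correlation_between_paths(part, by=sim.generation,
                                 path_a="F", path_b="M(S)")
print("mean F:M(S) correlation, generations 5-10:",
      round(corr.loc[5:10].mean(), 3))
```

Output:

```
 group   n     F   M(N)  M(S)  total
     8 200 1.621 -0.036 6.336  7.922
     9 200 1.726  0.013 6.780  8.519
    10 200 1.886 -0.059 7.210  9.036
 group   n     F  M(N)  M(S)    cov  total
     8 200 0.329 0.166 0.059 -0.056  0.499
     9 200 0.427 0.153 0.077 -0.103  0.553
    10 200 0.344 0.160 0.081 -0.080  0.505
mean F:M(S) correlation, generations 5-10: -0.067
```

Reading the mean table: by selection generation 10 the cohort mean is
+9.0 base-genetic-SD units, of which the five selected sires per
generation contributed 7.2 and the (unselected) females 1.9 — females
contribute through the dissemination of their sires' gains and through
their sons. Non-selected males contribute nothing that persists. In the
variance table each generation's total genetic variance (0.50 at
generation 10, down from 1.0 in the base cohort) splits into path
variances plus a collapsed covariance column; the negative `cov` shows
that the female and selected-male contributions co-vary negatively, so
path variances must never be read in isolation. The same calls accept a
matrix of posterior samples, giving interval estimates for every cell.

The command-line interface mirrors the workflow
(`bvpart simulate | gibbs | partition | summarize | metrics`); every run
is reproducible from its config file and seed.

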