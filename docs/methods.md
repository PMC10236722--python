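# Methods

## Partitioning model

The package decomposes breeding values over a pedigree. With `a = T w`
(`T` the gene-flow matrix, `w` the Mendelian sampling terms) and a path
variable splitting individuals into `p` disjoint groups via diagonal 0/1
selectors `P_j` with `Σ P_j = I`, the contribution of path `j` is
`a_j = T P_j w`. The attribution convention is that a Mendelian term
belongs to the path of the individual who *expresses* it: an individual's
`a_j` collects the segregation deviations of all its ancestors (and, for
its own term, itself) that carry label `j`. Partitions are computed by a
single pass over the topologically ordered pedigree,

```
a_{k,·} = ½ a_{sire(k),·} + ½ a_{dam(k),·} + e_{path(k)} w_k ,
```

which is algebraically identical to the dense products `T P_j w` but runs
in O(n·p) time and memory. Unknown parents contribute zero, so a founder's
entire value lands in its own path. The same code path serves true values,
point estimates, multiple traits, and posterior samples (column by column,
constant memory per column).

Because partitioning is linear and exact, two identities hold to rounding
error and are enforced in tests: contributions sum to the input value per
individual, and per-category total variance equals the sum of path
variances plus twice the sum of pairwise path covariances.

## Summaries

Per-category means, variances, and covariances of path contributions use
the **population denominator 1/n_k** by default. This is deliberate: only
under that convention is the variance decomposition identity exact, which
is the property the whole analysis rests on. A sample (n−1) option is not
offered for the decomposition because it would silently break additivity.
Covariances are reported either collapsed into a single column
(`2·ΣΣ_{j<j'} Cov`) or as `p(p−1)/2` pairwise columns (each `2·Cov`); the
collapsed value always equals the pairwise sum. Categories are emitted in
natural sort order; declared-but-empty categories yield explicit null
rows rather than disappearing.

With `S` posterior samples of breeding values, every summary cell is
computed per sample and then summarised across samples by the posterior
mean and a 95% interval — equal-tailed by default, or highest posterior
density. The HPD is the shortest window of order statistics containing
`ceil(level·S)` points; a neighbouring convention (one extra point, as in
some libraries) differs by at most one order statistic and is covered by a
tolerance test, not silently adopted.

## Animal model and samplers

Breeding values are inferred under the single-trait pedigree model
`y | b, a ~ N(Xb + Za, Iσ²_e)`, `a ~ N(0, Aσ²_a)`. Two samplers are
provided:

- **Single-site Gibbs** over all location effects with variance draws from
  scaled-inverse-chi-square full conditionals (shape from `aᵀA⁻¹a` and the
  residual sum of squares). Priors default to df = 4 with data-derived
  scales (half the phenotypic variance each); a flat improper option
  (df = −2, scale 0) exists. Defaults are weakly informative because real
  phenotype tables rarely justify more; the likelihood dominates at the
  problem sizes used here. One chain by default; burn-in is user-declared
  and assessed with trace/autocorrelation diagnostics (`chain_diagnostics`,
  effective sample size via arviz), not auto-stopped. The kernel is
  compiled with numba; a chain is bit-reproducible given its seed.
- **Known-variance (empirical-Bayes) sampler**: exact joint Gaussian draws
  of `(b, a)` at fixed variance components using the simulate-and-correct
  construction — draw a prior replicate `(a*, e*)`, solve the mixed-model
  equations for the discrepancy, and shift. Its long-run mean equals the
  direct sparse MME solution, which is the cross-check used in tests.

`A⁻¹` is assembled by Henderson's rank-one rules with
inbreeding-corrected Mendelian variance coefficients
(`0.5 − 0.25(F_s + F_d)` both parents known, `0.75 − 0.25·F_p` one known,
1 otherwise); inbreeding itself comes from the Meuwissen–Luo algorithm.
Ignoring inbreeding at the inbreeding levels this breeding scheme produces
(mean F above 0.4 by the late generations) visibly corrupts variance
partitions, so `A⁻¹` always uses F.

Unknown parents are a single sentinel; an individual with one unknown
parent is assigned F = 0 through that side (unknown parent treated as an
unrelated base individual). Pedigrees are re-sorted topologically rather
than rejected when offspring precede parents, since real files are often
unsorted; identifiers are opaque strings mapped to dense indices, and the
mapping round-trips.

## Simulator

The synthetic generator emulates a deliberately intense closed nucleus:
discrete generations of 1000 candidates (500 male / 500 female), the best
5 males selected each generation — on phenotype during a 20-generation
burn-in, then on phenotype ("medium accuracy") or true breeding value
("high accuracy") for 20 more generations — and every female used as a dam
in two consecutive generations (1000 dams per mating round; effective size
4·5·1000/1005 < 20). Generation labels run −19…0 (burn-in) and 1…20
(selection). True breeding values follow the infinitesimal model with
Mendelian variance `(0.5 − 0.25(F_s + F_d))·σ²_a`; the base cohort is
standardised to mean 0, variance 1 exactly (population denominator);
phenotypes add residual noise with `σ²_e = σ²_a(1−h²)/h²`, h² = 0.3.

Where the scheme leaves details open, the generator declares them: dams
are drawn without replacement (the 500 base females are each used twice in
the very first round, when only one cohort exists); litters are split
across the 5 sires as evenly as possible; offspring sex is balanced
exactly; the final cohort still has 5 males labelled "selected" for
consistent path counts. A `random` selection criterion provides a no-trend
control.

A finite-locus mode replaces Gaussian deviations with explicit unlinked
biallelic loci (uniform founder frequencies, normal effects rescaled so
the base cohort variance is σ²_a, independent segregation, monomorphic
founder loci re-drawn). Unlike the infinitesimal run it exhibits genuine
genic-variance erosion by drift and selection, which is what makes a
pedigree-based model's base-variance estimate exceed realised
late-generation variance — a qualitative effect covered by a test.

What the generator does **not** emulate: linked loci, recombination maps,
and coalescent founders with realistic livestock demography (related base
individuals, background LD). Passing tests therefore demonstrate the
correctness of the partitioning algebra and the calibration of the
samplers under the stated model, not the exact magnitudes that
genome-based simulation produces. Concretely, the mean within-generation
correlation between female and selected-male partitions over selection
generations 8–20 under high accuracy comes out near −0.1 here (negative
in every replicate, stronger than under medium accuracy), weaker than the
≈ −0.33 a linked-genome simulation with related founders yields; the
maximum relative change in true genetic variance across the 40 generations
is 60–70%. Both quantities are recomputed from scratch by
`scripts/acceptance.py`.

## Agreement metrics

Lin's concordance correlation `ρc = 2σ₁₂/(σ₁² + σ₂² + (μ₁−μ₂)²)` with all
moments in the population (1/m) convention, computed in one code path so
the convention cancels. The decomposition `ρc = ρ·C_b`,
`C_b = 2(v + v⁻¹ + u²)⁻¹`, uses Lin's standard-deviation shifts
`v = σ₁/σ₂` and `u = (μ₁−μ₂)/√(σ₁σ₂)` — the only convention under which
the factorisation is an exact identity, which the tests assert to 1e−12.
Confidence intervals for ρc are intentionally not provided. RMSD is the
root mean square difference. `truth_vs_estimate_differences` summarises
(true − estimated) per category across replicates with mean and
equal-tailed bands; under a well-calibrated model the bands straddle zero.

## Problem sizes and numerics

Structural identities are tested on random pedigrees up to 200 individuals
against dense oracles (tabular relationship matrix, explicit `T P_j w`
products) at tolerances 1e−8…1e−10. Sampler calibration uses 50 replicates
of n = 2000 (5 random-mating generations) with shortened chains
(2500 iterations, 500 burn-in, thin 4), which keeps the full suite around
a minute while leaving Monte-Carlo error well inside the asserted binomial
bands; the mean-trajectory calibration study uses 10+10 generations × 200
individuals with a 6000-iteration chain. Accumulation is plain double
precision — error grows with pedigree depth × machine epsilon and is
negligible at 40 generations. Degenerate inputs are handled explicitly:
empty categories give null rows, zero-variance paths give missing
correlations, `S = 1` with an interval request is an error, non-finite
variance draws abort with the iteration index.

## Known limitations

- Path contributions to variance are not independent; single-path
  variances can mislead without the covariance column (which is why the
  collapsed column is always emitted).
- The pedigree-based model cannot see allele-frequency change; under
  intense selection its base-variance scale overstates late-generation
  variance (shown qualitatively in the finite-locus test). A genomic
  extension is out of scope.
- Multi-trait models are not implemented; the partitioning machinery is
  already multi-column, so traits are handled by looping.
- REML is not included; the known-variance sampler accepts externally
  estimated components.
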