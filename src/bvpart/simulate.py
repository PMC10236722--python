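"""Breeding-programme simulator under the infinitesimal model.

Emulates a simple closed cattle nucleus: discrete generations of 1000
candidates (500 male, 500 female), the best 5 males selected as sires each
generation — on phenotype during a 20-generation burn-in and then on
phenotype (medium accuracy, r ≈ 0.3) or true breeding value (high
accuracy, r = 1) for 20 further generations — and every female used as a
dam across two consecutive generations.  With 5 sires and 1000 dams the
scheme's effective population size 4·nSires·nDams/(nSires+nDams) is below
20, deliberately intense so that both genetic mean and variance change.

True breeding values follow the infinitesimal model: founders are drawn
from N(0, σ²_a) and standardised so the base cohort has mean 0 and
variance 1 exactly; offspring receive the parent average plus a Mendelian
deviation with variance (0.5 − 0.25(F_s + F_d))·σ²_a, so inbreeding erodes
segregation variance.  Phenotypes add N(0, σ²_e) noise with
σ²_e = σ²_a(1−h²)/h².  An optional finite-locus mode replaces the Gaussian
deviations with explicit biallelic loci, which additionally exhibits
drift and selection-driven change in the realised genic variance.

Generation labels run −19…0 for burn-in and 1…20 for the selection phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .partition import PathAssignment
from .pedigree import Pedigree, compute_inbreeding

PATH_F = "F"
PATH_MS = "M(S)"
PATH_MN = "M(N)"


def effective_size(n_sires: int, n_dams: int) -> float:
    """Idealised-population effective size 4·Ns·Nd/(Ns+Nd)."""
    return 4.0 * n_sires * n_dams / (n_sires + n_dams)


@dataclass
class SimConfig:
    n_generations_burnin: int = 20
    n_generations_selection: int = 20
    n_per_generation: int = 1000
    n_sires: int = 5
    dam_generations_used: int = 2
    h2: float = 0.3
    sigma2_a: float = 1.0
    selection_criterion: str = "phenotype"  # phenotype | true_bv | random
    standardize_base: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.n_sires > self.n_per_generation // 2:
            raise ValueError("cannot select more sires than male candidates")
        if self.selection_criterion not in ("phenotype", "true_bv", "random"):
            raise ValueError(f"unknown selection criterion: {self.selection_criterion}")

    @property
    def sigma2_e(self) -> float:
        return self.sigma2_a * (1.0 - self.h2) / self.h2

    @property
    def n_generations(self) -> int:
        return self.n_generations_burnin + self.n_generations_selection


@dataclass
class SimOutput:
    """Pedigree, true breeding values, phenotypes and selection metadata."""

    ped: Pedigree
    true_bv: np.ndarray
    phenotype: np.ndarray
    F: np.ndarray
    selected: np.ndarray
    generation: np.ndarray  # generation label per individual (−19…20)
    config: SimConfig = field(repr=False, default=None)

    def genetic_variance_by_generation(self) -> dict:
        """Population-denominator variance of true breeding values per
        generation label."""
        out = {}
        for g in np.unique(self.generation):
            a = self.true_bv[self.generation == g]
            out[int(g)] = float(a.var())
        return out


def _mating_plan(rng, sire_pool, dam_pool, n_off):
    """Dams shuffled without replacement (cycled when the pool is short of
    one dam per offspring); litters split across sires as evenly as
    possible."""
    dams = np.asarray(dam_pool)
    reps = int(np.ceil(n_off / dams.size))
    dams = np.concatenate([rng.permutation(dams) for _ in range(reps)])[:n_off]
    counts = np.full(len(sire_pool), n_off // len(sire_pool))
    counts[: n_off % len(sire_pool)] += 1
    sires = np.repeat(np.asarray(sire_pool), counts)
    return sires, dams


def _criterion_values(criterion, a, y, rng):
    if criterion == "phenotype":
        return y
    if criterion == "true_bv":
        return a
    return rng.random(a.shape[0])  # random control


def simulate_programme(cfg: SimConfig, seed: int | None = None) -> SimOutput:
    """Run one replicate of the breeding programme.

    Fully deterministic under ``seed`` (falls back to ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_per_generation
    n_half = n // 2
    n_gen = cfg.n_generations
    total = n_gen * n

    sire = np.full(total, -1, dtype=np.int64)
    dam = np.full(total, -1, dtype=np.int64)
    a = np.empty(total)
    y = np.empty(total)
    sex = np.empty(total, dtype=object)
    selected = np.zeros(total, dtype=bool)
    generation = np.empty(total, dtype=np.int64)
    F = np.zeros(total)

    prev_females: np.ndarray | None = None
    cur_males = cur_females = None

    for g in range(n_gen):
        lo, hi = g * n, (g + 1) * n
        idx = np.arange(lo, hi)
        generation[idx] = g - (cfg.n_generations_burnin - 1)
        sex[idx[:n_half]] = "M"
        sex[idx[n_half:]] = "F"
        if g == 0:
            founders = rng.normal(0.0, np.sqrt(cfg.sigma2_a), n)
            if cfg.standardize_base:
                founders = (founders - founders.mean()) / founders.std()
                founders *= np.sqrt(cfg.sigma2_a)
            a[idx] = founders
        else:
            sires_g, dams_g = _mating_plan(
                rng, cur_sires, dam_pool, n  # noqa: F821 - bound in prior loop turn
            )
            order = rng.permutation(n)  # decouple sire blocks from sex blocks
            sires_g, dams_g = sires_g[order], dams_g[order]
            sire[idx] = sires_g
            dam[idx] = dams_g
            w_coef = 0.5 - 0.25 * (F[sires_g] + F[dams_g])
            a[idx] = 0.5 * (a[sires_g] + a[dams_g]) + rng.normal(
                0.0, np.sqrt(w_coef * cfg.sigma2_a)
            )
        y[idx] = a[idx] + rng.normal(0.0, np.sqrt(cfg.sigma2_e), n)
        # incremental inbreeding for the new cohort
        ped_part = Pedigree(
            ids=np.arange(hi).astype(str).astype(object),
            sire=sire[:hi],
            dam=dam[:hi],
        )
        F[:hi] = compute_inbreeding(ped_part, F_known=F[:lo])

        cur_males = idx[sex[idx] == "M"]
        cur_females = idx[sex[idx] == "F"]
        in_selection_phase = (g + 1) > cfg.n_generations_burnin
        criterion = (
            cfg.selection_criterion if in_selection_phase else "phenotype"
        )
        vals = _criterion_values(criterion, a[cur_males], y[cur_males], rng)
        top = cur_males[np.argsort(vals)[::-1][: cfg.n_sires]]
        selected[top] = True
        cur_sires = top
        if prev_females is None or cfg.dam_generations_used == 1:
            dam_pool = cur_females
        else:
            dam_pool = np.concatenate([prev_females, cur_females])
        prev_females = cur_females

    path = np.where(
        sex == "F", PATH_F, np.where(selected, PATH_MS, PATH_MN)
    ).astype(object)
    ped = Pedigree(
        ids=np.arange(1, total + 1).astype(str).astype(object),
        sire=sire,
        dam=dam,
        path=path,
        group=generation.copy(),
        sex=sex,
    )
    return SimOutput(
        ped=ped, true_bv=a, phenotype=y, F=F, selected=selected,
        generation=generation, config=cfg,
    )


def assign_paths(sim: SimOutput, scheme: str = "by_sex_and_selection") -> PathAssignment:
    """Path labels: by sex (F/M) or by sex and selection status
    (F, M(S), M(N)); either way the levels partition the population."""
    sex = sim.ped.sex
    if scheme == "by_sex":
        labels = np.where(sex == "F", PATH_F, "M").astype(object)
        return PathAssignment(labels, [PATH_F, "M"])
    if scheme == "by_sex_and_selection":
        labels = np.where(
            sex == "F", PATH_F, np.where(sim.selected, PATH_MS, PATH_MN)
        ).astype(object)
        return PathAssignment(labels, [PATH_F, PATH_MN, PATH_MS])
    raise ValueError(f"unknown path scheme: {scheme}")


def simulate_finite_locus(
    cfg: SimConfig, n_loci: int = 1000, seed: int | None = None
) -> SimOutput:
    """Finite-locus variant: explicit biallelic loci instead of Gaussian
    Mendelian deviations.

    Founders carry genotypes at ``n_loci`` independent loci with uniform
    allele frequencies (monomorphic draws re-sampled) and normal additive
    effects rescaled so the base cohort has genetic variance σ²_a; gametes
    segregate independently.  Unlike the infinitesimal run, later-cohort
    genic variance genuinely erodes with drift and selection, which is the
    mechanism behind pedigree-model variance miscalibration.
    """
    if n_loci < 100:
        raise ValueError("n_loci must be at least 100")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_per_generation
    n_half = n // 2
    n_gen = cfg.n_generations
    total = n_gen * n

    geno = np.empty((total, n_loci), dtype=np.int8)
    freq = rng.uniform(0.0, 1.0, n_loci)
    g0 = rng.binomial(2, freq, (n, n_loci)).astype(np.int8)
    mono = (g0.min(axis=0) == g0.max(axis=0))
    while mono.any():  # degenerate monomorphic founders are re-drawn
        freq[mono] = rng.uniform(0.0, 1.0, mono.sum())
        g0[:, mono] = rng.binomial(2, freq[mono], (n, int(mono.sum()))).astype(np.int8)
        mono = (g0.min(axis=0) == g0.max(axis=0))
    geno[:n] = g0
    effects = rng.normal(0.0, 1.0, n_loci)

    raw = g0 @ effects
    offset = raw.mean()
    scale = np.sqrt(cfg.sigma2_a) / raw.std()
    if not cfg.standardize_base:
        offset, scale = 0.0, 1.0

    def bv(rows):
        return (geno[rows] @ effects - offset) * scale

    sire = np.full(total, -1, dtype=np.int64)
    dam = np.full(total, -1, dtype=np.int64)
    a = np.empty(total)
    y = np.empty(total)
    sex = np.empty(total, dtype=object)
    selected = np.zeros(total, dtype=bool)
    generation = np.empty(total, dtype=np.int64)

    def gamete(parents):
        g = geno[parents]
        het = g == 1
        out = (g // 2).astype(np.int8)
        out[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8)
        return out

    prev_females = None
    for g in range(n_gen):
        lo, hi = g * n, (g + 1) * n
        idx = np.arange(lo, hi)
        generation[idx] = g - (cfg.n_generations_burnin - 1)
        sex[idx[:n_half]] = "M"
        sex[idx[n_half:]] = "F"
        if g > 0:
            sires_g, dams_g = _mating_plan(rng, cur_sires, dam_pool, n)  # noqa: F821
            order = rng.permutation(n)
            sires_g, dams_g = sires_g[order], dams_g[order]
            sire[idx] = sires_g
            dam[idx] = dams_g
            geno[idx] = gamete(sires_g) + gamete(dams_g)
        a[idx] = bv(idx)
        y[idx] = a[idx] + rng.normal(0.0, np.sqrt(cfg.sigma2_e), n)

        cur_males = idx[sex[idx] == "M"]
        cur_females = idx[sex[idx] == "F"]
        in_selection_phase = (g + 1) > cfg.n_generations_burnin
        criterion = cfg.selection_criterion if in_selection_phase else "phenotype"
        vals = _criterion_values(criterion, a[cur_males], y[cur_males], rng)
        top = cur_males[np.argsort(vals)[::-1][: cfg.n_sires]]
        selected[top] = True
        cur_sires = top
        if prev_females is None or cfg.dam_generations_used == 1:
            dam_pool = cur_females
        else:
            dam_pool = np.concatenate([prev_females, cur_females])
        prev_females = cur_females

    path = np.where(sex == "F", PATH_F, np.where(selected, PATH_MS, PATH_MN)).astype(object)
    ped = Pedigree(
        ids=np.arange(1, total + 1).astype(str).astype(object),
        sire=sire, dam=dam, path=path, group=generation.copy(), sex=sex,
    )
    F = compute_inbreeding(ped)
    return SimOutput(
        ped=ped, true_bv=a, phenotype=y, F=F, selected=selected,
        generation=generation, config=replace(cfg),
    )
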