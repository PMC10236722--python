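"""Breeding-programme simulator: scheme structure, model properties, and
the finite-locus variant."""

import numpy as np
import pytest

from bvpart.partition import partition_breeding_values
from bvpart.simulate import (
    SimConfig,
    assign_paths,
    effective_size,
    simulate_finite_locus,
    simulate_programme,
)


def small_cfg(**kw):
    defaults = dict(
        n_generations_burnin=5,
        n_generations_selection=5,
        n_per_generation=100,
        n_sires=5,
        h2=0.3,
        seed=42,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestScheme:
    def test_effective_size_of_paper_scheme_below_20(self):
        assert effective_size(5, 1000) == pytest.approx(4 * 5 * 1000 / 1005)
        assert effective_size(5, 1000) < 20

    def test_seeded_determinism(self):
        s1 = simulate_programme(small_cfg())
        s2 = simulate_programme(small_cfg())
        np.testing.assert_array_equal(s1.true_bv, s2.true_bv)
        np.testing.assert_array_equal(s1.ped.sire, s2.ped.sire)
        assert not np.array_equal(
            s1.true_bv, simulate_programme(small_cfg(seed=43)).true_bv
        )

    def test_base_cohort_standardised_exactly(self):
        sim = simulate_programme(small_cfg())
        base = sim.true_bv[sim.generation == sim.generation.min()]
        assert base.mean() == pytest.approx(0.0, abs=1e-12)
        assert base.var() == pytest.approx(1.0, abs=1e-12)

    def test_generation_labels_span_burnin_and_selection(self):
        sim = simulate_programme(small_cfg())
        labels = np.unique(sim.generation)
        np.testing.assert_array_equal(labels, np.arange(-4, 6))

    def test_path_counts_per_generation(self):
        sim = simulate_programme(small_cfg())
        paths = assign_paths(sim, "by_sex_and_selection")
        for g in np.unique(sim.generation):
            labs = paths.labels[sim.generation == g]
            assert (labs == "F").sum() == 50
            assert (labs == "M(S)").sum() == 5
            assert (labs == "M(N)").sum() == 45

    def test_by_sex_counts_and_partition_property(self):
        sim = simulate_programme(small_cfg())
        by_sex = assign_paths(sim, "by_sex")
        g0 = sim.generation == 1
        assert (by_sex.labels[g0] == "F").sum() == 50
        assert (by_sex.labels[g0] == "M").sum() == 50
        # one-hot indicators sum to one for every individual
        three = assign_paths(sim, "by_sex_and_selection")
        onehot = np.zeros((sim.ped.n, three.n_paths))
        onehot[np.arange(sim.ped.n), three.codes] = 1
        np.testing.assert_array_equal(onehot.sum(axis=1), np.ones(sim.ped.n))

    def test_parents_come_from_allowed_cohorts(self):
        sim = simulate_programme(small_cfg())
        gen_of = sim.generation
        off = sim.ped.sire >= 0
        ks = np.nonzero(off)[0]
        assert np.all(gen_of[sim.ped.sire[ks]] == gen_of[ks] - 1)
        dam_gap = gen_of[ks] - gen_of[sim.ped.dam[ks]]
        assert set(np.unique(dam_gap)) <= {1, 2}
        assert np.all(sim.ped.sex[sim.ped.sire[ks]] == "M")
        assert np.all(sim.ped.sex[sim.ped.dam[ks]] == "F")

    def test_sires_are_the_selected_males(self):
        sim = simulate_programme(small_cfg())
        used = np.unique(sim.ped.sire[sim.ped.sire >= 0])
        assert np.all(sim.selected[used])

    def test_infeasible_sire_count_rejected(self):
        with pytest.raises(ValueError, match="sires"):
            small_cfg(n_sires=60)


class TestModelProperties:
    def test_offspring_deviation_variance_half_sigma2a(self):
        # founder parents are non-inbred, so Var(a − parent average) = 0.5 σ²_a
        cfg = small_cfg(n_generations_burnin=2, n_generations_selection=0,
                        n_per_generation=4000, n_sires=200)
        sim = simulate_programme(cfg)
        off = sim.generation == sim.generation.max()
        dev = (
            sim.true_bv[off]
            - 0.5 * sim.true_bv[sim.ped.sire[off]]
            - 0.5 * sim.true_bv[sim.ped.dam[off]]
        )
        assert dev.var() == pytest.approx(0.5, rel=0.1)

    def test_random_selection_has_no_trend_and_phenotypic_does(self):
        cfg_r = small_cfg(n_generations_burnin=0, n_generations_selection=10,
                          n_per_generation=200, selection_criterion="random")
        sim_r = simulate_programme(cfg_r)
        drift = sim_r.true_bv[sim_r.generation == 10].mean()
        cfg_s = small_cfg(n_generations_burnin=0, n_generations_selection=10,
                          n_per_generation=200, selection_criterion="phenotype")
        sim_s = simulate_programme(cfg_s)
        gain = sim_s.true_bv[sim_s.generation == 10].mean()
        assert abs(drift) < 2.0  # drift at Ne≈19.5 stays near zero
        assert gain > 2.0

    def test_phenotype_heritability_matches_h2(self):
        sim = simulate_programme(small_cfg(n_per_generation=2000,
                                           n_generations_burnin=1,
                                           n_generations_selection=0))
        e = sim.phenotype - sim.true_bv
        h2 = sim.true_bv.var() / (sim.true_bv.var() + e.var())
        assert h2 == pytest.approx(0.3, abs=0.03)

    def test_inbreeding_rises_under_selection(self):
        sim = simulate_programme(small_cfg())
        assert sim.F[sim.generation == 5].mean() > 0.05
        assert np.all(sim.F[sim.generation == sim.generation.min()] == 0.0)

    def test_mendelian_terms_center_zero_except_selected_sires(self):
        cfg = small_cfg(n_generations_burnin=10, n_generations_selection=0,
                        n_per_generation=400)
        sim = simulate_programme(cfg)
        paths = assign_paths(sim)
        part = partition_breeding_values(sim.ped, sim.true_bv, paths)
        w = part.mendelian
        nonbase = sim.generation > sim.generation.min()
        sel = sim.selected & nonbase
        unsel = ~sim.selected & nonbase
        # unselected mean within Monte-Carlo error of 0; selected clearly above
        n_u = unsel.sum()
        assert abs(w[unsel].mean()) < 4 * np.sqrt(0.5 / n_u)
        assert w[sel].mean() > 0.2


class TestFiniteLocus:
    def test_base_variance_scaled_to_sigma2a(self):
        sim = simulate_finite_locus(small_cfg(), n_loci=300)
        base = sim.true_bv[sim.generation == sim.generation.min()]
        assert base.var() == pytest.approx(1.0, abs=1e-10)
        assert base.mean() == pytest.approx(0.0, abs=1e-10)

    def test_minimum_locus_count_enforced(self):
        with pytest.raises(ValueError, match="n_loci"):
            simulate_finite_locus(small_cfg(), n_loci=10)

    def test_neutral_variance_decays_at_drift_rate(self):
        # expected per-generation decay ≈ 1/(2Ne) without selection
        cfg = small_cfg(n_generations_burnin=0, n_generations_selection=12,
                        n_per_generation=200, selection_criterion="random")
        ne = effective_size(cfg.n_sires, cfg.n_per_generation)
        ratios = []
        for seed in (1, 2, 3):
            sim = simulate_finite_locus(cfg, n_loci=500, seed=seed)
            var = sim.genetic_variance_by_generation()
            ratios.append(var[12] / var[1])
        expected = (1 - 1 / (2 * ne)) ** 11
        assert np.mean(ratios) == pytest.approx(expected, abs=0.15)

    def test_selection_erodes_variance_below_base(self):
        cfg = small_cfg(selection_criterion="true_bv")
        sim = simulate_finite_locus(cfg, n_loci=300)
        var = sim.genetic_variance_by_generation()
        assert var[5] < 0.8 * var[-4]

    def test_pedigree_model_overstates_late_variance_under_selection(self):
        """Base-population variance estimated by the sampler exceeds the
        realised variance of late generations: the genomic erosion of
        variance is invisible to the pedigree model's base-variance scale."""
        from bvpart.bayes import GibbsConfig, PhenotypeData, gibbs_animal_model
        from bvpart.pedigree import build_A_inverse
        import pandas as pd

        cfg = small_cfg(n_generations_burnin=4, n_generations_selection=4,
                        n_per_generation=150, selection_criterion="true_bv")
        sim = simulate_finite_locus(cfg, n_loci=300)
        data = PhenotypeData.from_frame(
            pd.DataFrame({"id": sim.ped.ids, "phenotype": sim.phenotype}), sim.ped
        )
        Ainv = build_A_inverse(sim.ped, sim.F)
        gcfg = GibbsConfig(n_iter=2000, burn_in=500, thin=3, seed=5)
        samples = gibbs_animal_model(sim.ped, Ainv, data, gcfg)
        base_var_est = samples.vc[:, 0].mean()
        late_true_var = sim.true_bv[sim.generation == 4].var()
        assert base_var_est > late_true_var
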