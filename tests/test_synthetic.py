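import numpy as np
import pytest

import idload as il
from idload.inbreeding import meuwissen_luo_F
from idload.partial import partial_inbreeding
from idload.regression import linear_depression_regression
from idload.synthetic import (FIXTURES, make_fixture, sample_genetic_effects,
                              simulate_pedigree, simulate_phenotypes)


class TestSimulatePedigree:
    def test_no_close_matings_single_generation_no_inbreeding(self):
        cfg = il.PedigreeSimConfig(n_founders=20, n_generations=1,
                                   matings_per_generation=10,
                                   close_mating_probability=0.0, seed=0)
        assert np.all(meuwissen_luo_F(simulate_pedigree(cfg)) == 0.0)

    def test_forced_fullsib_matings_give_quarter_F(self):
        cfg = il.PedigreeSimConfig(n_founders=12, n_generations=2,
                                   matings_per_generation=10,
                                   offspring_per_mating=3,
                                   close_mating_probability=1.0, seed=3)
        ped = simulate_pedigree(cfg)
        F = meuwissen_luo_F(ped)
        gen2 = ped.birth_year == 2002
        assert F[gen2].max() == pytest.approx(0.25)

    def test_same_seed_identical(self):
        cfg = il.PedigreeSimConfig(seed=9)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(a.sire, b.sire)
        assert np.array_equal(a.dam, b.dam)
        assert np.array_equal(a.sex, b.sex)

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            il.PedigreeSimConfig(n_founders=1)


class TestGeneticEffects:
    def test_founder_pairs_match_G(self):
        cfg = il.PedigreeSimConfig(n_founders=5000, n_generations=1,
                                   matings_per_generation=1, seed=2)
        ped = simulate_pedigree(cfg)
        G = np.array([[0.5, -0.3], [-0.3, 2.0]])
        rng = np.random.default_rng(0)
        ui = sample_genetic_effects(ped, G, np.zeros(ped.n), rng)
        founders = ui[ped.is_founder.nonzero()[0]]
        emp = np.cov(founders.T)
        se = 4 / np.sqrt(len(founders))
        assert abs(emp[0, 0] - 0.5) < se * 0.5 * np.sqrt(2)
        assert abs(emp[1, 1] - 2.0) < se * 2.0 * np.sqrt(2)
        assert abs(emp[0, 1] + 0.3) < se * np.sqrt(0.5 * 2.0)

    def test_additive_variance_grows_with_inbreeding(self):
        """Per-animal Var(u_x) over replicates is sigma_u^2 (1 + F_x)."""
        cfg = il.PedigreeSimConfig(n_founders=30, n_generations=4,
                                   matings_per_generation=30,
                                   close_mating_probability=0.9, seed=5)
        ped = simulate_pedigree(cfg)
        F = meuwissen_luo_F(ped)
        x = int(np.argmax(F))
        assert F[x] >= 0.25
        G = np.eye(2)
        rng = np.random.default_rng(1)
        u_x, u_f = [], []
        founder = int(np.nonzero(ped.is_founder)[0][0])
        for _ in range(600):
            ui = sample_genetic_effects(ped, G, F, rng)
            u_x.append(ui[x, 0])
            u_f.append(ui[founder, 0])
        assert np.var(u_x) > np.var(u_f)
        assert np.var(u_x) == pytest.approx(1 + F[x], rel=0.2)
        assert np.var(u_f) == pytest.approx(1.0, rel=0.2)


class TestSimulatePhenotypes:
    def setup_population(self, seed=0):
        cfg = il.PedigreeSimConfig(n_founders=40, n_generations=3,
                                   matings_per_generation=40,
                                   close_mating_probability=0.3, seed=seed)
        ped = simulate_pedigree(cfg)
        return ped, partial_inbreeding(ped)

    def test_pure_noise_variance(self):
        ped, pset = self.setup_population()
        comp = il.VarianceTruth(sigma2_u=1e-12, sigma_ui=0.0, sigma2_i=1e-12,
                                sigma2_e=0.8, c=0.0)
        cfg = il.PhenotypeSimConfig(components=comp, sex_effect=0.0,
                                    stud_size_effects=(0, 0, 0),
                                    age_slope=0.0, mean_records=45.0, seed=4)
        pheno, _ = simulate_phenotypes(ped, pset, cfg)
        n = len(pheno)
        assert n > 5000
        v = pheno["gait"].var()
        se = 0.8 * np.sqrt(2.0 / n)
        assert abs(v - 0.8) < 3 * se

    def test_noninbred_population_has_zero_idl_contribution(self):
        cfg = il.PedigreeSimConfig(n_founders=20, n_generations=1,
                                   matings_per_generation=10,
                                   close_mating_probability=0.0, seed=1)
        ped = simulate_pedigree(cfg)
        pset = partial_inbreeding(ped)
        pcfg = il.PhenotypeSimConfig(seed=2)
        _, truth = simulate_phenotypes(ped, pset, pcfg)
        assert np.all(truth["ki"] == 0.0)

    def test_depression_slope_recovered_by_screening_regression(self):
        ped, pset = self.setup_population(seed=8)
        comp = il.VarianceTruth(sigma2_u=0.05, sigma_ui=0.0, sigma2_i=0.05,
                                sigma2_e=0.1, c=-0.7)
        cfg = il.PhenotypeSimConfig(components=comp, sex_effect=0.0,
                                    stud_size_effects=(0, 0, 0),
                                    age_slope=0.0, mean_records=8.0, seed=9)
        pheno, _ = simulate_phenotypes(ped, pset, cfg)
        res = linear_depression_regression(pheno["gait"].to_numpy(),
                                           pheno["F"].to_numpy())
        assert abs(res.coefficient - (-0.7)) < 4 * res.standard_error

    def test_ordinal_trait_classes(self):
        ped, pset = self.setup_population(seed=3)
        comp = il.VarianceTruth(sigma2_u=0.1, sigma_ui=0.0, sigma2_i=0.2,
                                sigma2_e=0.4, c=0.5)
        cfg = il.PhenotypeSimConfig(components=comp, trait="closed_hock",
                                    kind="ordinal",
                                    ordinal_thresholds=(0.6, 1.6), seed=5)
        pheno, _ = simulate_phenotypes(ped, pset, cfg)
        assert set(pheno["closed_hock"].unique()) <= {1, 2, 3}
        counts = pheno["closed_hock"].value_counts()
        assert counts.idxmax() == 1        # majority class 1, like defects

    def test_bitwise_reproducible(self):
        ped, pset = self.setup_population(seed=6)
        cfg = il.PhenotypeSimConfig(seed=11)
        a, _ = simulate_phenotypes(ped, pset, cfg)
        b, _ = simulate_phenotypes(ped, pset, cfg)
        assert a.equals(b)


class TestFixtures:
    def test_unknown_name_lists_available(self):
        with pytest.raises(ValueError, match="tiny_trio"):
            make_fixture("nope")

    @pytest.mark.parametrize("name", ["tiny_trio", "fullsib_loop",
                                      "deep_loop"])
    def test_small_fixtures_have_expected_values(self, name):
        fx = make_fixture(name)
        ped = fx["pedigree"]
        F = meuwissen_luo_F(ped)
        if name == "tiny_trio":
            assert np.array_equal(F, fx["expected_F"])
        elif name == "fullsib_loop":
            assert np.array_equal(F, fx["expected_F"])
            pset = partial_inbreeding(ped, threshold=0.0)
            ent = pset.entries.set_index(["animal", "ancestor"])["fij"]
            for key, val in fx["expected_fij"].items():
                assert ent[key] == pytest.approx(val)
        else:
            x = ped.internal(fx["focal"])
            assert F[x] == pytest.approx(fx["expected_F_focal"])
            assert il.six_generation_F(ped)[x] == 0.0

    def test_recovery_small_shape(self, recovery_small):
        assert recovery_small["pedigree"].n == 600
        assert 1000 <= len(recovery_small["phenotypes"]) <= 1500
        assert recovery_small["model_form"] == "reduced"
        assert (recovery_small["truth"]["F"] > 0).sum() > 100
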