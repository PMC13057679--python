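import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import idload as il
from idload.model import (ChainConfig, DesignMatrices, ModelSpec,
                          build_design, gibbs_fit, hpd_interval,
                          idl_incidence, summarize_posterior, variance_ratios)
from idload.partial import partial_inbreeding


def small_recovery_setup(seed=0, **chain_kw):
    cfg = il.PedigreeSimConfig(n_founders=30, n_generations=3,
                               matings_per_generation=27,
                               offspring_per_mating=2,
                               close_mating_probability=0.4, seed=seed)
    ped = il.simulate_pedigree(cfg)
    pset = partial_inbreeding(ped)
    comp = il.VarianceTruth(sigma2_u=0.4, sigma_ui=0.0, sigma2_i=1.5,
                            sigma2_e=0.5, c=-0.7)
    pcfg = il.PhenotypeSimConfig(components=comp, mean_records=2.0,
                                 seed=seed + 500)
    pheno, truth = il.simulate_phenotypes(ped, pset, pcfg)
    kw = dict(length=20_000, burn_in=2_000, thinning=10, seed=seed + 9)
    kw.update(chain_kw)
    spec = ModelSpec(trait="gait", model_form="reduced",
                     fixed_effects=["sex", "stud_size"], covariates=["age"],
                     chain=ChainConfig(**kw))
    return ped, pset, pheno, truth, spec


class TestBuildDesign:
    def test_noninbred_animal_has_zero_K_row(self, fullsib):
        ped = fullsib["pedigree"]
        pset = partial_inbreeding(ped)
        pheno = pd.DataFrame({"animal": [3, 5], "gait": [6.0, 5.5],
                              "sex": [1, 2], "age": [6.0, 7.0]})
        spec = ModelSpec(trait="gait", model_form="reduced",
                         fixed_effects=["sex"], covariates=["age"])
        dm = build_design(ped, pheno, pset, spec)
        K = dm.K.toarray()
        assert np.all(K[0] == 0.0)          # animal 3 is not inbred
        assert np.any(K[1] != 0.0)          # animal 5 is (F = 0.25)

    def test_fij_scaling_enters_T(self, parent_offspring):
        """F_ij = 0.25 with the default x10 scaling gives a T entry of 2.5."""
        ped = parent_offspring
        pset = partial_inbreeding(ped)
        ent = pset.entries.iloc[0]
        T = sparse.coo_matrix(([ent.fij * 10.0],
                               ([ent.animal_idx], [ent.ancestor_idx])),
                              shape=(ped.n, ped.n))
        assert T.toarray().max() == pytest.approx(2.5)
        Kanim = idl_incidence(ped, pset, fij_scaling=10.0)
        # K = T(I-P): the founder ancestor has no parents, so the K entry
        # linking the inbred animal to it keeps the full 2.5 weight
        assert Kanim[ped.internal(4), ped.internal(1)] == pytest.approx(2.5)

    def test_projection_annihilates_parent_average(self, trio):
        pset = partial_inbreeding(trio)
        n = trio.n
        from idload.pedigree import UNKNOWN
        rows, cols, vals = [], [], []
        for x in range(n):
            for p in (trio.sire[x], trio.dam[x]):
                if p != UNKNOWN:
                    rows.append(x)
                    cols.append(p)
                    vals.append(0.5)
        P = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        v = np.ones(n)
        res = (sparse.identity(n) - P) @ v
        assert res[trio.internal(3)] == pytest.approx(0.0)   # 1 - 0.5 - 0.5

    def test_missing_phenotyped_animal_errors(self, trio):
        pset = partial_inbreeding(trio)
        pheno = pd.DataFrame({"animal": [99], "gait": [5.0], "sex": [1],
                              "age": [5.0]})
        spec = ModelSpec(trait="gait", model_form="reduced")
        with pytest.raises(ValueError, match="99"):
            build_design(trio, pheno, pset, spec)

    def test_single_level_factor_dropped_with_warning(self, fullsib):
        ped = fullsib["pedigree"]
        pset = partial_inbreeding(ped)
        pheno = pd.DataFrame({"animal": [3, 5], "gait": [6.0, 5.5],
                              "sex": [1, 1], "age": [6.0, 7.0]})
        spec = ModelSpec(trait="gait", model_form="reduced",
                         fixed_effects=["sex"], covariates=["age"])
        with pytest.warns(UserWarning, match="single level"):
            dm = build_design(ped, pheno, pset, spec)
        assert "sex[2]" not in dm.x_names


class TestGibbsSampler:
    def test_same_seed_bitwise_identical(self):
        ped, pset, pheno, _, spec = small_recovery_setup(
            seed=1, length=2_000, burn_in=200)
        dm = build_design(ped, pheno, pset, spec)
        a = gibbs_fit(dm, ped, spec)
        b = gibbs_fit(dm, ped, spec)
        assert a.draws.equals(b.draws)
        assert a.i_mean.equals(b.i_mean)

    def test_different_seed_differs(self):
        ped, pset, pheno, _, spec = small_recovery_setup(
            seed=1, length=2_000, burn_in=200)
        dm = build_design(ped, pheno, pset, spec)
        a = gibbs_fit(dm, ped, spec)
        spec2 = ModelSpec(trait="gait", model_form="reduced",
                          fixed_effects=["sex", "stud_size"],
                          covariates=["age"],
                          chain=ChainConfig(length=2_000, burn_in=200,
                                            thinning=10, seed=12345))
        b = gibbs_fit(dm, ped, spec2)
        assert not a.draws.equals(b.draws)

    def test_conjugate_degenerate_matches_closed_form(self):
        """Intercept-only Gaussian model: the sampler must reproduce the
        flat-prior normal/inverse-chi-square posterior moments."""
        rng = np.random.default_rng(3)
        n = 300
        y = rng.normal(2.0, 1.5, size=n)
        X = sparse.csc_matrix(np.ones((n, 1)))
        empty = sparse.csc_matrix((n, 0))
        dm = DesignMatrices(y=y, f=np.zeros(n), X=X, x_names=["intercept"],
                            W=None, R=None, Z=empty, K=empty,
                            obs_animal=np.zeros(n, dtype=np.int64),
                            n_animals=0)
        spec = ModelSpec(trait="y", model_form="reduced",
                         chain=ChainConfig(length=60_000, burn_in=5_000,
                                           thinning=5, seed=11))
        ch = gibbs_fit(dm, None, spec)
        # grid-integration oracle over (mu, sigma2) with flat priors
        ybar, ss = y.mean(), ((y - y.mean()) ** 2).sum()
        mus = np.linspace(ybar - 1, ybar + 1, 600)
        s2s = np.linspace(1.0, 5.0, 600)
        M, S = np.meshgrid(mus, s2s)
        logw = -n / 2 * np.log(S) - (ss + n * (M - ybar) ** 2) / (2 * S)
        W = np.exp(logw - logw.max())
        W /= W.sum()
        mu_mean, mu_sd = (M * W).sum(), np.sqrt((M ** 2 * W).sum()
                                                - (M * W).sum() ** 2)
        s2_mean, s2_sd = (S * W).sum(), np.sqrt((S ** 2 * W).sum()
                                                - (S * W).sum() ** 2)
        mc = 1.0 / np.sqrt(ch.n_draws / 10)   # generous MC slack
        assert ch.draws["intercept"].mean() == pytest.approx(
            mu_mean, abs=6 * mu_sd * mc)
        assert ch.draws["intercept"].std() == pytest.approx(mu_sd, rel=0.1)
        assert ch.draws["sigma2_e"].mean() == pytest.approx(
            s2_mean, abs=6 * s2_sd * mc)
        assert ch.draws["sigma2_e"].std() == pytest.approx(s2_sd, rel=0.1)

    def test_additive_variance_recovery_small_idl(self):
        """With sigma_ui = 0 and a tiny IDL variance, the additive variance
        posterior must cover the simulated truth."""
        cfg = il.PedigreeSimConfig(n_founders=40, n_generations=4,
                                   matings_per_generation=40,
                                   offspring_per_mating=2,
                                   close_mating_probability=0.3, seed=21)
        ped = il.simulate_pedigree(cfg)
        pset = partial_inbreeding(ped)
        comp = il.VarianceTruth(sigma2_u=0.4, sigma_ui=0.0, sigma2_i=0.02,
                                sigma2_e=0.4, c=0.0)
        pcfg = il.PhenotypeSimConfig(components=comp, mean_records=2.0,
                                     seed=77)
        pheno, _ = il.simulate_phenotypes(ped, pset, pcfg)
        spec = ModelSpec(trait="gait", model_form="reduced",
                         fixed_effects=["sex", "stud_size"],
                         covariates=["age"],
                         chain=ChainConfig(length=20_000, burn_in=2_000,
                                           thinning=10, seed=5))
        dm = build_design(ped, pheno, pset, spec)
        ch = gibbs_fit(dm, ped, spec)
        s = summarize_posterior(ch)
        assert s["sigma2_u"]["hpd_low"] <= 0.4 <= s["sigma2_u"]["hpd_high"]

    def test_fij_scaling_rescales_idl_variance_only(self):
        """Halving the F_ij scaling multiplies sigma2_i by 4, leaves d2
        unchanged (up to Monte-Carlo error of the two chains)."""
        ped, pset, pheno, _, spec5 = small_recovery_setup(
            seed=2, length=4_000, burn_in=500)
        spec10 = ModelSpec(trait="gait", model_form="reduced",
                           fixed_effects=["sex", "stud_size"],
                           covariates=["age"], fij_scaling=10.0,
                           chain=spec5.chain)
        spec5.fij_scaling = 5.0
        ch10 = gibbs_fit(build_design(ped, pheno, pset, spec10), ped, spec10)
        ch5 = gibbs_fit(build_design(ped, pheno, pset, spec5), ped, spec5)
        s10 = ch10.draws["sigma2_i"].mean()
        s5 = ch5.draws["sigma2_i"].mean()
        assert s5 / s10 == pytest.approx(4.0, rel=1e-3)
        d10 = summarize_posterior(ch10).frame.loc["d2", "mean"]
        d5 = summarize_posterior(ch5).frame.loc["d2", "mean"]
        assert d5 == pytest.approx(d10, rel=1e-3)


class TestPosteriorSummary:
    def test_table_ratio_arithmetic(self):
        comps = {"sigma2_u": 2.0, "sigma2_i": 1.0, "sigma2_h": 0.5,
                 "sigma2_r": 0.5, "sigma2_e": 1.0}
        r = variance_ratios(comps, "full")
        assert r["h2"] == pytest.approx(0.4)
        assert r["d2"] == pytest.approx(0.2)
        assert r["repeatability"] == pytest.approx(0.5)

    def test_ratios_within_unit_interval_per_draw(self):
        ped, pset, pheno, _, spec = small_recovery_setup(
            seed=3, length=3_000, burn_in=500, thinning=5)
        dm = build_design(ped, pheno, pset, spec)
        ch = gibbs_fit(dm, ped, spec)
        sp = ch.draws["sigma2_u"] + ch.draws["sigma2_i"] + ch.draws["sigma2_e"]
        h2 = ch.draws["sigma2_u"] / sp
        d2 = ch.draws["sigma2_i"] / sp
        assert ((h2 >= 0) & (h2 <= 1)).all()
        assert ((d2 >= 0) & (d2 <= 1)).all()
        assert ((h2 + d2) <= 1).all()

    def test_hpd_matches_percentiles_for_symmetric_sample(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(np.percentile(x, 2.5), abs=0.02)
        assert hi == pytest.approx(np.percentile(x, 97.5), abs=0.02)
        assert lo <= np.median(x) <= hi

    def test_short_chain_rejected(self):
        frame = pd.DataFrame({"sigma2_u": np.ones(10), "sigma_ui": 0.0,
                              "sigma2_i": np.ones(10),
                              "sigma2_e": np.ones(10)})
        from idload.model import GibbsChain
        chain = GibbsChain(draws=frame, u_mean=pd.Series(dtype=float),
                           i_mean=pd.Series(dtype=float),
                           spec=ModelSpec(trait="t", model_form="reduced"))
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(chain)
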