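"""Synthetic pedigrees and phenotypes with known truth.

The generator is the forward direction of the fitted model: a
generation-structured pedigree with a controllable rate of close (full- or
half-sib) matings creates recent and ancestral inbreeding; additive and IDL
effects are sampled jointly down the pedigree by bivariate Mendelian
sampling (founders ~ N(0, G), non-founders = parent mean + N(0, d_x G)),
exactly the N(0, G kron A) prior of the analysis model; records then follow

    y = f c + X b + W h + R r + Z u + K i + e

with K = T(I - P) built from the same partial-inbreeding decomposition used
at fitting time.  Ordinal defect-like traits are thresholded from the
latent Gaussian.  Everything is bitwise-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import idl_incidence
from .partial import PartialInbreedingSet, partial_inbreeding
from .pedigree import UNKNOWN, Pedigree, mendelian_variance
from .inbreeding import meuwissen_luo_F


@dataclass
class PedigreeSimConfig:
    """Generation-structured random-mating pedigree with close matings."""

    n_founders: int = 60
    n_generations: int = 5
    matings_per_generation: int = 54
    offspring_per_mating: int = 2
    close_mating_probability: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_generations,
               self.matings_per_generation, self.offspring_per_mating) < 1:
            raise ValueError("all counts must be positive")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0.0 <= self.close_mating_probability <= 1.0:
            raise ValueError("close_mating_probability must be in [0, 1]")


@dataclass
class VarianceTruth:
    """Variance components on the model's scales (IDL per 10% F_ij)."""

    sigma2_u: float = 0.3
    sigma_ui: float = 0.0
    sigma2_i: float = 2.0
    sigma2_h: float = 0.0
    sigma2_r: float = 0.0
    sigma2_e: float = 0.5
    c: float = -0.7

    @property
    def G(self) -> np.ndarray:
        return np.array([[self.sigma2_u, self.sigma_ui],
                         [self.sigma_ui, self.sigma2_i]])


@dataclass
class PhenotypeSimConfig:
    """Forward-model settings for one simulated trait."""

    components: VarianceTruth = field(default_factory=VarianceTruth)
    trait: str = "gait"
    kind: str = "continuous"            # "continuous" | "ordinal"
    mean: float = 6.5
    sex_effect: float = 0.2
    stud_size_effects: tuple = (0.0, 0.1, 0.25)
    age_slope: float = 0.05
    mean_records: float = 2.0           # >= 1; extra records ~ Poisson
    n_riders: int = 40
    ordinal_thresholds: tuple = (0.5, 1.5)
    fij_scaling: float = 10.0
    phenotyped: str = "nonfounders"     # or "all"
    seed: int = 0

    def __post_init__(self):
        G = self.components.G
        if np.linalg.eigvalsh(G)[0] <= 0:
            raise ValueError("G is not positive definite")
        if self.kind == "ordinal" and \
                np.any(np.diff(self.ordinal_thresholds) <= 0):
            raise ValueError("ordinal thresholds must be strictly increasing")


def simulate_pedigree(cfg: PedigreeSimConfig) -> Pedigree:
    """Generation-structured pedigree; close matings create inbreeding.

    With probability ``close_mating_probability`` a mating pairs a male with
    a full or half sister from the previous generation (when one exists);
    otherwise sire and dam are drawn at random from that generation.
    """
    rng = np.random.default_rng(cfg.seed)
    sire, dam, sex, year = [], [], [], []
    for _ in range(cfg.n_founders):
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        sex.append(1 if rng.random() < 0.5 else 2)
        year.append(2000)
    # founders with a forced sex balance
    sex[0], sex[1] = 1, 2
    prev = list(range(cfg.n_founders))
    for g in range(1, cfg.n_generations + 1):
        males = [x for x in prev if sex[x] == 1]
        females = [x for x in prev if sex[x] == 2]
        if not males or not females:
            raise ValueError("a generation lost one sex entirely; "
                             "increase founders or offspring")
        cur = []
        for _ in range(cfg.matings_per_generation):
            s = males[rng.integers(len(males))]
            d = None
            if rng.random() < cfg.close_mating_probability:
                sibs = [x for x in females
                        if (sire[x] != UNKNOWN and sire[x] == sire[s])
                        or (dam[x] != UNKNOWN and dam[x] == dam[s])]
                if sibs:
                    d = sibs[rng.integers(len(sibs))]
            if d is None:
                d = females[rng.integers(len(females))]
            for _k in range(cfg.offspring_per_mating):
                sire.append(s)
                dam.append(d)
                sex.append(1 if rng.random() < 0.5 else 2)
                year.append(2000 + g)
                cur.append(len(sire) - 1)
        prev = cur
    n = len(sire)
    return Pedigree(sire=np.array(sire), dam=np.array(dam),
                    ext_id=np.arange(1, n + 1, dtype=np.int64),
                    sex=np.array(sex, dtype=np.int8),
                    birth_year=np.array(year, dtype=float))


def sample_genetic_effects(ped: Pedigree, G: np.ndarray, F: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Joint (u, i) ~ N(0, G kron A) by bivariate Mendelian sampling.

    Founder pairs are N(0, G); a non-founder gets the parent average plus
    N(0, d_x G) with d_x the Mendelian-sampling variance.  Returns an
    (n, 2) array, column 0 additive, column 1 IDL.
    """
    L = np.linalg.cholesky(G)
    d = mendelian_variance(ped, F)
    out = np.zeros((ped.n, 2))
    noise = rng.standard_normal((ped.n, 2)) @ L.T
    for x in range(ped.n):
        mean = np.zeros(2)
        for p in (ped.sire[x], ped.dam[x]):
            if p != UNKNOWN:
                mean += 0.5 * out[p]
        out[x] = mean + np.sqrt(d[x]) * noise[x]
    return out


def simulate_phenotypes(ped: Pedigree, pset: PartialInbreedingSet,
                        cfg: PhenotypeSimConfig) -> tuple:
    """Phenotype table and truth record from the forward model."""
    rng = np.random.default_rng(cfg.seed)
    vc = cfg.components
    F = meuwissen_luo_F(ped)
    ui = sample_genetic_effects(ped, vc.G, F, rng)
    u, i_vals = ui[:, 0], ui[:, 1]
    Kanim = idl_incidence(ped, pset, cfg.fij_scaling)
    ki = Kanim @ i_vals                       # per-animal IDL contribution

    if cfg.phenotyped == "all":
        animals = np.arange(ped.n)
    else:
        animals = np.where(~ped.is_founder)[0]
    n_anim = len(animals)

    h = rng.standard_normal(n_anim) * np.sqrt(vc.sigma2_h)
    riders = rng.standard_normal(cfg.n_riders) * np.sqrt(vc.sigma2_r)
    stud = rng.integers(0, 3, size=n_anim)
    n_rec = 1 + rng.poisson(max(cfg.mean_records - 1.0, 0.0), size=n_anim)

    rows = []
    for a_pos, x in enumerate(animals):
        for _rec in range(n_rec[a_pos]):
            rider = int(rng.integers(cfg.n_riders))
            age = float(rng.integers(4, 16))
            latent = (cfg.mean
                      + vc.c * F[x]
                      + (cfg.sex_effect if ped.sex[x] == 1 else 0.0)
                      + cfg.stud_size_effects[stud[a_pos]]
                      + cfg.age_slope * (age - 9.0)
                      + h[a_pos] + riders[rider]
                      + u[x] + ki[x]
                      + rng.standard_normal() * np.sqrt(vc.sigma2_e))
            rows.append((ped.ext_id[x], ped.sex[x], ("S", "M", "L")[stud[a_pos]],
                         rider + 1, age, ped.birth_year[x], F[x], latent))
    df = pd.DataFrame(rows, columns=["animal", "sex", "stud_size", "rider",
                                     "age", "birth_year", "F", cfg.trait])
    if cfg.kind == "ordinal":
        edges = np.asarray(cfg.ordinal_thresholds, dtype=float)
        df[cfg.trait] = 1 + np.searchsorted(
            edges, df[cfg.trait].to_numpy() - cfg.mean)
    truth = {"components": vc, "u": u, "i": i_vals, "F": F, "h": h,
             "riders": riders, "ki": ki, "config": cfg}
    return df, truth


# -- canned fixtures -------------------------------------------------------

FIXTURES = ("tiny_trio", "fullsib_loop", "deep_loop",
            "recovery_small", "recovery_medium")


def _fixture_pedigree(rows) -> Pedigree:
    df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    return Pedigree.from_frame(df)


def make_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic canned scenarios shared across the test suites.

    * tiny_trio — two founders and their offspring.
    * fullsib_loop — full-sib mating: F = 0.25 split 0.125/0.125 over the
      two founder grandparents.
    * deep_loop — a single common ancestor seven meioses back: F > 0 but
      F6 = 0.
    * recovery_small — ~600-animal pedigree with ~1,200 records from the
      reduced model with known components, for sampler recovery checks.
    * recovery_medium — ~2,000 animals with rider and permanent-environment
      effects (full model).
    """
    if name == "tiny_trio":
        ped = _fixture_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        return {"pedigree": ped, "expected_F": np.array([0.0, 0.0, 0.0])}
    if name == "fullsib_loop":
        ped = _fixture_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2),
                                 (4, 1, 2), (5, 3, 4)])
        return {"pedigree": ped,
                "expected_F": np.array([0, 0, 0, 0, 0.25]),
                "expected_fij": {(5, 1): 0.125, (5, 2): 0.125}}
    if name == "deep_loop":
        rows = [(1, 0, 0)]
        nid = 1
        chain_a, chain_b = [1], [1]
        for _ in range(6):                      # two 6-deep descent lines
            nid += 1
            rows.append((nid, chain_a[-1], 0))
            chain_a.append(nid)
            nid += 1
            rows.append((nid, 0, chain_b[-1]))
            chain_b.append(nid)
        nid += 1
        rows.append((nid, chain_a[-1], chain_b[-1]))
        ped = _fixture_pedigree(rows)
        return {"pedigree": ped, "focal": nid,
                "expected_F_focal": 0.5 ** 13}
    if name in ("recovery_small", "recovery_medium"):
        medium = name == "recovery_medium"
        pcfg = PedigreeSimConfig(
            n_founders=80 if medium else 60,
            n_generations=6 if medium else 5,
            matings_per_generation=160 if medium else 54,
            offspring_per_mating=2,
            close_mating_probability=0.4,
            seed=1000 + seed)
        ped = simulate_pedigree(pcfg)
        pset = partial_inbreeding(ped)
        comp = VarianceTruth(sigma2_u=0.3, sigma_ui=0.0, sigma2_i=2.0,
                             sigma2_h=0.2 if medium else 0.0,
                             sigma2_r=0.15 if medium else 0.0,
                             sigma2_e=0.5, c=-0.7)
        scfg = PhenotypeSimConfig(components=comp, trait="gait",
                                  mean_records=2.2, seed=2000 + seed)
        pheno, truth = simulate_phenotypes(ped, pset, scfg)
        return {"pedigree": ped, "pset": pset, "phenotypes": pheno,
                "truth": truth,
                "model_form": "full" if medium else "reduced"}
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
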