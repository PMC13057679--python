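"""Bayesian animal model with ancestor-specific inbreeding depression load.

Phenotypes follow

    y = f c + X b + W h + R r + Z u + K i + e        (full form)
    y = f c + X b + Z u + K i + e                    (reduced form)

where f is the per-observation total inbreeding, c the global depression
slope, u the additive genetic values and i the ancestor-specific IDL effects
with joint prior (u, i) ~ N(0, G kron A).  IDL effects reach phenotypes
through K = T (I - P): T carries the (scaled) partial inbreeding coefficients
F_ij linking each inbred phenotyped animal to the ancestors causing its
inbreeding, and P links every animal to its sire and dam with 0.5 so that the
transmissible part of i is removed and only each ancestor's own load term
enters.  F_ij are multiplied by ``fij_scaling`` (default 10), putting the IDL
variance on a per-10%-partial-inbreeding reference scale.

The sampler is single-site Gibbs (see :mod:`idload._gibbs`), deterministic
per seed.  Posterior ratios are formed per draw: with total phenotypic
variance s_p^2 = s_u^2 + s_i^2 [+ s_h^2 + s_r^2] + s_e^2,
h^2 = s_u^2/s_p^2, d^2 = s_i^2/s_p^2 and repeatability = (s_u^2+s_h^2)/s_p^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ._gibbs import run_chain
from .inbreeding import meuwissen_luo_F
from .partial import PartialInbreedingSet
from .pedigree import UNKNOWN, Pedigree, build_a_inverse

VARCOMP_NAMES = ["sigma2_u", "sigma_ui", "sigma2_i",
                 "sigma2_h", "sigma2_r", "sigma2_e"]


@dataclass
class ChainConfig:
    """MCMC chain specification (desk-scale defaults)."""

    length: int = 50_000
    burn_in: int = 5_000
    thinning: int = 10
    seed: int = 0


@dataclass
class Priors:
    """Variance priors.

    Defaults are the improper flat choices: scaled-inv-chi-square(nu=-2,
    s2=0) on scalar variances and inverse Wishart(nu=-3, zero scale) on G —
    both flat on the variance scale.  Set positive nu/scales for proper
    priors at small n.
    """

    nu_e: float = -2.0
    s2_e: float = 0.0
    nu_h: float = -2.0
    s2_h: float = 0.0
    nu_r: float = -2.0
    s2_r: float = 0.0
    nu_g: float = -3.0
    Vg: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


@dataclass
class ModelSpec:
    """Trait, effect structure and chain settings for one analysis."""

    trait: str
    model_form: str = "full"            # "full" (with h, r) | "reduced"
    fixed_effects: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    animal_col: str = "animal"
    rider_col: str = "rider"
    fij_scaling: float = 10.0
    chain: ChainConfig = field(default_factory=ChainConfig)

    def __post_init__(self):
        if self.model_form not in ("full", "reduced"):
            raise ValueError("model_form must be 'full' or 'reduced'")
        if self.fij_scaling <= 0:
            raise ValueError("fij_scaling must be positive")


@dataclass
class DesignMatrices:
    y: np.ndarray
    f: np.ndarray
    X: sparse.csc_matrix          # fixed effects + covariates + f (c last)
    x_names: list
    W: sparse.csc_matrix | None   # permanent environment (full form)
    R: sparse.csc_matrix | None   # rider (full form)
    Z: sparse.csc_matrix          # obs -> animal
    K: sparse.csc_matrix          # obs -> ancestor IDL, = Z T (I - P)
    obs_animal: np.ndarray
    n_animals: int
    h_levels: np.ndarray | None = None
    r_levels: np.ndarray | None = None


def idl_incidence(ped: Pedigree, pset: PartialInbreedingSet,
                  fij_scaling: float = 10.0) -> sparse.csr_matrix:
    """Animal-level IDL incidence K = T (I - P) over all pedigree animals."""
    n = ped.n
    ent = pset.entries
    T = sparse.coo_matrix(
        (ent["fij"].to_numpy(dtype=float) * fij_scaling,
         (ent["animal_idx"].to_numpy(dtype=np.int64),
          ent["ancestor_idx"].to_numpy(dtype=np.int64))),
        shape=(n, n)).tocsr()
    rows, cols, vals = [], [], []
    for x in range(n):
        for p in (ped.sire[x], ped.dam[x]):
            if p != UNKNOWN:
                rows.append(x)
                cols.append(p)
                vals.append(0.5)
    P = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return (T @ (sparse.identity(n, format="csr") - P)).tocsr()


def _incidence(codes: np.ndarray, n_levels: int) -> sparse.csc_matrix:
    n = len(codes)
    return sparse.coo_matrix((np.ones(n), (np.arange(n), codes)),
                             shape=(n, n_levels)).tocsc()


def build_design(ped: Pedigree, phenotypes: pd.DataFrame,
                 pset: PartialInbreedingSet, spec: ModelSpec,
                 F: np.ndarray | None = None) -> DesignMatrices:
    """Assemble y, f, X, W, R, Z and K for one trait.

    Fixed factors are dummy-coded with the first level dropped (an intercept
    column is always present); single-level factors are dropped with a
    warning.  K rows of non-inbred animals are exactly zero.
    """
    if F is None:
        F = meuwissen_luo_F(ped)
    df = phenotypes
    missing = sorted({int(a) for a in df[spec.animal_col]
                      if int(a) not in ped.index})
    if missing:
        raise ValueError(f"phenotyped animals missing from pedigree: "
                         f"{missing[:20]}")
    obs_animal = np.array([ped.index[int(a)] for a in df[spec.animal_col]],
                          dtype=np.int64)
    y = df[spec.trait].to_numpy(dtype=float)
    f = F[obs_animal]

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in spec.fixed_effects:
        cat = pd.Categorical(df[fac])
        if len(cat.categories) < 2:
            warnings.warn(f"factor '{fac}' has a single level; dropped")
            continue
        dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
        for lev in dummies.columns:
            cols.append(dummies[lev].to_numpy())
            names.append(f"{fac}[{lev}]")
    for cov in spec.covariates:
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    if np.any(f != 0.0):
        cols.append(f)
        names.append("c")
    else:
        warnings.warn("no inbred phenotyped animal; depression covariate c "
                      "dropped")
    X = sparse.csc_matrix(np.column_stack(cols))

    W = R = None
    h_levels = r_levels = None
    if spec.model_form == "full":
        h_levels, h_codes = np.unique(obs_animal, return_inverse=True)
        W = _incidence(h_codes, len(h_levels))
        r_levels, r_codes = np.unique(
            df[spec.rider_col].to_numpy(), return_inverse=True)
        R = _incidence(r_codes, len(r_levels))

    Z = _incidence(obs_animal, ped.n)
    Kanim = idl_incidence(ped, pset, spec.fij_scaling)
    K = (Z.tocsr() @ Kanim).tocsc()
    return DesignMatrices(y=y, f=f, X=X, x_names=names, W=W, R=R, Z=Z, K=K,
                          obs_animal=obs_animal, n_animals=ped.n,
                          h_levels=h_levels, r_levels=r_levels)


@dataclass
class GibbsChain:
    """Thinned post-burn-in draws plus posterior-mean animal effects."""

    draws: pd.DataFrame           # betas (incl. c) and variance components
    u_mean: pd.Series             # posterior-mean EBV per animal (ext id)
    i_mean: pd.Series             # posterior-mean IDL per animal (ext id)
    spec: ModelSpec

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def running_means(self) -> pd.DataFrame:
        """Running posterior means along the chain (convergence check)."""
        return self.draws.expanding().mean()


def gibbs_fit(dm: DesignMatrices, ped: Pedigree, spec: ModelSpec,
              priors: Priors | None = None,
              F: np.ndarray | None = None) -> GibbsChain:
    """Fit the model by single-site Gibbs sampling; deterministic per seed."""
    if priors is None:
        priors = Priors()
    if dm.n_animals > 0:
        if F is None:
            F = meuwissen_luo_F(ped)
        Ainv = build_a_inverse(ped, F)
    else:  # degenerate model without genetic effects
        Ainv = sparse.csr_matrix((0, 0), dtype=float)

    blocks = [dm.X]
    n_h = n_r = 0
    if dm.W is not None:
        blocks.append(dm.W)
        n_h = dm.W.shape[1]
    if dm.R is not None:
        blocks.append(dm.R)
        n_r = dm.R.shape[1]
    blocks += [dm.Z, dm.K]
    M = sparse.hstack(blocks).tocsc()
    css = np.asarray(M.multiply(M).sum(axis=0)).ravel()
    p_beta = dm.X.shape[1]
    if np.any(css[:p_beta] == 0):
        raise ValueError("empty fixed-effect column in design")

    cc = spec.chain
    vary = float(np.var(dm.y))
    draws, u_mean, i_mean, status = run_chain(
        dm.y.astype(float), M.indptr, M.indices, M.data, css,
        p_beta, n_h, n_r, dm.n_animals,
        Ainv.indptr, Ainv.indices, Ainv.data,
        cc.length, cc.burn_in, cc.thinning, cc.seed,
        priors.nu_e, priors.s2_e, priors.nu_h, priors.s2_h,
        priors.nu_r, priors.s2_r,
        priors.nu_g, float(priors.Vg[0, 0]), float(priors.Vg[0, 1]),
        float(priors.Vg[1, 1]),
        0.5 * vary, 0.0, 0.5 * vary,      # G init
        0.5 * vary, 0.25 * vary, 0.25 * vary)  # sigma_e, sigma_h, sigma_r init
    if status != 0:
        raise RuntimeError("Gibbs sampler diverged (residual variance left "
                           "the representable range); check the model or "
                           "use proper priors")
    colnames = dm.x_names + VARCOMP_NAMES
    frame = pd.DataFrame(draws, columns=colnames)
    if dm.W is None:
        frame = frame.drop(columns=["sigma2_h", "sigma2_r"])
    if dm.n_animals == 0:
        frame = frame.drop(columns=["sigma2_u", "sigma_ui", "sigma2_i"])
    idx = ped.ext_id if dm.n_animals > 0 else []
    return GibbsChain(draws=frame,
                      u_mean=pd.Series(u_mean, index=idx, dtype=float),
                      i_mean=pd.Series(i_mean, index=idx, dtype=float),
                      spec=spec)


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple:
    """Shortest interval containing ``prob`` of the sample mass."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[k:] - xs[:n - k]
    j = int(np.argmin(widths))
    return float(xs[j]), float(xs[j + k])


def variance_ratios(components: dict, model_form: str = "full",
                    fij_scaling: float = 10.0) -> dict:
    """h2, d2 and repeatability from one set of variance components.

    ``components`` holds sigma2_u, sigma2_i, sigma2_e and, for the full
    form, sigma2_h and sigma2_r.  The IDL variance is put on the
    10%-partial-inbreeding reference via the factor (0.1 * fij_scaling)^2 —
    the identity at the default scaling of 10 — which makes the ratios
    invariant to the arbitrary F_ij multiplier.
    """
    s2i = components["sigma2_i"] * (0.1 * fij_scaling) ** 2
    sp = components["sigma2_u"] + s2i + components["sigma2_e"]
    if model_form == "full":
        sp += components["sigma2_h"] + components["sigma2_r"]
    out = {"h2": components["sigma2_u"] / sp, "d2": s2i / sp}
    if model_form == "full":
        out["repeatability"] = (components["sigma2_u"]
                                + components["sigma2_h"]) / sp
    return out


@dataclass
class PosteriorSummary:
    """Mean, SD, median and HPD95 per parameter, plus derived ratios."""

    frame: pd.DataFrame

    def __getitem__(self, name):
        return self.frame.loc[name]


def summarize_posterior(chain: GibbsChain, prob: float = 0.95
                        ) -> PosteriorSummary:
    """Posterior summaries with per-draw derived ratios.

    Ratios are computed draw by draw (a posterior mean of a ratio, not a
    ratio of posterior means) and summarised like every other parameter.
    """
    if chain.n_draws < 100:
        raise ValueError("need at least 100 post-burn-in draws to summarise")
    d = chain.draws.copy()
    full = chain.spec.model_form == "full"
    # IDL variance on the per-10%-partial-inbreeding reference
    s2i = d["sigma2_i"] * (0.1 * chain.spec.fij_scaling) ** 2
    sp = d["sigma2_u"] + s2i + d["sigma2_e"]
    if full:
        sp = sp + d["sigma2_h"] + d["sigma2_r"]
    d["h2"] = d["sigma2_u"] / sp
    d["d2"] = s2i / sp
    if full:
        d["repeatability"] = (d["sigma2_u"] + d["sigma2_h"]) / sp

    rows = {}
    for name in d.columns:
        x = d[name].to_numpy()
        lo, hi = hpd_interval(x, prob)
        rows[name] = {"mean": float(np.mean(x)), "sd": float(np.std(x)),
                      "median": float(np.median(x)),
                      "hpd_low": lo, "hpd_high": hi}
    return PosteriorSummary(pd.DataFrame(rows).T)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by initial-positive-sequence autocorrelation truncation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 2):
        rho = np.dot(x[:-lag], x[lag:]) / (n * var)
        if rho <= 0:
            break
        acf_sum += rho
    return n / (1.0 + 2.0 * acf_sum)
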