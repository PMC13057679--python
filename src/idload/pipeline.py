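"""End-to-end orchestration: simulate -> coeffs -> partial -> regress ->
fit -> idl-report -> index, driven by a single configuration mapping.

Each stage reads its inputs from the output directory (or produces them
upstream), is idempotent per seed, and is recorded in a machine-readable
run manifest with file digests, seeds and per-stage runtimes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (HIGHER, LOWER, IdlProfile, cohort_trends,
                       favorable_proportion, favorable_threshold,
                       idl_correlations)
from .inbreeding import coefficient_table
from .model import (ChainConfig, ModelSpec, build_design, gibbs_fit,
                    summarize_posterior)
from .partial import partial_inbreeding, PartialInbreedingSet
from .pedigree import read_pedigree, write_pedigree
from .regression import depression_regression
from .selection import IndexScenario, expected_response, weight_sweep
from .synthetic import (PedigreeSimConfig, PhenotypeSimConfig, VarianceTruth,
                        simulate_pedigree, simulate_phenotypes)

log = logging.getLogger("idload")

STAGES = ["simulate", "coeffs", "partial", "regress", "fit", "idl_report",
          "index"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    config: dict
    seeds: dict = field(default_factory=dict)
    runtimes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "version": self.version, "config": self.config,
            "seeds": self.seeds, "runtimes": self.runtimes,
            "outputs": self.outputs}, indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, outdir=None, stages=None) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` is a mapping (or a YAML path).  Re-running with the same
    configuration and seeds reproduces identical outputs; a stage whose
    inputs are missing raises :class:`StageError` naming the file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "idload_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or config.get("stages", STAGES)
    manifest = RunManifest(version=__version__, config=config)

    def record(name: str, *paths: Path):
        for p in paths:
            manifest.outputs[str(p)] = _digest(p)
        log.info("stage %s done: %s", name, ", ".join(str(p) for p in paths))

    def need(stage: str, path: Path) -> Path:
        if not path.exists():
            raise StageError(stage, f"required input {path} is missing")
        return path

    ped_csv = outdir / "pedigree.csv"
    pheno_csv = outdir / "phenotypes.csv"
    coeff_csv = outdir / "coeffs.csv"
    fij_csv = outdir / "fij.csv"

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            scfg = config.get("simulate", {})
            seed = int(scfg.get("seed", 0))
            manifest.seeds["simulate"] = seed
            pcfg = PedigreeSimConfig(seed=seed,
                                     **scfg.get("pedigree", {}))
            ped = simulate_pedigree(pcfg)
            write_pedigree(ped, ped_csv)
            comp = VarianceTruth(**scfg.get("components", {}))
            phcfg = PhenotypeSimConfig(components=comp, seed=seed + 1,
                                       **scfg.get("phenotypes", {}))
            pset = partial_inbreeding(ped)
            pheno, truth = simulate_phenotypes(ped, pset, phcfg)
            pheno.to_csv(pheno_csv, index=False)
            (outdir / "truth.json").write_text(json.dumps(
                {"components": vars(comp)}, indent=2))
            record(stage, ped_csv, pheno_csv, outdir / "truth.json")
        elif stage == "coeffs":
            ped = read_pedigree(need(stage, ped_csv))
            seed = int(config.get("coeffs", {}).get("seed", 0))
            reps = int(config.get("coeffs", {}).get("fk_replicates", 10_000))
            manifest.seeds["coeffs"] = seed
            coefficient_table(ped, fk_replicates=reps, seed=seed
                              ).to_csv(coeff_csv)
            record(stage, coeff_csv)
        elif stage == "partial":
            ped = read_pedigree(need(stage, ped_csv))
            thr = float(config.get("partial", {}).get("threshold", 1e-5))
            pset = partial_inbreeding(ped, threshold=thr)
            pset.to_csv(fij_csv)
            record(stage, fij_csv)
        elif stage == "regress":
            rcfg = config.get("regress", {})
            pheno = pd.read_csv(need(stage, pheno_csv))
            coeffs = pd.read_csv(need(stage, coeff_csv))
            trait = rcfg.get("trait", config.get("trait", "gait"))
            model = rcfg.get("model", "linear")
            per_animal = pheno.groupby("animal")[trait].mean()
            merged = coeffs.set_index("id").join(per_animal, how="inner")
            rows = []
            for coeff in ("F", "F6", "Fk"):
                res = depression_regression(
                    merged[trait].to_numpy(), merged[coeff].to_numpy(), model)
                rows.append({"trait": trait, "coefficient": coeff,
                             "b": res.coefficient, "se": res.standard_error,
                             "t_or_z": res.t_or_z, "p": res.p_value,
                             "n": res.n})
            pd.DataFrame(rows).to_csv(outdir / "regressions.csv", index=False)
            record(stage, outdir / "regressions.csv")
        elif stage == "fit":
            fcfg = config.get("fit", {})
            ped = read_pedigree(need(stage, ped_csv))
            pheno = pd.read_csv(need(stage, pheno_csv))
            pset = partial_inbreeding(ped)
            chain_cfg = ChainConfig(**fcfg.get("chain", {}))
            manifest.seeds["fit"] = chain_cfg.seed
            spec = ModelSpec(trait=fcfg.get("trait",
                                            config.get("trait", "gait")),
                             model_form=fcfg.get("model_form", "reduced"),
                             fixed_effects=fcfg.get(
                                 "fixed_effects", ["sex", "stud_size"]),
                             covariates=fcfg.get("covariates", ["age"]),
                             chain=chain_cfg)
            dm = build_design(ped, pheno, pset, spec)
            chain = gibbs_fit(dm, ped, spec)
            chain.draws.to_csv(outdir / "chain.csv", index=False)
            summarize_posterior(chain).frame.to_csv(outdir / "posterior.csv")
            pd.DataFrame({"id": chain.u_mean.index,
                          "ebv": chain.u_mean.to_numpy(),
                          "idl": chain.i_mean.to_numpy()}
                         ).to_csv(outdir / "animal_effects.csv", index=False)
            record(stage, outdir / "chain.csv", outdir / "posterior.csv",
                   outdir / "animal_effects.csv")
        elif stage == "idl_report":
            acfg = config.get("idl_report", {})
            eff = pd.read_csv(need(stage, outdir / "animal_effects.csv"))
            coeffs = pd.read_csv(need(stage, coeff_csv))
            ped_df = pd.read_csv(need(stage, ped_csv))
            trait = acfg.get("trait", config.get("trait", "gait"))
            direction = acfg.get("direction", HIGHER)
            ref = float(acfg.get("reference_f", 0.10))
            merged = eff.merge(coeffs[["id", "F", "F6"]], on="id")
            thr, slope, intercept = favorable_threshold(
                merged["idl"].to_numpy(), merged["F"].to_numpy(), ref)
            n_fav, pct = favorable_proportion(merged["idl"].to_numpy(), thr,
                                              direction)
            profile = IdlProfile(merged.set_index("id")[["idl"]].rename(
                columns={"idl": trait}), {trait: direction})
            corr, coin = idl_correlations(profile, {trait: thr})
            trends = cohort_trends(
                merged.merge(ped_df[["id", "birth_year"]], on="id")
                [["birth_year", "F6", "ebv", "idl"]])
            pd.DataFrame([{"trait": trait, "threshold": thr, "slope": slope,
                           "intercept": intercept, "n_favorable": n_fav,
                           "pct_favorable": pct}]).to_csv(
                outdir / "thresholds.csv", index=False)
            trends.to_csv(outdir / "cohort_trends.csv", index=False)
            record(stage, outdir / "thresholds.csv",
                   outdir / "cohort_trends.csv")
        elif stage == "index":
            icfg = config.get("index", {})
            post_path = outdir / "posterior.csv"
            if post_path.exists() and "h2" not in icfg:
                post = pd.read_csv(post_path, index_col=0)
                h2 = float(post.loc["h2", "mean"])
                g = post.loc[["sigma2_u", "sigma_ui", "sigma2_i"], "mean"]
                r = float(g["sigma_ui"]
                          / np.sqrt(g["sigma2_u"] * g["sigma2_i"]))
            else:
                h2 = float(icfg.get("h2", 0.1))
                r = float(icfg.get("r_ebv_idl", 0.0))
            scen = IndexScenario(h2=h2, r_ebv_idl=np.clip(r, -1.0, 1.0))
            rows = []
            for itype in (1, 2):
                res = expected_response(scen, itype)
                rows.append({"index": itype, "w_ebv": 1.0, "w_idl": 0.0,
                             "egr": res.egr,
                             "relative_vs_index1": res.relative_vs_index1})
            sweep = weight_sweep(scen)
            for _, row in sweep.iterrows():
                rows.append({"index": 3, "w_ebv": row.w_ebv,
                             "w_idl": row.w_idl, "egr": row.egr,
                             "relative_vs_index1": row.relative_vs_index1})
            pd.DataFrame(rows).to_csv(outdir / "indices.csv", index=False)
            record(stage, outdir / "indices.csv")
        else:
            raise StageError(stage, "unknown stage")
        manifest.runtimes[stage] = round(time.perf_counter() - t0, 3)

    manifest.to_json(outdir / "manifest.json")
    return manifest
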