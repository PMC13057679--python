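"""Shared configuration for the numbered analysis scripts.

The synthetic study population emulates the structure of a closed sport-horse
studbook: a multi-generation pedigree with a substantial rate of close
matings (hence nonzero recent and ancestral inbreeding), one continuous
gait-like trait with repeated records, rider and permanent-environment
effects, and one ordinal 1-3 defect-like trait scored once per animal.
"""

from pathlib import Path

import idload as il

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY = RESULTS / "study"

SEED = 20250930

PEDIGREE_CFG = il.PedigreeSimConfig(
    n_founders=80, n_generations=6, matings_per_generation=160,
    offspring_per_mating=2, close_mating_probability=0.4, seed=SEED)

GAIT_COMPONENTS = il.VarianceTruth(
    sigma2_u=0.06, sigma_ui=-0.1, sigma2_i=2.7, sigma2_h=0.13,
    sigma2_r=0.17, sigma2_e=0.28, c=-0.7)

DEFECT_COMPONENTS = il.VarianceTruth(
    sigma2_u=0.07, sigma_ui=0.03, sigma2_i=0.09, sigma2_h=0.0,
    sigma2_r=0.0, sigma2_e=0.29, c=0.5)

GAIT_CFG = il.PhenotypeSimConfig(
    components=GAIT_COMPONENTS, trait="gait", kind="continuous", mean=6.5,
    mean_records=2.5, n_riders=60, seed=SEED + 1)

DEFECT_CFG = il.PhenotypeSimConfig(
    components=DEFECT_COMPONENTS, trait="closed_hock", kind="ordinal",
    mean=0.0, sex_effect=0.1, stud_size_effects=(0.0, 0.05, 0.1),
    age_slope=0.02, mean_records=1.0, ordinal_thresholds=(0.7, 1.7),
    seed=SEED + 2)

CHAIN = dict(length=50_000, burn_in=5_000, thinning=10)
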