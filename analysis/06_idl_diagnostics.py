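"""IDL population diagnostics.

Favourable-IDL thresholds at a 10% reference inbreeding, favourable
proportions, cross-trait Pearson correlation with coincident-favourable
counts, and birth-cohort trends of F6, EBV and IDL.
"""

import pandas as pd

from idload.analysis import (HIGHER, LOWER, IdlProfile, cohort_trends,
                             favorable_proportion, favorable_threshold,
                             idl_correlations)
from idload.pedigree import read_pedigree

from study import STUDY

DIRECTIONS = {"gait": HIGHER, "closed_hock": LOWER}


def main():
    coeffs = pd.read_csv(STUDY / "coefficients.csv").set_index("id")
    ped_df = read_pedigree(STUDY / "pedigree.csv").to_frame().set_index("id")

    idl = {}
    thresholds = {}
    rows = []
    for trait in DIRECTIONS:
        eff = pd.read_csv(STUDY / f"effects_{trait}.csv").set_index("id")
        merged = eff.join(coeffs[["F", "F6"]])
        thr, slope, intercept = favorable_threshold(
            merged["idl"].to_numpy(), merged["F"].to_numpy(), 0.10)
        n_fav, pct = favorable_proportion(merged["idl"].to_numpy(), thr,
                                          DIRECTIONS[trait])
        idl[trait] = eff["idl"]
        thresholds[trait] = thr
        rows.append({"trait": trait, "direction": DIRECTIONS[trait],
                     "threshold_at_10pct_F": thr, "slope": slope,
                     "n_favorable": n_fav, "pct_favorable": pct})
    thr_table = pd.DataFrame(rows)
    thr_table.to_csv(STUDY / "idl_thresholds.csv", index=False)
    print(thr_table.round(4).to_string(index=False))

    profile = IdlProfile(pd.DataFrame(idl), DIRECTIONS)
    corr, coincident = idl_correlations(profile, thresholds)
    corr.to_csv(STUDY / "idl_correlations.csv")
    coincident.to_csv(STUDY / "idl_coincidence.csv", index=False)
    print("\nIDL Pearson correlations:")
    print(corr.round(3).to_string())
    print("\ncoincident favourable animals per pair:")
    print(coincident.round(3).to_string(index=False))

    eff = pd.read_csv(STUDY / "effects_gait.csv").set_index("id")
    trend_in = eff.join(coeffs[["F6"]]).join(ped_df[["birth_year"]])
    trends = cohort_trends(trend_in.reset_index(drop=True))
    trends.to_csv(STUDY / "cohort_trends.csv", index=False)
    print("\ncohort means (gait):")
    print(trends.pivot(index="cohort", columns="quantity",
                       values="mean_value").round(4).to_string())


if __name__ == "__main__":
    main()
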