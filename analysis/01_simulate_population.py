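"""Simulate the synthetic study population.

Writes the pedigree, the two phenotype tables (continuous gait trait with
repeated records; ordinal 1-3 hock-defect trait) and the true simulation
parameters under results/study/.
"""

import json

import idload as il
from idload.partial import partial_inbreeding
from idload.pedigree import write_pedigree

from study import DEFECT_CFG, GAIT_CFG, PEDIGREE_CFG, STUDY


def main():
    STUDY.mkdir(parents=True, exist_ok=True)
    ped = il.simulate_pedigree(PEDIGREE_CFG)
    write_pedigree(ped, STUDY / "pedigree.csv")
    pset = partial_inbreeding(ped)

    gait, gait_truth = il.simulate_phenotypes(ped, pset, GAIT_CFG)
    gait.to_csv(STUDY / "gait_phenotypes.csv", index=False)
    defect, defect_truth = il.simulate_phenotypes(ped, pset, DEFECT_CFG)
    defect.to_csv(STUDY / "defect_phenotypes.csv", index=False)

    truth = {"gait": vars(gait_truth["config"].components),
             "closed_hock": vars(defect_truth["config"].components)}
    (STUDY / "truth.json").write_text(json.dumps(truth, indent=2))

    F = gait_truth["F"]
    print(f"pedigree: {ped.n} animals, {int(ped.is_founder.sum())} founders, "
          f"max depth {ped.stats()['max_depth']}")
    print(f"inbred animals: {(F > 0).sum()} ({100 * (F > 0).mean():.1f}%), "
          f"mean F among inbred {F[F > 0].mean():.4f}")
    print(f"gait records: {len(gait)} on {gait.animal.nunique()} animals; "
          f"defect scores: {len(defect)}")
    print("class mix (defect):",
          defect.closed_hock.value_counts(normalize=True).round(3).to_dict())


if __name__ == "__main__":
    main()
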