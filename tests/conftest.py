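import numpy as np
import pandas as pd
import pytest

import idload as il
from idload.pedigree import Pedigree


def small_pedigree(rows):
    """Pedigree from (id, sire, dam) tuples."""
    return Pedigree.from_frame(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def random_pedigree(seed, *, n_generations=4, founders=20, matings=18,
                    close=0.3):
    """Simulated pedigree of <= 200 animals with nonzero inbreeding."""
    cfg = il.PedigreeSimConfig(n_founders=founders,
                               n_generations=n_generations,
                               matings_per_generation=matings,
                               offspring_per_mating=2,
                               close_mating_probability=close, seed=seed)
    return il.simulate_pedigree(cfg)


def mask_parents(ped, seed, prob=0.15):
    """Copy of ``ped`` with some known parents re-coded unknown, to exercise
    the single-known-parent Mendelian-variance convention."""
    rng = np.random.default_rng(seed)
    df = ped.to_frame()
    for col in ("sire", "dam"):
        known = df[col] != 0
        drop = known & (rng.random(len(df)) < prob)
        df.loc[drop, col] = 0
    return Pedigree.from_frame(df[["id", "sire", "dam"]])


@pytest.fixture(scope="session")
def trio():
    return il.make_fixture("tiny_trio")["pedigree"]


@pytest.fixture(scope="session")
def fullsib():
    return il.make_fixture("fullsib_loop")


@pytest.fixture(scope="session")
def parent_offspring():
    # animal 4 = founder sire 1 mated to his daughter 3
    return small_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 3)])


@pytest.fixture(scope="session")
def deep_loop():
    return il.make_fixture("deep_loop")


@pytest.fixture(scope="session")
def recovery_small():
    return il.make_fixture("recovery_small")
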