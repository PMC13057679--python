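"""Decomposition of F into per-ancestor partial inbreeding coefficients F_ij.

Using A = L D L' (L the genome-contribution matrix, D the diagonal of
Mendelian-sampling variances) the inbreeding of animal i decomposes exactly as

    F_i = 0.5 * a(sire_i, dam_i) = sum_j  0.5 * d_j * L_{sire(i),j} * L_{dam(i),j}

with one term per common ancestor j of the two parents.  Founders contribute
through their founder term (d = 1) and non-founders through their
Mendelian-sampling term, realising the Garcia-Cortes partition
deterministically: the per-ancestor terms are non-negative and sum to F_i
exactly, which is the module's primary test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inbreeding import l_row, meuwissen_luo_F
from .pedigree import UNKNOWN, Pedigree, mendelian_variance

#: the default reporting cut for tiny coefficients
DEFAULT_THRESHOLD = 1e-5


@dataclass
class PartialInbreedingSet:
    """Sparse (animal, ancestor, F_ij) triplets above a reporting threshold.

    ``entries`` holds external ids in ``animal``/``ancestor`` and internal
    indices in ``animal_idx``/``ancestor_idx``; ``discarded`` is the
    per-animal F_ij mass dropped by the threshold, so that
    ``entries`` grouped sum + ``discarded`` reproduces F exactly.
    """

    entries: pd.DataFrame
    threshold: float
    discarded: pd.Series = field(repr=False)
    n_animals: int = 0

    def per_animal_sum(self, *, include_discarded: bool = True) -> pd.Series:
        s = self.entries.groupby("animal_idx")["fij"].sum()
        s = s.reindex(range(self.n_animals), fill_value=0.0)
        if include_discarded:
            s = s.add(self.discarded.reindex(s.index, fill_value=0.0))
        return s

    def to_csv(self, path) -> None:
        self.entries[["animal", "ancestor", "fij"]].to_csv(path, index=False)


def partial_inbreeding(ped: Pedigree, F: np.ndarray | None = None,
                       threshold: float = DEFAULT_THRESHOLD
                       ) -> PartialInbreedingSet:
    """Per-ancestor partition of every animal's inbreeding coefficient.

    ``F`` must come from :func:`idload.inbreeding.meuwissen_luo_F` on the same
    pedigree (recomputed when omitted); a mismatch is rejected because the
    ancestor Mendelian terms depend on it.  Entries <= ``threshold`` are
    dropped from storage but kept in the per-animal discarded mass; the
    decomposition is always exact pre-threshold.
    """
    if F is None:
        F = meuwissen_luo_F(ped)
    F = np.asarray(F, dtype=float)
    if F.shape != (ped.n,):
        raise ValueError("F vector does not match the pedigree")
    d = mendelian_variance(ped, F)

    rows: list[tuple] = []
    discarded = np.zeros(ped.n)
    lcache: dict[int, dict] = {}

    def lrow(x):
        r = lcache.get(x)
        if r is None:
            r = lcache[x] = l_row(ped, x)
        return r

    for i in range(ped.n):
        s, dm = ped.sire[i], ped.dam[i]
        if s == UNKNOWN or dm == UNKNOWN:
            continue
        Ls, Ld = lrow(s), lrow(dm)
        if len(Ld) < len(Ls):
            Ls, Ld = Ld, Ls
        total = 0.0
        for j, ls in Ls.items():
            ld = Ld.get(j)
            if ld is None:
                continue
            fij = 0.5 * d[j] * ls * ld
            if fij <= 0.0:
                continue
            total += fij
            if fij > threshold:
                rows.append((ped.ext_id[i], ped.ext_id[j], i, j, fij))
            else:
                discarded[i] += fij
        if abs(total - F[i]) > 1e-8:
            raise ValueError(
                f"F vector inconsistent with pedigree at animal "
                f"{ped.ext_id[i]}: decomposition {total} vs F {F[i]}")

    entries = pd.DataFrame(rows, columns=["animal", "ancestor",
                                          "animal_idx", "ancestor_idx", "fij"])
    return PartialInbreedingSet(entries=entries, threshold=threshold,
                                discarded=pd.Series(discarded),
                                n_animals=ped.n)


def ancestor_summary(pset: PartialInbreedingSet) -> pd.DataFrame:
    """Per-ancestor descendant counts and total contributed load.

    One row per ancestor appearing in the retained entries, sorted by
    descending descendant count.
    """
    if pset.entries.empty:
        raise ValueError("partial inbreeding set is empty")
    g = pset.entries.groupby("ancestor")["fij"]
    out = pd.DataFrame({"n_descendants": g.size(), "total_load": g.sum()})
    out = out.sort_values("n_descendants", ascending=False).reset_index()
    return out
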