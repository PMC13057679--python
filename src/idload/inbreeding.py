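"""Per-animal inbreeding coefficients: F, recent F6 and ancestral Fk.

* ``meuwissen_luo_F`` — Wright's coefficient through the sparse A = L D L'
  decomposition: F_x = 0.5 a(sire, dam) = 0.5 * sum_j d_j L_sj L_dj, computed
  by per-animal ancestor traversal without ever forming the dense A.
* ``six_generation_F`` — F on the pedigree truncated six meioses behind each
  animal, capturing recent inbreeding only.
* ``kalinowski_Fk`` — Monte-Carlo gene dropping estimate of the probability
  that an animal is autozygous for an allele that was already identical by
  descent in a strict ancestor.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, truncate_generations


def l_row(ped: Pedigree, x: int) -> dict:
    """Sparse row x of L in A = L D L': expected genome contributions.

    Returns ``{ancestor_or_self: L_xj}`` with L_xx = 1 and
    L_xj = 0.5 (L_sire(x),j + L_dam(x),j).  Computed by walking coefficients
    upward in decreasing topological order.
    """
    out: dict = {}
    coeff = {x: 1.0}
    heap = [-x]
    while heap:
        y = -heapq.heappop(heap)
        c = coeff.pop(y, None)
        if c is None:  # already drained (duplicate heap entry)
            continue
        out[y] = c
        for p in (ped.sire[y], ped.dam[y]):
            if p != UNKNOWN:
                if p not in coeff:
                    heapq.heappush(heap, -p)
                    coeff[p] = 0.0
                coeff[p] += 0.5 * c
    return out


def meuwissen_luo_F(ped: Pedigree) -> np.ndarray:
    """Wright inbreeding coefficients by the Meuwissen–Luo traversal.

    Animals with any unknown parent get F = 0.  Ancestor Mendelian terms d_j
    use the F values of earlier animals, available because the pedigree is
    topologically ordered.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.ones(n)  # running Mendelian-sampling variances
    for x in range(n):
        s, dm = ped.sire[x], ped.dam[x]
        if s != UNKNOWN and dm != UNKNOWN:
            d[x] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN:
            d[x] = 0.75 - 0.25 * F[s]
        elif dm != UNKNOWN:
            d[x] = 0.75 - 0.25 * F[dm]
        if s == UNKNOWN or dm == UNKNOWN:
            continue
        Ls = l_row(ped, s)
        Ld = l_row(ped, dm)
        if len(Ld) < len(Ls):
            Ls, Ld = Ld, Ls
        a_sd = 0.0
        for j, ls in Ls.items():
            ld = Ld.get(j)
            if ld is not None:
                a_sd += d[j] * ls * ld
        F[x] = 0.5 * a_sd
    return F


def six_generation_F(ped: Pedigree, depth: int = 6) -> np.ndarray:
    """Recent inbreeding: F on the per-animal pedigree truncated at ``depth``.

    Equals F wherever the full ancestor pedigree is shallower than ``depth``;
    inbreeding loops closing beyond ``depth`` meioses contribute nothing.
    """
    F = meuwissen_luo_F(ped)
    F6 = np.zeros(ped.n)
    for x in range(ped.n):
        if F[x] == 0.0:
            continue  # truncation can only remove inbreeding paths
        sub = truncate_generations(ped, ped.ext_id[x], depth)
        F6[x] = meuwissen_luo_F(sub)[sub.internal(ped.ext_id[x])]
    return F6


@dataclass
class CoefficientTable:
    """Per-animal F, F6 and Kalinowski Fk with its Monte-Carlo error."""

    frame: pd.DataFrame  # columns: id, F, F6, Fk, Fk_se

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def kalinowski_Fk(ped: Pedigree, replicates: int = 100_000,
                  seed: int | None = None, *, chunk: int = 20_000,
                  return_autozygosity: bool = False):
    """Ancestral inbreeding by gene-dropping Monte Carlo.

    Each replicate drops two uniquely labelled alleles per founder (an
    unknown parent likewise contributes a unique allele) down the pedigree.
    An animal is autozygous when its two copies share a label.  A copy
    carries a flag, set whenever the carrying animal was autozygous, and
    transmitted with the copy; Fk(x) is the fraction of replicates in which
    x is autozygous *and* an inherited copy was flagged in a strict ancestor.

    Returns ``(Fk, Fk_se)`` (plus the raw autozygosity rate when
    ``return_autozygosity``), with the binomial standard error
    sqrt(p (1-p) / replicates).
    """
    if replicates <= 0:
        raise ValueError("replicates must be a positive integer")
    rng = np.random.default_rng(seed)
    n = ped.n
    fk_hits = np.zeros(n, dtype=np.int64)
    auto_hits = np.zeros(n, dtype=np.int64)

    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        lab = np.empty((n, 2, r), dtype=np.int32)
        flg = np.zeros((n, 2, r), dtype=bool)
        next_label = 0
        for x in range(n):
            inherited = []
            for slot, p in enumerate((ped.sire[x], ped.dam[x])):
                if p == UNKNOWN:
                    lab[x, slot] = next_label
                    flg[x, slot] = False
                    next_label += 1
                else:
                    pick = rng.integers(0, 2, size=r)
                    lab[x, slot] = np.where(pick, lab[p, 1], lab[p, 0])
                    flg[x, slot] = np.where(pick, flg[p, 1], flg[p, 0])
                    inherited.append(slot)
            auto = lab[x, 0] == lab[x, 1]
            if len(inherited) == 2:
                prior_ibd = flg[x, 0] | flg[x, 1]
                fk_hits[x] += int((auto & prior_ibd).sum())
                auto_hits[x] += int(auto.sum())
                # focal autozygosity flags the copies for descendants only
                flg[x, 0] |= auto
                flg[x, 1] |= auto
        done += r

    fk = fk_hits / replicates
    se = np.sqrt(fk * (1.0 - fk) / replicates)
    if return_autozygosity:
        return fk, se, auto_hits / replicates
    return fk, se


def coefficient_table(ped: Pedigree, fk_replicates: int = 100_000,
                      seed: int | None = None) -> CoefficientTable:
    """All three coefficients for every animal, full floating precision."""
    F = meuwissen_luo_F(ped)
    F6 = six_generation_F(ped)
    Fk, se = kalinowski_Fk(ped, replicates=fk_replicates, seed=seed)
    return CoefficientTable(pd.DataFrame({
        "id": ped.ext_id, "F": F, "F6": F6, "Fk": Fk, "Fk_se": se}))
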