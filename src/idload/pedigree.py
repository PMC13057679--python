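"""Pedigree container, file I/O, validation and dense relationship oracles.

A :class:`Pedigree` stores animals in topological order (every known parent
precedes its offspring) with consecutive internal indices 0..n-1; the original
studbook identifiers are kept in a bidirectional lookup.  Unknown parents are
coded 0 or empty in files and ``-1`` internally.

The dense tabular relationship matrix and its sparse inverse are the exact
oracles against which the fast per-animal traversals in
:mod:`idload.inbreeding` and :mod:`idload.partial` are verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1

#: guard for the dense oracle — production paths use sparse traversal only
DENSE_GUARD = 5000

_SEX_CODES = {"male": 1, "female": 2, "unknown": 0,
              "m": 1, "f": 2, "u": 0, "1": 1, "2": 2, "0": 0, "": 0}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad parent ids...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    sire, dam
        Internal parent indices per animal, ``-1`` for unknown.
    ext_id
        Original identifier of each animal (position = internal index).
    sex
        0 unknown, 1 male, 2 female.
    birth_year
        Float array, NaN where missing.
    """

    sire: np.ndarray
    dam: np.ndarray
    ext_id: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {int(e): i for i, e in enumerate(self.ext_id)}
        self._validate()

    # -- basic interface ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sire)

    def __len__(self) -> int:
        return self.n

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def internal(self, ext) -> int:
        """Internal index for an external id."""
        try:
            return self.index[int(ext)]
        except KeyError:
            raise PedigreeError(f"animal id {ext} not in pedigree") from None

    def _validate(self) -> None:
        n = self.n
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.where((par != UNKNOWN) & ((par < 0) | (par >= n)))[0]
            if bad.size:
                raise PedigreeError(f"{name} index out of range for animal "
                                    f"{self.ext_id[bad[0]]}")
            ahead = np.where((par != UNKNOWN) & (par >= np.arange(n)))[0]
            if ahead.size:
                raise PedigreeError(
                    f"pedigree not topologically ordered: {name} of animal "
                    f"{self.ext_id[ahead[0]]} does not precede it")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, add_missing_founders: bool = False
                   ) -> "Pedigree":
        """Build a validated, topologically sorted pedigree from a table.

        ``df`` needs columns ``id``, ``sire``, ``dam`` and optionally ``sex``
        and ``birth_year``; rows may appear in any order.
        """
        ids = pd.to_numeric(df["id"], errors="raise").astype(np.int64).to_numpy()
        if (ids <= 0).any():
            raise PedigreeError("animal ids must be positive integers")
        if len(np.unique(ids)) != len(ids):
            dup = pd.Series(ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup}")

        def _parents(col):
            s = df[col] if col in df else pd.Series(0, index=df.index)
            s = pd.to_numeric(s.replace("", 0), errors="raise").fillna(0)
            return s.astype(np.int64).to_numpy()

        sire_e, dam_e = _parents("sire"), _parents("dam")
        for par in (sire_e, dam_e):
            if (par == ids).any():
                bad = ids[par == ids][0]
                raise PedigreeError(f"animal {bad} listed as its own parent")

        known = set(ids.tolist())
        missing = sorted({int(p) for p in np.r_[sire_e, dam_e]
                          if p != 0 and p not in known})
        if missing:
            if not add_missing_founders:
                raise PedigreeError(f"parent ids absent from pedigree: {missing}")
            ids = np.r_[np.array(missing, dtype=np.int64), ids]
            sire_e = np.r_[np.zeros(len(missing), dtype=np.int64), sire_e]
            dam_e = np.r_[np.zeros(len(missing), dtype=np.int64), dam_e]
            df = None  # sex/birth_year lookups below handle padding

        # topological sort (Kahn) on the parent->offspring DAG
        pos = {int(e): k for k, e in enumerate(ids)}
        nn = len(ids)
        indeg = np.zeros(nn, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(nn)]
        for k in range(nn):
            for p in (sire_e[k], dam_e[k]):
                if p != 0:
                    children[pos[int(p)]].append(k)
                    indeg[k] += 1
        order: list[int] = []
        stack = sorted(np.where(indeg == 0)[0].tolist(), reverse=True)
        while stack:
            k = stack.pop()
            order.append(k)
            for ch in children[k]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    stack.append(ch)
        if len(order) != nn:
            on_cycle = ids[np.where(indeg > 0)[0][0]]
            raise PedigreeError(f"pedigree contains a cycle involving animal "
                                f"{on_cycle}")

        ids_o = ids[order]
        new_pos = {int(e): i for i, e in enumerate(ids_o)}
        sire_i = np.array([new_pos[int(s)] if s != 0 else UNKNOWN
                           for s in sire_e[order]], dtype=np.int64)
        dam_i = np.array([new_pos[int(d)] if d != 0 else UNKNOWN
                          for d in dam_e[order]], dtype=np.int64)

        sex = np.zeros(nn, dtype=np.int8)
        by = np.full(nn, np.nan)
        if df is not None:
            if "sex" in df:
                raw = df["sex"].astype(str).str.strip().str.lower()
                coded = raw.map(_SEX_CODES).fillna(0).astype(np.int8).to_numpy()
                sex = coded[order]
            if "birth_year" in df:
                byr = pd.to_numeric(df["birth_year"], errors="coerce").to_numpy()
                by = byr[order]
        return cls(sire=sire_i, dam=dam_i, ext_id=ids_o, sex=sex, birth_year=by)

    def to_frame(self) -> pd.DataFrame:
        sire_e = np.where(self.sire == UNKNOWN, 0, self.ext_id[self.sire])
        dam_e = np.where(self.dam == UNKNOWN, 0, self.ext_id[self.dam])
        return pd.DataFrame({"id": self.ext_id, "sire": sire_e, "dam": dam_e,
                             "sex": self.sex, "birth_year": self.birth_year})

    # -- traversal helpers -------------------------------------------------
    def ancestors(self, x: int) -> set:
        """Internal indices of all strict ancestors of internal index ``x``."""
        seen: set = set()
        stack = [p for p in (self.sire[x], self.dam[x]) if p != UNKNOWN]
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            for p in (self.sire[a], self.dam[a]):
                if p != UNKNOWN:
                    stack.append(p)
        return seen

    def stats(self) -> dict:
        """Counts, founder number and maximal generation depth."""
        depth = np.zeros(self.n, dtype=np.int64)
        for x in range(self.n):
            d = 0
            for p in (self.sire[x], self.dam[x]):
                if p != UNKNOWN:
                    d = max(d, depth[p] + 1)
            depth[x] = d
        return {"n_animals": self.n,
                "n_founders": int(self.is_founder.sum()),
                "n_males": int((self.sex == 1).sum()),
                "n_females": int((self.sex == 2).sum()),
                "max_depth": int(depth.max()) if self.n else 0}


def read_pedigree(path, dialect: dict | None = None, *,
                  add_missing_founders: bool = False) -> Pedigree:
    """Read a pedigree CSV (columns ``id,sire,dam[,sex,birth_year]``).

    ``dialect`` maps standard column names to the file's column names, e.g.
    ``{"id": "animal", "sire": "father"}``.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if dialect:
        rename = {v.strip().lower(): k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    for col in ("id", "sire", "dam"):
        if col not in df:
            raise PedigreeError(f"column '{col}' not found in {path}")
    return Pedigree.from_frame(df, add_missing_founders=add_missing_founders)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def truncate_generations(ped: Pedigree, focal, depth: int) -> Pedigree:
    """Sub-pedigree of ``focal``'s ancestors within ``depth`` meioses.

    The focal animal is generation 0 and its parents generation 1.  An
    ancestor is retained when its minimal meiosis distance from the focal
    animal is <= ``depth``; ancestors exactly at ``depth`` become founders.
    ``focal`` is an external id.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    fx = ped.internal(focal)
    dist = {fx: 0}
    frontier = [fx]
    for g in range(depth):
        nxt = []
        for x in frontier:
            for p in (ped.sire[x], ped.dam[x]):
                if p != UNKNOWN and p not in dist:
                    dist[p] = g + 1
                    nxt.append(p)
        frontier = nxt
    keep = sorted(dist)  # ascending internal index = topological order
    sub = {x: i for i, x in enumerate(keep)}

    def _par(x, p):
        if p == UNKNOWN or dist[x] >= depth or p not in dist:
            return UNKNOWN
        return sub[p]

    sire = np.array([_par(x, ped.sire[x]) for x in keep], dtype=np.int64)
    dam = np.array([_par(x, ped.dam[x]) for x in keep], dtype=np.int64)
    return Pedigree(sire=sire, dam=dam, ext_id=ped.ext_id[keep],
                    sex=ped.sex[keep], birth_year=ped.birth_year[keep])


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the recursive tabular method.

    Exact but O(n^2); guarded at ``DENSE_GUARD`` animals.  Serves as the
    oracle for the sparse Meuwissen–Luo and Henderson/Quaas routines.
    """
    n = ped.n
    if n > DENSE_GUARD:
        raise PedigreeError(
            f"dense tabular method guarded at {DENSE_GUARD} animals "
            f"(got {n}); use the sparse algorithms")
    A = np.zeros((n, n))
    for y in range(n):
        s, d = ped.sire[y], ped.dam[y]
        row = np.zeros(y)
        if s != UNKNOWN:
            row += 0.5 * A[s, :y]
        if d != UNKNOWN:
            row += 0.5 * A[d, :y]
        A[y, :y] = row
        A[:y, y] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[y, y] = 1.0 + 0.5 * asd
    return A


def mendelian_variance(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Mendelian-sampling variance d_x per animal.

    d = 0.5 - 0.25 (F_sire + F_dam) with both parents known, 1 for founders
    and 0.75 - 0.25 F_known with a single known parent.
    """
    d = np.ones(ped.n)
    for x in range(ped.n):
        s, dm = ped.sire[x], ped.dam[x]
        if s != UNKNOWN and dm != UNKNOWN:
            d[x] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN:
            d[x] = 0.75 - 0.25 * F[s]
        elif dm != UNKNOWN:
            d[x] = 0.75 - 0.25 * F[dm]
    return d


def build_a_inverse(ped: Pedigree, F: np.ndarray) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson/Quaas).

    ``F`` must be the inbreeding vector of the same pedigree (see
    :func:`idload.inbreeding.meuwissen_luo_F`); inbreeding enters through the
    Mendelian-sampling variances.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (ped.n,):
        raise ValueError(f"F has length {F.shape}, pedigree has {ped.n} animals")
    d = mendelian_variance(ped, F)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for x in range(ped.n):
        alpha = 1.0 / d[x]
        add(x, x, alpha)
        for p in (ped.sire[x], ped.dam[x]):
            if p != UNKNOWN:
                add(x, p, -0.5 * alpha)
                add(p, x, -0.5 * alpha)
        for p in (ped.sire[x], ped.dam[x]):
            for q in (ped.sire[x], ped.dam[x]):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()
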