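"""Pedigree container, validation, pruning and numerator-relationship algebra.

The pedigree is the backbone of every evaluation: the additive (numerator)
relationship matrix A, its sparse inverse built with Henderson's rules, and
inbreeding coefficients F all derive from it.  Parents are encoded by id with
``UNKNOWN = "0"`` for a missing parent; the table is stored topologically
sorted so that parents always precede their offspring.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"

PED_COLUMNS = ["animal", "sire", "dam", "sex", "birth_year", "country"]


@dataclass
class PedigreeIssue:
    """A single validation finding (reporting only, never raised)."""

    kind: str  # loop | duplicate_id | sex_conflict | birth_year_inversion
    animal: str
    detail: str = ""


class Pedigree:
    """Topologically sorted pedigree with integer-coded parent links.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``animal, sire, dam, sex, birth_year, country``; missing
        parents as ``"0"``; input row order is free.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        for col in PED_COLUMNS:
            if col not in df.columns:
                if col == "sex":
                    df[col] = "UNKNOWN"
                elif col == "birth_year":
                    df[col] = np.nan
                elif col == "country":
                    df[col] = "NA"
                else:
                    raise ValueError(f"pedigree table missing column {col!r}")
        df["animal"] = df["animal"].astype(str)
        df["sire"] = df["sire"].astype(str).replace({"": UNKNOWN, "nan": UNKNOWN})
        df["dam"] = df["dam"].astype(str).replace({"": UNKNOWN, "nan": UNKNOWN})
        if df["animal"].duplicated().any():
            dups = df.loc[df["animal"].duplicated(), "animal"].tolist()
            raise ValueError(f"duplicate animal ids in pedigree: {dups[:5]}")
        order = _topological_order(df)
        self.table = df.iloc[order].reset_index(drop=True)[PED_COLUMNS]
        self._index = {a: i for i, a in enumerate(self.table["animal"])}
        self.sire_idx = np.array(
            [self._index.get(s, -1) for s in self.table["sire"]], dtype=np.int64
        )
        self.dam_idx = np.array(
            [self._index.get(d, -1) for d in self.table["dam"]], dtype=np.int64
        )
        self._F: np.ndarray | None = None
        self._ainv: sp.csr_matrix | None = None
        self._ainv_lu = None

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, animal: str) -> bool:
        return str(animal) in self._index

    @property
    def animals(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from None

    # -- inbreeding --------------------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F (Meuwissen & Luo algorithm).

        F of a founder is 0 and F(k) = 0.5 a(sire, dam).  The result is
        cached; the pedigree is immutable after construction.
        """
        if self._F is None:
            self._F = _meuwissen_luo(self.sire_idx, self.dam_idx)
        return self._F

    # -- relationship algebra ---------------------------------------------
    def a_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of the numerator relationship matrix A.

        Henderson's rules accounting for inbreeding: A^{-1} =
        (I - P)' D^{-1} (I - P) with P carrying 0.5 on parent links and D
        the Mendelian-sampling variances.
        """
        if self._ainv is not None:
            return self._ainv
        F = self.inbreeding()
        n = len(self)
        s, d = self.sire_idx, self.dam_idx
        mend = np.ones(n)
        has_s, has_d = s >= 0, d >= 0
        mend[has_s] -= 0.25 * (1.0 + F[s[has_s]])
        mend[has_d] -= 0.25 * (1.0 + F[d[has_d]])
        rows, cols, vals = [np.arange(n)], [np.arange(n)], [np.ones(n)]
        for par, mask in ((s, has_s), (d, has_d)):
            rows.append(np.arange(n)[mask])
            cols.append(par[mask])
            vals.append(np.full(mask.sum(), -0.5))
        ImP = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        Dinv = sp.diags(1.0 / mend)
        self._ainv = (ImP.T @ Dinv @ ImP).tocsr()
        return self._ainv

    def a_submatrix(self, row_ids, col_ids) -> "RelationshipBlock":
        """Dense block of numerator relationships a(i, j).

        Computed as columns of A obtained by solving A^{-1} X = E_cols with a
        sparse LU factorisation, which scales to the pedigree sizes used here.
        """
        rows = self.index_of(row_ids)
        cols = self.index_of(col_ids)
        A_cols = self.a_columns(cols)
        values = A_cols[rows, :]
        return RelationshipBlock(
            row_ids=list(map(str, row_ids)),
            col_ids=list(map(str, col_ids)),
            values=values,
        )

    def a_columns(self, col_indices: np.ndarray) -> np.ndarray:
        """Dense n x k block of A columns for integer positions."""
        n = len(self)
        if self._ainv_lu is None:
            self._ainv_lu = sp.linalg.splu(self.a_inverse().tocsc())
        lu = self._ainv_lu
        rhs = np.zeros((n, len(col_indices)))
        rhs[col_indices, np.arange(len(col_indices))] = 1.0
        return lu.solve(rhs)

    # -- structure queries -------------------------------------------------
    def ancestors_of(self, ids) -> set[str]:
        """Every ancestor (any depth) of the given animals."""
        seen: set[int] = set()
        stack = list(self.index_of(ids))
        while stack:
            k = stack.pop()
            for p in (self.sire_idx[k], self.dam_idx[k]):
                if p >= 0 and p not in seen:
                    seen.add(p)
                    stack.append(p)
        animals = self.animals
        return {animals[k] for k in seen}

    def progeny_counts(self) -> pd.Series:
        """Number of pedigree offspring per animal id."""
        counts = np.zeros(len(self), dtype=np.int64)
        for par in (self.sire_idx, self.dam_idx):
            known = par[par >= 0]
            np.add.at(counts, known, 1)
        return pd.Series(counts, index=self.animals)


@dataclass
class RelationshipBlock:
    """Block of the numerator relationship matrix (entries in [0, 2])."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def validate_pedigree(table: pd.DataFrame) -> list[PedigreeIssue]:
    """Report loops, duplicate ids, sex conflicts and birth-year inversions.

    This is a reporting operation: it never raises, and an empty list means
    the structural invariants hold.  Birth-year inversions are warnings (real
    pedigrees contain them) and do not prevent construction of a Pedigree.
    """
    issues: list[PedigreeIssue] = []
    df = table.copy()
    df["animal"] = df["animal"].astype(str)
    df["sire"] = df.get("sire", UNKNOWN).astype(str)
    df["dam"] = df.get("dam", UNKNOWN).astype(str)

    dup = df.loc[df["animal"].duplicated(), "animal"].unique()
    for a in dup:
        issues.append(PedigreeIssue("duplicate_id", a, "animal id appears twice"))
    df = df.drop_duplicates("animal", keep="first")

    sires = set(df["sire"]) - {UNKNOWN}
    dams = set(df["dam"]) - {UNKNOWN}
    for a in sorted(sires & dams):
        issues.append(
            PedigreeIssue("sex_conflict", a, "id used both as sire and as dam")
        )
    sex = dict(zip(df["animal"], df.get("sex", "UNKNOWN").astype(str)))
    for a in sorted(sires):
        if sex.get(a) == "F":
            issues.append(PedigreeIssue("sex_conflict", a, "female recorded as sire"))
    for a in sorted(dams):
        if sex.get(a) == "M":
            issues.append(PedigreeIssue("sex_conflict", a, "male recorded as dam"))

    # loops: animals on a directed cycle parent -> offspring
    idx = {a: i for i, a in enumerate(df["animal"])}
    s_idx = np.array([idx.get(x, -1) for x in df["sire"]])
    d_idx = np.array([idx.get(x, -1) for x in df["dam"]])
    looped = _animals_on_cycles(s_idx, d_idx)
    animals = df["animal"].to_numpy()
    for k in looped:
        issues.append(PedigreeIssue("loop", animals[k], "animal is its own ancestor"))

    if "birth_year" in df.columns:
        yr = pd.to_numeric(df["birth_year"], errors="coerce").to_numpy()
        for k in range(len(df)):
            for p, role in ((s_idx[k], "sire"), (d_idx[k], "dam")):
                if p >= 0 and np.isfinite(yr[k]) and np.isfinite(yr[p]) and yr[p] >= yr[k]:
                    issues.append(
                        PedigreeIssue(
                            "birth_year_inversion",
                            animals[k],
                            f"{role} {animals[p]} born {int(yr[p])} "
                            f">= offspring year {int(yr[k])}",
                        )
                    )
    return issues


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Restrict to ``keep_ids`` and all their ancestors, no depth limit.

    Parent links pointing outside the retained set are set to UNKNOWN.  The
    operation is idempotent.
    """
    keep = {str(a) for a in keep_ids}
    missing = keep - set(ped.animals)
    if missing:
        raise KeyError(f"unknown ids in keep_ids: {sorted(missing)[:5]}")
    retained = keep | ped.ancestors_of(keep)
    sub = ped.table[ped.table["animal"].isin(retained)].copy()
    sub.loc[~sub["sire"].isin(retained), "sire"] = UNKNOWN
    sub.loc[~sub["dam"].isin(retained), "dam"] = UNKNOWN
    return Pedigree(sub)


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient per animal id."""
    return pd.Series(ped.inbreeding(), index=ped.animals)


def a_submatrix(ped: Pedigree, row_ids, col_ids) -> RelationshipBlock:
    return ped.a_submatrix(row_ids, col_ids)


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    return ped.a_inverse()


def generation_interval(ped: Pedigree) -> tuple[float, float, float]:
    """(L_m, L_f, L): mean sire age, mean dam age at offspring birth, average.

    L = (L_m + L_f) / 2; only parent-offspring pairs with both birth years
    known contribute.
    """
    yr = pd.to_numeric(ped.table["birth_year"], errors="coerce").to_numpy(float)
    out = []
    for par in (ped.sire_idx, ped.dam_idx):
        mask = (par >= 0) & np.isfinite(yr)
        mask[mask] &= np.isfinite(yr[par[mask]])
        ages = yr[mask] - yr[par[mask]]
        out.append(float(np.mean(ages)) if ages.size else np.nan)
    L_m, L_f = out
    if not (np.isfinite(L_m) and np.isfinite(L_f)):
        raise ValueError("no parent-offspring pair with both birth years known")
    return L_m, L_f, 0.5 * (L_m + L_f)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _topological_order(df: pd.DataFrame) -> np.ndarray:
    """Kahn's algorithm over parent -> offspring edges; raises on loops."""
    idx = {a: i for i, a in enumerate(df["animal"])}
    n = len(df)
    s_idx = np.array([idx.get(x, -1) for x in df["sire"]])
    d_idx = np.array([idx.get(x, -1) for x in df["dam"]])
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for p in (s_idx[k], d_idx[k]):
            if p >= 0:
                children[p].append(k)
                indeg[k] += 1
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    order = []
    while queue:
        k = queue.popleft()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise ValueError("pedigree contains a loop (an animal is its own ancestor)")
    return np.array(order, dtype=np.int64)


def _animals_on_cycles(s_idx: np.ndarray, d_idx: np.ndarray) -> list[int]:
    n = len(s_idx)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for p in (s_idx[k], d_idx[k]):
            if p >= 0:
                children[p].append(k)
                indeg[k] += 1
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    removed = 0
    indeg = indeg.copy()
    while queue:
        k = queue.popleft()
        removed += 1
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return [k for k in range(n) if indeg[k] > 0]


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo (1992) inbreeding for a topologically sorted pedigree.

    For each animal k with both parents known, a_kk = sum_i L_i^2 D_i over the
    ancestor paths of k (L_k = 1), where D_i is the within-family variance of
    ancestor i; F_k = a_kk - 1.  Parents precede offspring, so D of every
    ancestor is already available when k is processed.
    """
    import heapq

    n = len(sire)
    F = np.zeros(n)
    D = np.zeros(n)
    for k in range(n):
        s, d = sire[k], dam[k]
        dk = 1.0
        if s >= 0:
            dk -= 0.25 * (1.0 + F[s])
        if d >= 0:
            dk -= 0.25 * (1.0 + F[d])
        D[k] = dk
        if s < 0 or d < 0:
            continue  # founder or half-known parentage: F = 0
        L = {k: 1.0}
        heap = [-k]
        a_kk = 0.0
        while heap:
            i = -heapq.heappop(heap)
            li = L.pop(i)
            a_kk += li * li * D[i]
            for p in (sire[i], dam[i]):
                if p >= 0:
                    if p not in L:
                        L[p] = 0.0
                        heapq.heappush(heap, -p)
                    L[p] += 0.5 * li
        F[k] = a_kk - 1.0
    return F
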