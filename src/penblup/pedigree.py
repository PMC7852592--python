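"""Pedigree container and numerator-relationship machinery.

The additive relationship matrix A is never materialized at population scale.
Instead the pedigree supplies:

* inbreeding coefficients F (Meuwissen & Luo recursion),
* the sparse inverse A^-1 assembled by Henderson's rules with inbreeding,
* quadratic forms Q A Q' through the factorization A = (I-P)^-1 D (I-P)^-T,
  where P holds the half parent contributions and D the Mendelian-sampling
  variances d_i = 0.5 - 0.25 (F_s + F_d).

Dense A (the tabular method) is available for moderate pedigrees, which is
what the genomic H-matrix construction and the test oracles use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

UNKNOWN = -1


@njit(cache=True)
def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray):
    """Inbreeding coefficients and Mendelian-sampling variances.

    Parents must precede offspring.  Unknown parents are treated as unrelated
    non-inbred base animals.
    """
    n = sire.shape[0]
    F = np.zeros(n)
    D = np.empty(n)
    L = np.zeros(n)
    for i in range(n):
        s = sire[i]
        d = dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            D[i] = 1.0
        elif s == UNKNOWN:
            D[i] = 0.75 - 0.25 * F[d]
        elif d == UNKNOWN:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # a_ii = sum_j L_ij^2 d_j over ancestors j of i (L_ii = 1)
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj != 0.0:
                aii += lj * lj * D[j]
                sj = sire[j]
                dj = dam[j]
                if sj != UNKNOWN:
                    L[sj] += 0.5 * lj
                if dj != UNKNOWN:
                    L[dj] += 0.5 * lj
                L[j] = 0.0
        F[i] = aii - 1.0
    return F, D


@njit(cache=True)
def _tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            v = 0.0
            if s != UNKNOWN:
                v += 0.5 * A[j, s]
            if d != UNKNOWN:
                v += 0.5 * A[j, d]
            A[i, j] = v
            A[j, i] = v
    return A


class Pedigree:
    """Ordered pedigree (parents before offspring) with relationship utilities.

    Parameters
    ----------
    sire, dam : integer arrays of internal parent indices, ``-1`` = unknown.
    generation, sex, litter : optional per-animal annotations.
    ids : external identifiers (default ``1..n``).
    """

    def __init__(
        self,
        sire: np.ndarray,
        dam: np.ndarray,
        generation: np.ndarray | None = None,
        sex: np.ndarray | None = None,
        litter: np.ndarray | None = None,
        ids: np.ndarray | None = None,
    ) -> None:
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        n = len(self.sire)
        if len(self.dam) != n:
            raise ValueError("sire and dam arrays must have equal length")
        idx = np.arange(n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par >= idx):
                raise ValueError(
                    f"{name} index not earlier than offspring: pedigree must be "
                    "sorted parents-before-offspring (no cycles)"
                )
            if np.any(par < UNKNOWN):
                raise ValueError(f"invalid {name} index")
        self.generation = (
            np.asarray(generation, dtype=np.int32)
            if generation is not None
            else np.zeros(n, dtype=np.int32)
        )
        self.sex = np.asarray(sex, dtype=np.int8) if sex is not None else None
        self.litter = np.asarray(litter, dtype=np.int64) if litter is not None else None
        self.ids = np.asarray(ids) if ids is not None else np.arange(1, n + 1)
        if len(self.ids) != n:
            raise ValueError("ids must match pedigree length")
        self._id_to_index = {int(i): k for k, i in enumerate(self.ids)}
        self._F: np.ndarray | None = None
        self._D: np.ndarray | None = None
        self._breeding: np.ndarray | None = None

    # -- basic ------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sire)

    def __len__(self) -> int:
        return self.n

    def indices_of(self, ids) -> np.ndarray:
        return np.fromiter(
            (self._id_to_index[int(i)] for i in np.atleast_1d(ids)),
            dtype=np.int64,
            count=len(np.atleast_1d(ids)),
        )

    @property
    def breeding(self) -> np.ndarray:
        """True for animals that are a parent of a later-generation animal."""
        if self._breeding is None:
            flags = np.zeros(self.n, dtype=bool)
            for par in (self.sire, self.dam):
                known = par[par != UNKNOWN]
                flags[known] = True
            self._breeding = flags
        return self._breeding

    def to_dataframe(self) -> pd.DataFrame:
        def ext(par):
            out = np.zeros(self.n, dtype=np.int64)
            known = par != UNKNOWN
            out[known] = self.ids[par[known]]
            return out  # 0 = unknown

        df = pd.DataFrame(
            {
                "id": self.ids,
                "sire": ext(self.sire),
                "dam": ext(self.dam),
                "generation": self.generation,
                "sex": self.sex if self.sex is not None else np.zeros(self.n, np.int8),
                "breeding_flag": self.breeding.astype(int),
            }
        )
        if self.litter is not None:
            df["litter"] = self.litter
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from columns id/sire/dam (0 = unknown parent), optionally
        generation, sex, litter.  Rows are topologically sorted if needed."""
        df = df.copy()
        ids = df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate animal ids")
        order = np.arange(len(df))
        pos = {int(i): k for k, i in enumerate(ids)}

        def par_idx(col):
            out = np.full(len(df), UNKNOWN, dtype=np.int64)
            for k, v in enumerate(df[col].to_numpy()):
                v = int(v)
                if v != 0:
                    if v not in pos:
                        raise ValueError(f"unknown parent id {v}")
                    out[k] = pos[v]
            return out

        s = par_idx("sire")
        d = par_idx("dam")
        # Kahn topological sort (stable); detects cycles.
        n = len(df)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for k in range(n):
            for p in (s[k], d[k]):
                if p != UNKNOWN:
                    children[p].append(k)
                    indeg[k] += 1
        from collections import deque

        queue = deque(np.flatnonzero(indeg == 0).tolist())
        topo = []
        while queue:
            u = queue.popleft()
            topo.append(u)
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        if len(topo) != n:
            raise ValueError("pedigree contains a cycle")
        order = np.array(topo)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)
        remap = lambda p: np.where(p == UNKNOWN, UNKNOWN, rank[np.maximum(p, 0)])[order]
        kwargs = {}
        for col, key in (("generation", "generation"), ("sex", "sex"), ("litter", "litter")):
            if col in df.columns:
                kwargs[key] = df[col].to_numpy()[order]
        return cls(
            sire=remap(s), dam=remap(d), ids=ids[order], **kwargs
        )

    # -- relationship machinery -------------------------------------------

    def inbreeding(self) -> np.ndarray:
        if self._F is None:
            self._F, self._D = _meuwissen_luo(self.sire, self.dam)
        return self._F

    def mendelian_variances(self) -> np.ndarray:
        """d_i = Var(mendelian sampling)/sigma_a^2, accounting for inbreeding."""
        if self._D is None:
            self.inbreeding()
        return self._D

    def additive_matrix(self, rows=None, cols=None) -> np.ndarray:
        """Dense A by the tabular method (guarded against huge pedigrees);
        optionally sliced to ``rows`` x ``cols`` (internal indices)."""
        if self.n > 20000:
            raise MemoryError(
                "dense A is limited to 20k animals; use a_inverse() or "
                "relationship_product() at scale"
            )
        A = _tabular_A(self.sire, self.dam)
        if rows is not None or cols is not None:
            rows = np.arange(self.n) if rows is None else np.asarray(rows)
            cols = np.arange(self.n) if cols is None else np.asarray(cols)
            return A[np.ix_(rows, cols)]
        return A

    def a_inverse(self) -> sp.csr_matrix:
        """Sparse A^-1 by Henderson's rules with inbreeding."""
        d = self.mendelian_variances()
        alpha = 1.0 / d
        i = np.arange(self.n)
        s, dm = self.sire, self.dam
        has_s = s != UNKNOWN
        has_d = dm != UNKNOWN
        both = has_s & has_d
        rows = [i]
        cols = [i]
        vals = [alpha]
        for par, has in ((s, has_s), (dm, has_d)):
            rows += [i[has], par[has], par[has]]
            cols += [par[has], i[has], par[has]]
            vals += [-alpha[has] / 2, -alpha[has] / 2, alpha[has] / 4]
        rows += [s[both], dm[both]]
        cols += [dm[both], s[both]]
        vals += [alpha[both] / 4, alpha[both] / 4]
        Ainv = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        return Ainv.tocsr()

    def relationship_product(self, Q) -> np.ndarray:
        """Dense ``Q A Q'`` for sparse/dense Q of shape (m, n) without forming A.

        Uses A = (I-P)^-1 D (I-P)^-T: first B = Q (I-P)^-1 by backward
        accumulation of half parent contributions, then (B sqrt(D)) (.)'.
        """
        if sp.issparse(Q):
            B = np.asarray(Q.todense(), dtype=float)
        else:
            B = np.array(Q, dtype=float)
        if B.shape[1] != self.n:
            raise ValueError("Q must have one column per pedigree animal")
        s, dm = self.sire, self.dam
        for k in range(self.n - 1, -1, -1):
            colk = B[:, k]
            if s[k] != UNKNOWN:
                B[:, s[k]] += 0.5 * colk
            if dm[k] != UNKNOWN:
                B[:, dm[k]] += 0.5 * colk
        B *= np.sqrt(self.mendelian_variances())[None, :]
        return B @ B.T

    def log_det_A(self) -> float:
        """log|A| = sum log d_i (the (I-P) factors are unit triangular)."""
        return float(np.log(self.mendelian_variances()).sum())
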