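"""Genomic and combined relationship matrices for GBLUP / single-step GBLUP.

Pipeline (fixed order):

1. ``build_G_vanraden`` — G = ZZ' / (2 sum p_j (1-p_j)) with Z the dosage
   matrix centred at twice the observed allele frequencies (VanRaden method 1,
   frequencies computed from the genotyped animals themselves).
2. ``rescale_G_to_A11`` — adjust G to the scale of the pedigree relationships
   among the genotyped animals (matching the means of the diagonal and of the
   whole matrix).
3. ``blend_Gw`` — Gw = (1-w) G + w A11 with w = 0.05, which also guarantees
   invertibility.
4. ``assemble_H`` — the single-step matrix combining Gw with the pedigree
   blocks; its sparse-friendly inverse is
   H^-1 = A^-1 + [[Gw^-1 - A11^-1, 0], [0, 0]] on the genotyped block.

Missing genotypes are not supported: dosages must be complete 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .pedigree import Pedigree


@dataclass
class RelationshipMatrix:
    """A dense additive relationship matrix with its id order."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # A | G_raw | G_adjusted | Gw | H
    genotyped_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match id count")

    @property
    def n(self) -> int:
        return len(self.ids)


def build_A(ped: Pedigree, ids=None) -> RelationshipMatrix:
    """Dense numerator relationship matrix (with inbreeding) for the pedigree,
    optionally restricted to a subset of ids (rows/cols in that order)."""
    if ids is None:
        return RelationshipMatrix(ids=ped.ids, values=ped.additive_matrix(), kind="A")
    idx = ped.indices_of(ids)
    return RelationshipMatrix(
        ids=np.atleast_1d(ids), values=ped.additive_matrix(idx, idx), kind="A"
    )


def build_G_vanraden(
    dosages: np.ndarray,
    ids,
    frequencies: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix from 0/1/2 dosages.

    Allele frequencies default to the observed frequencies among the
    genotyped animals themselves."""
    M = np.asarray(dosages, dtype=float)
    if M.ndim != 2:
        raise ValueError("dosages must be a (n_animals, n_markers) matrix")
    if np.any((M < 0) | (M > 2)) or np.any(np.isnan(M)):
        raise ValueError("dosages must be complete 0/1/2 (missing genotypes unsupported)")
    p = M.mean(axis=0) / 2.0 if frequencies is None else np.asarray(frequencies, float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: G denominator is zero")
    Z = M - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(ids=np.atleast_1d(ids), values=G, kind="G_raw")


def rescale_G_to_A11(
    G: RelationshipMatrix, A11: RelationshipMatrix
) -> RelationshipMatrix:
    """Adjust G to the scale of A11: find beta, alpha with
    mean(diag(beta G + alpha)) = mean(diag(A11)) and
    mean(beta G + alpha) = mean(A11)."""
    if G.n != A11.n or not np.array_equal(G.ids, A11.ids):
        raise ValueError("G and A11 must cover the same animals in the same order")
    g_diag, g_all = G.values.diagonal().mean(), G.values.mean()
    a_diag, a_all = A11.values.diagonal().mean(), A11.values.mean()
    det = g_diag - g_all
    if abs(det) < 1e-12 * max(1.0, abs(g_diag)):
        raise ValueError("degenerate G (constant matrix): cannot rescale")
    beta = (a_diag - a_all) / det
    alpha = a_diag - beta * g_diag
    return RelationshipMatrix(
        ids=G.ids, values=beta * G.values + alpha, kind="G_adjusted"
    )


def blend_Gw(
    G_adj: RelationshipMatrix, A11: RelationshipMatrix, w: float = 0.05
) -> RelationshipMatrix:
    """Gw = (1-w) G + w A11 (convex blend; w = 0.05 by default)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend weight w must be in [0, 1]")
    if not np.array_equal(G_adj.ids, A11.ids):
        raise ValueError("id order mismatch between G and A11")
    return RelationshipMatrix(
        ids=G_adj.ids, values=(1.0 - w) * G_adj.values + w * A11.values, kind="Gw"
    )


def genomic_matrix(
    dosages: np.ndarray,
    ids,
    ped: Pedigree,
    w: float = 0.05,
) -> RelationshipMatrix:
    """Full pipeline: VanRaden G, rescaled to A11, blended with weight w."""
    G = build_G_vanraden(dosages, ids)
    A11 = build_A(ped, ids)
    return blend_Gw(rescale_G_to_A11(G, A11), A11, w=w)


def assemble_H(
    ped: Pedigree,
    Gw: RelationshipMatrix,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """Dense single-step H matrix over the whole pedigree (pedigree id order).

    H restricted to the genotyped animals equals Gw; the non-genotyped blocks
    are pedigree regressions on the genotyped block:
    H = [[Gw, Gw A11^-1 A12], [A12' A11^-1 Gw, A22 + A12' A11^-1 (Gw - A11) A11^-1 A12]].
    """
    genotyped_ids = Gw.ids if genotyped_ids is None else np.atleast_1d(genotyped_ids)
    if not np.array_equal(genotyped_ids, Gw.ids):
        raise ValueError("genotyped ids must match the Gw id order")
    gidx = ped.indices_of(genotyped_ids)
    A = ped.additive_matrix()
    rest = np.setdiff1d(np.arange(ped.n), gidx)
    A11 = A[np.ix_(gidx, gidx)]
    A12 = A[np.ix_(gidx, rest)]
    A22 = A[np.ix_(rest, rest)]
    try:
        A11_inv_A12 = scipy.linalg.solve(A11, A12, assume_a="pos")
    except scipy.linalg.LinAlgError as e:
        raise ValueError("singular A11 block") from e
    H = np.empty_like(A)
    top = Gw.values @ A11_inv_A12
    H[np.ix_(gidx, gidx)] = Gw.values
    H[np.ix_(gidx, rest)] = top
    H[np.ix_(rest, gidx)] = top.T
    H[np.ix_(rest, rest)] = A22 + A11_inv_A12.T @ (Gw.values - A11) @ A11_inv_A12
    return RelationshipMatrix(
        ids=ped.ids, values=H, kind="H", genotyped_ids=genotyped_ids
    )


def h_inverse(
    ped: Pedigree,
    Gw: RelationshipMatrix,
) -> sp.csr_matrix:
    """Sparse-plus-block H^-1 = A^-1 + [[Gw^-1 - A11^-1, 0], [0, 0]].

    This is the form used inside the mixed-model equations at scale; on small
    pedigrees it agrees with inverting the dense block H."""
    gidx = ped.indices_of(Gw.ids)
    Ainv = ped.a_inverse()
    A11 = ped.additive_matrix(gidx, gidx) if ped.n <= 20000 else None
    if A11 is None:
        # A11 via quadratic form Q A Q' with Q selecting the genotyped rows
        Q = sp.csr_matrix(
            (np.ones(len(gidx)), (np.arange(len(gidx)), gidx)),
            shape=(len(gidx), ped.n),
        )
        A11 = ped.relationship_product(Q)
    corr = np.linalg.inv(Gw.values) - np.linalg.inv(A11)
    block = sp.coo_matrix(
        (
            corr.ravel(),
            (
                np.repeat(gidx, len(gidx)),
                np.tile(gidx, len(gidx)),
            ),
        ),
        shape=(ped.n, ped.n),
    )
    return (Ainv + block.tocsr()).tocsr()
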