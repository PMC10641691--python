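"""Relationship matrices for pedigree, genomic and single-step evaluation.

Flavors
-------
A      Wright's numerator relationship matrix (tabular/recursive method).
Ainv   Its sparse-structured inverse by Henderson's rules with inbreeding.
D      Pedigree dominance relationship matrix (non-inbred formula).
GA     VanRaden additive genomic matrix, per-locus standardized: G = WW'/M.
GD     Dominance genomic matrix with heterozygote coding 1 - 2pq and
       homozygote coding -2pq, scaled by 2*sum(pq(1-2pq)).
H      Single-step blend of A and GA (block formula).
Hinv   A^-1 plus the genotyped-block correction tau*(GA^-1 - A22^-1).

All builders return a :class:`KinshipMatrix` carrying an explicit ordered id
index; consumers must join on ids, never on position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .markers import MarkerMatrix
from .pedigree import Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix with an ordered id index."""

    flavor: str
    ids: list[str]
    values: np.ndarray
    #: for H/Hinv: ids of the genotyped block
    genotyped_ids: Optional[list[str]] = field(default=None)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KinshipError("matrix shape does not match id list")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return self.values[self._index[i], self._index[j]]

    def submatrix(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = np.array([self._index[str(i)] for i in ids])
        return KinshipMatrix(self.flavor, list(ids), self.values[np.ix_(idx, idx)])

    def reorder(self, ids: Sequence[str]) -> "KinshipMatrix":
        return self.submatrix(ids)

    def write_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path, flavor: str = "A") -> "KinshipMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(flavor, list(df.index.astype(str)), df.to_numpy(float))


# ----------------------------------------------------------------------
# Pedigree-based matrices
# ----------------------------------------------------------------------
def build_A(pedigree: Pedigree) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a_{sire,dam}/2; a_ij = (a_{j,sire(i)} + a_{j,dam(i)})/2 for
    earlier j, with unknown parents contributing 0.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    order = pedigree._order
    A = np.zeros((n, n))
    # position of each individual in processing order; parents come first
    for i in order:
        s, d = sire[i], dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i] = row
        A[:, i] = row
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return KinshipMatrix("A", pedigree.ids, A)


def _mendelian_sampling_variances(pedigree: Pedigree, F: np.ndarray) -> np.ndarray:
    """d_i of Henderson's rules, from parental inbreeding coefficients."""
    sire, dam = pedigree.parent_indices()
    d = np.ones(len(pedigree))
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & (dam < 0)
    one_d = (dam >= 0) & (sire < 0)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def build_A_inverse(pedigree: Pedigree) -> KinshipMatrix:
    """A^-1 by Henderson's rules, accounting for inbreeding."""
    A = build_A(pedigree)
    F = np.diag(A.values) - 1.0
    d = _mendelian_sampling_variances(pedigree, F)
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    Ainv = np.zeros((n, n))
    for i in range(n):
        inv_d = 1.0 / d[i]
        Ainv[i, i] += inv_d
        for p in (sire[i], dam[i]):
            if p >= 0:
                Ainv[i, p] -= 0.5 * inv_d
                Ainv[p, i] -= 0.5 * inv_d
        for p in (sire[i], dam[i]):
            for q in (sire[i], dam[i]):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += 0.25 * inv_d
    return KinshipMatrix("Ainv", pedigree.ids, Ainv)


def build_D_pedigree(pedigree: Pedigree) -> KinshipMatrix:
    """Dominance relationship matrix, classical non-inbred formula.

    d_ij = (a_{s(i)s(j)} a_{d(i)d(j)} + a_{s(i)d(j)} a_{d(i)s(j)}) / 4 for
    i != j (0 when any parent is unknown); d_ii = 1. Inbreeding is ignored,
    consistent with outbred polymix families.
    """
    A = build_A(pedigree).values
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    known = (sire >= 0) & (dam >= 0)
    D = np.zeros((n, n))
    idx = np.flatnonzero(known)
    if idx.size:
        s, d = sire[idx], dam[idx]
        D_sub = 0.25 * (
            A[np.ix_(s, s)] * A[np.ix_(d, d)] + A[np.ix_(s, d)] * A[np.ix_(d, s)]
        )
        D[np.ix_(idx, idx)] = D_sub
    np.fill_diagonal(D, 1.0)
    return KinshipMatrix("D", pedigree.ids, D)


# ----------------------------------------------------------------------
# Genomic matrices
# ----------------------------------------------------------------------
def _check_complete(m: MarkerMatrix) -> np.ndarray:
    X = m.dosages
    if np.isnan(X).any():
        raise KinshipError("genomic matrices require complete (imputed) dosages")
    return X


def build_GA(m: MarkerMatrix, freqs: Optional[np.ndarray] = None) -> KinshipMatrix:
    """Additive genomic relationship matrix, per-locus standardized.

    w_ij = (x_ij - 2 p_j) / sqrt(2 p_j q_j); G_A = W W' / M.
    """
    X = _check_complete(m)
    p = m.allele_freq() if freqs is None else np.asarray(freqs, float)
    q = 1.0 - p
    var = 2.0 * p * q
    if np.any(var <= 0):
        raise KinshipError("monomorphic SNP present; filter by MAF first")
    W = (X - 2.0 * p) / np.sqrt(var)
    G = W @ W.T / m.n_snps
    return KinshipMatrix("GA", m.ids, G)


def build_GD(m: MarkerMatrix, freqs: Optional[np.ndarray] = None) -> KinshipMatrix:
    """Dominance genomic relationship matrix.

    Heterozygotes are coded 1 - 2 p q, homozygotes -2 p q, and
    G_D = K K' / (2 sum_j p_j q_j (1 - 2 p_j q_j)).
    """
    X = _check_complete(m)
    p = m.allele_freq() if freqs is None else np.asarray(freqs, float)
    q = 1.0 - p
    pq = p * q
    het = (X == 1.0)
    K = np.where(het, 1.0 - 2.0 * pq, -2.0 * pq)
    denom = 2.0 * np.sum(pq * (1.0 - 2.0 * pq))
    if denom <= 0:
        raise KinshipError("dominance scaling denominator is zero")
    return KinshipMatrix("GD", m.ids, K @ K.T / denom)


# ----------------------------------------------------------------------
# Single-step matrices
# ----------------------------------------------------------------------
def _split_ids(A: KinshipMatrix, genotyped_ids: Sequence[str]):
    genotyped = [str(i) for i in genotyped_ids]
    gset = set(genotyped)
    missing = gset - set(A.ids)
    if missing:
        raise KinshipError(f"genotyped ids absent from A: {sorted(missing)[:5]}")
    ungenotyped = [i for i in A.ids if i not in gset]
    return ungenotyped, genotyped


def build_H(
    A: KinshipMatrix, GA: KinshipMatrix, genotyped_ids: Sequence[str]
) -> KinshipMatrix:
    """Single-step H: pedigree expectations corrected by realized G_A.

    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21;  H12 = A12 A22^-1 G;
    H22 = G. Output is re-ordered to A's id order.
    """
    ung, gen = _split_ids(A, genotyped_ids)
    GA = GA.reorder(gen)
    idx_u = np.array([A._index[i] for i in ung], dtype=int)
    idx_g = np.array([A._index[i] for i in gen], dtype=int)
    A11 = A.values[np.ix_(idx_u, idx_u)]
    A12 = A.values[np.ix_(idx_u, idx_g)]
    A22 = A.values[np.ix_(idx_g, idx_g)]
    G = GA.values
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A22) if A22.size else np.inf
        raise KinshipError(f"A22 singular (condition number {cond:.3e})") from exc
    T = A12 @ A22_inv
    H11 = A11 + T @ (G - A22) @ T.T
    H12 = T @ G
    n = len(A.ids)
    H = np.zeros((n, n))
    H[np.ix_(idx_u, idx_u)] = H11
    H[np.ix_(idx_u, idx_g)] = H12
    H[np.ix_(idx_g, idx_u)] = H12.T
    H[np.ix_(idx_g, idx_g)] = G
    return KinshipMatrix("H", A.ids, H, genotyped_ids=gen)


def build_H_inverse(
    A: KinshipMatrix,
    GA: KinshipMatrix,
    genotyped_ids: Sequence[str],
    tau: float = 1.0,
    ridge: float = 1e-6,
    Ainv: Optional[KinshipMatrix] = None,
) -> KinshipMatrix:
    """H^-1 = A^-1 + [0 0; 0 tau (G_A^-1 - A22^-1)] on A's id order.

    ``ridge`` is added to G_A's diagonal before inversion to guard against
    singularity (markers often rank-deficient); tau=1 uses the full genomic
    correction, tau=0 degenerates to A^-1.
    """
    ung, gen = _split_ids(A, genotyped_ids)
    GA = GA.reorder(gen)
    idx_g = np.array([A._index[i] for i in gen], dtype=int)
    A22 = A.values[np.ix_(idx_g, idx_g)]
    G = GA.values + ridge * np.eye(len(gen))
    try:
        G_inv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise KinshipError(
            "G_A singular even after ridge; increase the ridge parameter"
        ) from exc
    A22_inv = np.linalg.inv(A22)
    Ainv_values = Ainv.values if Ainv is not None else np.linalg.inv(A.values)
    H_inv = Ainv_values.copy()
    H_inv[np.ix_(idx_g, idx_g)] += tau * (G_inv - A22_inv)
    return KinshipMatrix("Hinv", A.ids, H_inv, genotyped_ids=gen)
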