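"""Pedigree and genomic relationship matrices and the single-step H inverse.

A is the numerator relationship matrix (tabular method, inbreeding
included); A^-1 comes from Henderson's rules with Meuwissen-Luo inbreeding
coefficients and is kept sparse.  The genomic matrix is G = Z D Z' with Z
the allele-frequency-centred genotype matrix and D a diagonal of marker
weights; at the first iteration D_ii = 1 / (m * 2 p_i (1 - p_i)), the
inverse of the expected marker variance, which normalizes mean(diag G) to
about 1.  The single-step inverse is

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

where A22 is the pedigree relationship block of the genotyped individuals
and G* is G blended with a small proportion of A22 for invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .simdata import MISSING, MarkerPanel, PedigreeTable
from .qc import mean_impute

__all__ = [
    "RelationshipMatrix",
    "HInverse",
    "MarkerWeights",
    "inbreeding_coefficients",
    "build_A",
    "build_A22",
    "build_A_inverse",
    "initial_weights",
    "build_G",
    "blend_G",
    "build_H_inverse",
]

_WEIGHT_NORM_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an explicit ID order."""

    values: np.ndarray
    ids: np.ndarray
    kind: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix/ID dimension mismatch")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    def submatrix(self, ids: Sequence) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids])
        return RelationshipMatrix(self.values[np.ix_(idx, idx)],
                                  np.asarray(ids), kind=self.kind + "_sub")

    def to_triplets(self):
        """Upper-triangle (id_i, id_j, value) triplets, sorted, for diffing."""
        n = len(self.ids)
        iu, ju = np.triu_indices(n)
        return [(str(self.ids[i]), str(self.ids[j]), float(self.values[i, j]))
                for i, j in zip(iu, ju)]


@dataclass
class HInverse:
    """Sparse single-step H^-1 over the full pedigree ID order."""

    matrix: sp.csr_matrix
    ids: np.ndarray
    genotyped_index: np.ndarray   # positions of the genotyped block

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("H^-1 must be square")
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("H^-1/ID dimension mismatch")


@dataclass
class MarkerWeights:
    """Diagonal D of per-marker weights, normalized so that
    sum_i d_i * 2 p_i (1 - p_i) = 1."""

    d: np.ndarray
    allele_freqs: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        if np.any(self.d < 0):
            raise ValueError("marker weights must be nonnegative")
        het = 2.0 * self.allele_freqs * (1.0 - self.allele_freqs)
        total = float(np.sum(self.d * het))
        if abs(total - 1.0) > _WEIGHT_NORM_TOL:
            raise ValueError(
                f"weights violate normalization sum d*2p(1-p) = 1 (got {total})")


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """Meuwissen & Luo inbreeding coefficients for a topologically
    ordered pedigree."""
    sire, dam = ped.parent_indices()
    n = len(ped)
    f = np.zeros(n)
    # L and D of A = L D L'; F_i = diag(A)_i - 1 computed animal by animal
    point = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            f[i] = 0.0
            continue
        fs = f[s] if s >= 0 else 0.0
        fd = f[d] if d >= 0 else 0.0
        d_i = 0.5 - 0.25 * (fs + fd)
        # trace ancestors of i accumulating L-row contributions
        point[:] = 0.0
        if s >= 0:
            point[s] += 0.5
        if d >= 0:
            point[d] += 0.5
        a_ii = d_i  # own Mendelian sampling term
        for j in range(i - 1, -1, -1):
            lj = point[j]
            if lj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            fsj = f[sj] if sj >= 0 else 0.0
            fdj = f[dj] if dj >= 0 else 0.0
            if sj >= 0 and dj >= 0:
                dj_var = 0.5 - 0.25 * (fsj + fdj)
            elif sj >= 0 or dj >= 0:
                dj_var = 0.75 - 0.25 * (fsj if sj >= 0 else fdj)
            else:
                dj_var = 1.0
            a_ii += lj * lj * dj_var
            if sj >= 0:
                point[sj] += 0.5 * lj
            if dj >= 0:
                point[dj] += 0.5 * lj
        f[i] = a_ii - 1.0
    return f


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    sire, dam = ped.parent_indices()
    n = len(ped)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * a[s, :i]
            if d >= 0:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
        a_sd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(a, ped.animals.copy(), kind="A")


def build_A22(ped: PedigreeTable, genotyped_ids: Sequence) -> RelationshipMatrix:
    """Pedigree relationship block for the genotyped individuals."""
    A = build_A(ped)
    out = A.submatrix(genotyped_ids)
    out.kind = "A22"
    return out


def build_A_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding."""
    sire, dam = ped.parent_indices()
    f = inbreeding_coefficients(ped)
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        fs = f[s] if s >= 0 else 0.0
        fd = f[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or d >= 0:
            di = 0.75 - 0.25 * (fs if s >= 0 else fd)
        else:
            di = 1.0
        k = 1.0 / di
        add(i, i, k)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * k)
                add(p, i, -0.5 * k)
                add(p, p, 0.25 * k)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * k)
            add(d, s, 0.25 * k)
            # diagonal 0.25k already added once per parent above
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return m


def initial_weights(panel: MarkerPanel) -> MarkerWeights:
    """Iteration-1 weights: inverse expected marker variance,
    D_ii = 1 / (m * 2 p_i (1 - p_i))."""
    p = panel.allele_freqs
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("fixed markers present; run QC before weighting")
    m = panel.n_markers
    d = 1.0 / (m * 2.0 * p * (1.0 - p))
    return MarkerWeights(d=d, allele_freqs=p.copy(), iteration=1)


def centered_Z(panel: MarkerPanel) -> np.ndarray:
    """Genotypes corrected by allele frequency: z = (g - 1) - (2p - 1),
    i.e. the 0/1/2 coding minus 2p; missing calls mean-imputed first."""
    g = mean_impute(panel)
    return g - 2.0 * panel.allele_freqs


def build_G(panel: MarkerPanel, weights: MarkerWeights) -> RelationshipMatrix:
    """Weighted genomic relationship matrix G = Z D Z'."""
    p = panel.allele_freqs
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("fixed markers present; run QC before building G")
    Z = centered_Z(panel)
    G = (Z * weights.d) @ Z.T
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, panel.ids.copy(), kind="G",
                              meta={"iteration": weights.iteration})


def blend_G(G: RelationshipMatrix, A22: RelationshipMatrix,
            alpha: float = 0.05) -> RelationshipMatrix:
    """G* = (1 - alpha) G + alpha A22; the standard positive-definiteness
    repair before inverting G."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if G.values.shape != A22.values.shape or not np.array_equal(G.ids, A22.ids):
        raise ValueError("G and A22 must share shape and ID order")
    out = (1.0 - alpha) * G.values + alpha * A22.values
    return RelationshipMatrix(out, G.ids.copy(), kind="G_weighted",
                              meta={**G.meta, "alpha": alpha})


def _inverse_or_raise(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        c = cho_factor(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} block is singular or not positive definite"
                         ) from exc
    return cho_solve(c, np.eye(mat.shape[0]))


def build_H_inverse(Ainv: sp.spmatrix, ped_ids: np.ndarray,
                    G_star: Optional[RelationshipMatrix],
                    A22: Optional[RelationshipMatrix]) -> HInverse:
    """Single-step H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1].

    With no genotyped individuals (G_star is None) this is exactly A^-1.
    """
    Ainv = sp.csr_matrix(Ainv)
    if G_star is None or G_star.values.shape[0] == 0:
        return HInverse(matrix=Ainv.copy(), ids=np.asarray(ped_ids),
                        genotyped_index=np.array([], dtype=np.int64))
    if A22 is None:
        raise ValueError("A22 required when genotyped individuals are present")
    if not np.array_equal(G_star.ids, A22.ids):
        raise ValueError("G* and A22 must share ID order")
    pos = {a: i for i, a in enumerate(ped_ids)}
    try:
        gidx = np.array([pos[a] for a in G_star.ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"genotyped individual {exc} not in pedigree") from exc

    Ginv = _inverse_or_raise(G_star.values, "G*")
    A22inv = _inverse_or_raise(A22.values, "A22")
    corr = Ginv - A22inv
    k = len(gidx)
    corr_sp = sp.coo_matrix(
        (corr.ravel(),
         (np.repeat(gidx, k), np.tile(gidx, k))),
        shape=Ainv.shape,
    ).tocsr()
    H = (Ainv + corr_sp).tocsr()
    return HInverse(matrix=H, ids=np.asarray(ped_ids), genotyped_index=gidx)
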