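"""Pedigree, genomic and combined relationship matrices.

* ``numerator_relationship`` — the pedigree numerator relationship matrix A
  by the tabular method (diagonal 1 + F, recursive parent averaging).
* ``inbreeding`` / ``a_inverse`` — inbreeding coefficients by the
  Meuwissen & Luo (1992) algorithm and the sparse direct construction of
  A^-1 by Henderson's rules with inbreeding.
* ``genomic_relationship`` — the VanRaden (2008) first G matrix:
  G = (M - P)(M - P)' / sum_j 2 p_j (1 - p_j), with M the allele-count
  matrix, P = 2 p_j the centering matrix of second-allele frequencies.
* ``blend_g`` — (1 - omega) G + omega A22, the standard fix that makes G
  invertible and nudges it onto the pedigree scale.
* ``h_inverse`` — the single-step combined matrix in its inverse form,
  H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block.

All matrices are dense (the package targets desk-scale pedigrees of a few
thousand animals); A^-1 is assembled from sparse triplets internally.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .containers import (
    UNKNOWN_PARENT,
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
)

__all__ = [
    "MatrixError",
    "numerator_relationship",
    "inbreeding",
    "a_inverse",
    "a22_from_full",
    "genomic_relationship",
    "blend_g",
    "tune_g",
    "h_inverse",
    "invert_psd",
]


class MatrixError(ValueError):
    """Singular or ill-conditioned relationship matrix."""


def invert_psd(values: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Invert a symmetric positive-definite matrix via Cholesky."""
    try:
        c = cho_factor(values, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(values)
        raise MatrixError(
            f"{name} is not positive definite (condition number {cond:.3e}); "
            "consider blending with A22"
        ) from exc
    inv = cho_solve(c, np.eye(values.shape[0]))
    return 0.5 * (inv + inv.T)


# ---------------------------------------------------------------------------
# pedigree-based matrices


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix A.

    a_ij = 0.5 (a_{s(i) j} + a_{d(i) j}) for j < i and
    a_ii = 1 + 0.5 a_{s(i) d(i)}; unknown parents contribute 0.
    """
    n = len(ped)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN_PARENT and d != UNKNOWN_PARENT:
            row = 0.5 * (a[s, :i] + a[d, :i])
            diag = 1.0 + 0.5 * a[s, d]
        elif s != UNKNOWN_PARENT:
            row = 0.5 * a[s, :i]
            diag = 1.0
        elif d != UNKNOWN_PARENT:
            row = 0.5 * a[d, :i]
            diag = 1.0
        else:
            row = np.zeros(i)
            diag = 1.0
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = diag
    return RelationshipMatrix(ids=ped.ids, values=a, kind="A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    For each animal the row of L (from A = LDL') is traced back through
    its ancestors; F_i = sum_j L_ij^2 D_j - 1.  Runs in O(n * ancestors^2)
    without ever forming A.
    """
    n = len(ped)
    f = np.zeros(n)
    d_within = np.zeros(n)  # Mendelian-sampling variance D_j, filled as we go

    for i in range(n):
        s, dd = ped.sire[i], ped.dam[i]
        if s != UNKNOWN_PARENT and dd != UNKNOWN_PARENT:
            d_within[i] = 0.5 - 0.25 * (f[s] + f[dd])
        elif s != UNKNOWN_PARENT:
            d_within[i] = 0.75 - 0.25 * f[s]
        elif dd != UNKNOWN_PARENT:
            d_within[i] = 0.75 - 0.25 * f[dd]
        else:
            d_within[i] = 1.0

        if s == UNKNOWN_PARENT or dd == UNKNOWN_PARENT:
            f[i] = 0.0
            continue

        # accumulate L-row coefficients over ancestors, youngest first
        coeff: dict[int, float] = {i: 1.0}
        aii = 0.0
        while coeff:
            j = max(coeff)
            lj = coeff.pop(j)
            aii += lj * lj * d_within[j]
            sj, dj = ped.sire[j], ped.dam[j]
            if sj != UNKNOWN_PARENT:
                coeff[sj] = coeff.get(sj, 0.0) + 0.5 * lj
            if dj != UNKNOWN_PARENT:
                coeff[dj] = coeff.get(dj, 0.0) + 0.5 * lj
        f[i] = aii - 1.0
    return f


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A^-1 assembled directly by Henderson's rules with inbreeding.

    Uses the Meuwissen-Luo inbreeding coefficients for the
    Mendelian-sampling variances, so the result is the exact inverse of
    the tabular A (not the non-inbred approximation).
    """
    n = len(ped)
    f = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN_PARENT and d != UNKNOWN_PARENT:
            alpha = 1.0 / (0.5 - 0.25 * (f[s] + f[d]))
            add(i, i, alpha)
            for p in (s, d):
                add(p, i, -alpha / 2.0)
                add(i, p, -alpha / 2.0)
                add(p, p, alpha / 4.0)
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)
        elif s != UNKNOWN_PARENT or d != UNKNOWN_PARENT:
            p = s if s != UNKNOWN_PARENT else d
            alpha = 1.0 / (0.75 - 0.25 * f[p])
            add(i, i, alpha)
            add(p, i, -alpha / 2.0)
            add(i, p, -alpha / 2.0)
            add(p, p, alpha / 4.0)
        else:
            add(i, i, 1.0)

    ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).toarray()
    return RelationshipMatrix(ids=ped.ids, values=ainv, kind="A_inverse")


def a22_from_full(a: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """A22: the genotyped-animal block of the full pedigree A."""
    return a.submatrix(genotyped_ids, kind="A22")


# ---------------------------------------------------------------------------
# genomic matrices


def genomic_relationship(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden G = (M - P)(M - P)' / sum_j 2 p_j (1 - p_j).

    ``freqs`` supplies the centering allele frequencies; by default the
    observed post-QC frequencies of the genotyped animals are used.
    Residual missing codes are mean-imputed to 2 p_j before centering, so
    a missing genotype contributes exactly zero to the cross-product.
    """
    p = np.asarray(freqs, dtype=float) if freqs is not None else geno.allele_frequencies()
    if len(p) != geno.n_snps:
        raise ValueError("frequency vector length must equal the SNP count")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise MatrixError(
            "sum 2p(1-p) is zero: the panel is monomorphic at the centering "
            "frequencies; run MAF filtering first"
        )
    m = geno.codes.astype(np.float64)
    missing = geno.missing_mask
    if missing.any():
        m[missing] = np.broadcast_to(2.0 * p, m.shape)[missing]
    z = m - 2.0 * p
    g = (z @ z.T) / denom
    return RelationshipMatrix(ids=geno.ids, values=g, kind="G")


def blend_g(
    g: RelationshipMatrix, a22: RelationshipMatrix, omega: float = 0.05
) -> RelationshipMatrix:
    """Blended genomic matrix G* = (1 - omega) G + omega A22."""
    if not 0.0 <= omega < 1.0:
        raise ValueError("omega must be in [0, 1)")
    if len(g) != len(a22) or not np.array_equal(np.sort(g.ids), np.sort(a22.ids)):
        raise MatrixError("G and A22 must cover the same animals")
    a22_aligned = a22.submatrix(g.ids).values
    return RelationshipMatrix(
        ids=g.ids,
        values=(1.0 - omega) * g.values + omega * a22_aligned,
        kind="G_blended",
        omega=omega,
    )


def tune_g(g: RelationshipMatrix, a22: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale G to A22 by the two-coefficient regression a + b*G.

    a and b are chosen so the mean diagonal and mean off-diagonal of the
    adjusted G match those of A22.  Optional: off by default in the
    pipeline (the blending step alone guarantees invertibility).
    """
    a22v = a22.submatrix(g.ids).values
    n = len(g)
    eye = np.eye(n, dtype=bool)
    gd, go = g.values[eye].mean(), g.values[~eye].mean() if n > 1 else 0.0
    ad, ao = a22v[eye].mean(), a22v[~eye].mean() if n > 1 else 0.0
    if np.isclose(gd, go):
        raise MatrixError("G diagonal and off-diagonal means coincide; cannot tune")
    b = (ad - ao) / (gd - go)
    a = ad - b * gd
    return RelationshipMatrix(
        ids=g.ids, values=a + b * g.values, kind="G", omega=g.omega
    )


# ---------------------------------------------------------------------------
# combined matrix


def h_inverse(
    a_inv: RelationshipMatrix,
    a22: RelationshipMatrix,
    g_blend: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """Single-step H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1].

    The correction G*^-1 - A22^-1 is added on the genotyped block of the
    full-pedigree A^-1; with no genotyped animals H^-1 is exactly A^-1.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    h = a_inv.values.copy()
    if len(genotyped_ids):
        g_inv = invert_psd(g_blend.submatrix(genotyped_ids).values, "blended G")
        a22_inv = invert_psd(a22.submatrix(genotyped_ids).values, "A22")
        idx = a_inv.index_of(genotyped_ids)
        h[np.ix_(idx, idx)] += g_inv - a22_inv
    return RelationshipMatrix(
        ids=a_inv.ids, values=h, kind="H_inverse", omega=g_blend.omega
    )
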