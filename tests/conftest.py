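"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by routes the package
does not use: generalized least squares from an explicitly inverted
phenotypic covariance, the combined relationship matrix in its explicit
joint (non-inverse) form, exact-rational Hardy-Weinberg enumeration, and
dense matrix inversion.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import inv

import ssgblup as ss
from ssgblup.models import build_design

# ---------------------------------------------------------------------------
# oracles


def gls_blup_oracle(phen, spec, k_values, k_ids, sigma_a2, sigma_e2):
    """BLUP via generalized least squares on V = ZKZ's_a + Is_e (dense).

    Independent of the MME route: builds the record-level covariance,
    inverts it directly, and applies the textbook GLS/BLUP formulas.
    """
    x, _, _ = build_design(phen, spec)
    lookup = {a: i for i, a in enumerate(k_ids)}
    idx = np.array([lookup[a] for a in phen["id"]])
    n, q = len(phen), len(k_ids)
    z = np.zeros((n, q))
    z[np.arange(n), idx] = 1.0
    y = phen[spec.trait].to_numpy(dtype=float)
    v = z @ k_values @ z.T * sigma_a2 + np.eye(n) * sigma_e2
    vi = inv(v)
    b = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    a = sigma_a2 * k_values @ z.T @ vi @ (y - x @ b)
    return b, a


def explicit_h(a_full: ss.RelationshipMatrix, g_blend: ss.RelationshipMatrix,
               genotyped_ids) -> np.ndarray:
    """The combined matrix H in its explicit joint form (Legarra):

    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21,  H12 = A12 A22^-1 G,
    H22 = G; ordered as a_full.ids."""
    q = len(a_full)
    gidx = a_full.index_of(genotyped_ids)
    gset = set(gidx.tolist())
    nidx = np.array([i for i in range(q) if i not in gset], dtype=int)
    a = a_full.values
    a22 = a[np.ix_(gidx, gidx)]
    a22i = inv(a22)
    g = g_blend.submatrix(a_full.ids[gidx]).values
    h = np.zeros((q, q))
    if len(nidx):
        a12 = a[np.ix_(nidx, gidx)]
        h[np.ix_(nidx, nidx)] = a[np.ix_(nidx, nidx)] + a12 @ a22i @ (g - a22) @ a22i @ a12.T
        h[np.ix_(nidx, gidx)] = a12 @ a22i @ g
        h[np.ix_(gidx, nidx)] = h[np.ix_(nidx, gidx)].T
    h[np.ix_(gidx, gidx)] = g
    return h


def hwe_exact_bruteforce(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational HWE p-value by full conditional enumeration.

    P(h het | allele counts) is proportional to 2^h / (n_AA! n_Aa! n_aa!);
    computed with Fractions, so exact up to the final float conversion.
    """
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        homr = (rare - het) // 2
        homc = n - het - homr
        if homr < 0 or homc < 0:
            continue
        # multinomial weight: n! / (homr! het! homc!) * 2^het
        w = Fraction(comb(n, het) * comb(n - het, homr)) * Fraction(2) ** het
        weights[het] = w
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


def random_pedigree(n: int, n_founders: int, seed: int) -> ss.Pedigree:
    """Random topologically ordered pedigree; non-founders draw two distinct
    earlier animals as parents (overlapping generations allowed)."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    ids = np.array([f"P{i:04d}" for i in range(n)])
    return ss.Pedigree(ids=ids, sire=sire, dam=dam)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_cfg() -> ss.SimConfig:
    return ss.SimConfig(
        n_founders=40,
        n_generations=2,
        matings_per_generation=25,
        offspring_per_mating=2,
        n_snps=500,
        n_phenotyped=80,
        genotyped_fraction=0.5,
        missing_rate=0.02,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(pedigree, full genotypes, phenotypes, truth, masked genotypes)."""
    return ss.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    ped, _, _, _, geno = small_dataset
    a = ss.numerator_relationship(ped)
    a_inv = ss.a_inverse(ped)
    g = ss.genomic_relationship(geno)
    a22 = ss.a22_from_full(a, geno.ids)
    g_blend = ss.blend_g(g, a22, omega=0.05)
    h_inv = ss.h_inverse(a_inv, a22, g_blend, geno.ids)
    return {"A": a, "A_inv": a_inv, "G": g, "A22": a22,
            "G_blend": g_blend, "H_inv": h_inv}


@pytest.fixture()
def trio() -> ss.Pedigree:
    """Two unrelated parents and one offspring."""
    return ss.Pedigree(
        ids=np.array(["sire", "dam", "kid"]),
        sire=np.array([-1, -1, 0]),
        dam=np.array([-1, -1, 1]),
    )


@pytest.fixture()
def fullsib_mating() -> ss.Pedigree:
    """Founders 1,2; full sibs 3,4; animal 5 = 3 x 4 (F = 0.25)."""
    return ss.Pedigree(
        ids=np.array(["a1", "a2", "a3", "a4", "a5"]),
        sire=np.array([-1, -1, 0, 0, 2]),
        dam=np.array([-1, -1, 1, 1, 3]),
    )


def make_phen(ids, y, **extra) -> pd.DataFrame:
    data = {"id": np.asarray(ids), "trait": np.asarray(y, dtype=float)}
    data.update(extra)
    return pd.DataFrame(data)
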