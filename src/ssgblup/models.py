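"""Henderson mixed-model equations: pedigree BLUP, GBLUP and ssGBLUP.

The animal model is y = Xb + Za + e with a ~ N(0, K sigma_a^2) and
e ~ N(0, I sigma_e^2), where K is the pedigree (A), blended genomic (G*)
or combined (H) relationship matrix.  Solutions come from the mixed-model
equations

    [ X'X        X'Z          ] [b]   [X'y]
    [ Z'X   Z'Z + lambda K^-1 ] [a] = [Z'y],   lambda = sigma_e^2 / sigma_a^2,

solved by dense Cholesky; breeding values are returned for every animal in
K, including unphenotyped ones.  Corrected phenotypes y_c = EBV + residual
(equivalently y - X b-hat) from a pedigree-BLUP fit serve as the response
for the genomic models, which fit an overall mean as their only fixed
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr

from .containers import RelationshipMatrix
from .kinship import invert_psd

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "CorrectedPhenotypes",
    "build_design",
    "solve_mme",
    "corrected_phenotypes",
    "gblup",
    "ssgblup",
]


@dataclass
class ModelSpec:
    """Fixed-effect structure of the animal model.

    Defaults match a slaughter-cohort design: categorical herd, slaughter
    year and slaughter month plus one numeric covariate (slaughter weight
    for meat-quality traits, fat content for fatty-acid traits).  Factors
    use reference coding (first level dropped) on top of an intercept.
    """

    trait: str = "trait"
    fixed_categorical: tuple[str, ...] = ("herd", "year", "month")
    covariates: tuple[str, ...] = ("covariate",)

    @classmethod
    def mean_only(cls, trait: str = "trait") -> "ModelSpec":
        return cls(trait=trait, fixed_categorical=(), covariates=())


@dataclass
class MixedModelFit:
    """Solutions of one mixed-model-equations solve."""

    fixed_effects: pd.Series
    breeding_values: pd.Series  # for ALL animals in K
    residuals: pd.Series  # phenotyped animals only
    sigma_a2: float
    sigma_e2: float
    kind: str  # relationship matrix kind used
    dropped_columns: list[str] = field(default_factory=list)
    fitted: pd.Series | None = None


@dataclass
class CorrectedPhenotypes:
    """y_c = EBV + residual per phenotyped animal, with provenance."""

    values: pd.Series
    provenance: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.values.index, "y_c": self.values.to_numpy()})


def build_design(
    phen: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix for the fixed part: intercept + reference-coded factors
    + covariates.  Rank deficiency is resolved by dropping dependent
    columns (pivoted QR); returns (X, kept column names, dropped names)."""
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    for factor in spec.fixed_categorical:
        dummies = pd.get_dummies(phen[factor].astype("category"), prefix=factor,
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(str(c))
    for cov in spec.covariates:
        cols.append(phen[cov].to_numpy(dtype=float))
        names.append(cov)
    x = np.column_stack(cols)

    # pivoted QR to detect (and drop) linearly dependent columns
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    return x[:, keep], [names[i] for i in keep], dropped


def solve_mme(
    phen: pd.DataFrame,
    spec: ModelSpec,
    k_inv: RelationshipMatrix,
    sigma_a2: float,
    sigma_e2: float,
) -> MixedModelFit:
    """Solve Henderson's MME for one trait.

    ``phen`` needs columns ``id``, the trait, and every fixed-effect
    column of ``spec``; every id must be present in ``k_inv``.  Breeding
    values are returned for all animals of ``k_inv``.
    """
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    y = phen[spec.trait].to_numpy(dtype=float)
    x, names, dropped = build_design(phen, spec)
    n, p = x.shape
    q = len(k_inv)
    idx = k_inv.index_of(phen["id"])

    lam = sigma_e2 / sigma_a2

    # Z is a record->animal selection matrix; assemble X'Z, Z'Z, Z'y by scatter
    xz = np.zeros((p, q))
    np.add.at(xz.T, idx, x)
    counts = np.bincount(idx, minlength=q).astype(float)
    zty = np.zeros(q)
    np.add.at(zty, idx, y)

    coeff = np.empty((p + q, p + q))
    coeff[:p, :p] = x.T @ x
    coeff[:p, p:] = xz
    coeff[p:, :p] = xz.T
    coeff[p:, p:] = lam * k_inv.values
    coeff[p + np.arange(q), p + np.arange(q)] += counts
    rhs = np.concatenate([x.T @ y, zty])

    try:
        c = cho_factor(coeff, lower=True)
        sol = cho_solve(c, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "MME coefficient matrix is not positive definite; check that the "
            "relationship matrix inverse is PD and fixed effects are estimable"
        ) from exc

    b_hat = sol[:p]
    a_hat = sol[p:]
    fitted = x @ b_hat + a_hat[idx]
    resid = y - fitted
    rec_index = pd.Index(phen["id"])
    return MixedModelFit(
        fixed_effects=pd.Series(b_hat, index=names),
        breeding_values=pd.Series(a_hat, index=k_inv.ids),
        residuals=pd.Series(resid, index=rec_index),
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        kind=k_inv.kind,
        dropped_columns=dropped,
        fitted=pd.Series(fitted, index=rec_index),
    )


def corrected_phenotypes(fit: MixedModelFit) -> CorrectedPhenotypes:
    """y_c = EBV + residual for each phenotyped animal.

    Expects a pedigree-BLUP fit on the full phenotyped set; algebraically
    y_c = y - X b-hat, i.e. the phenotype stripped of fixed effects.
    """
    ids = fit.residuals.index
    yc = fit.breeding_values.loc[ids].to_numpy() + fit.residuals.to_numpy()
    return CorrectedPhenotypes(
        values=pd.Series(yc, index=ids),
        provenance={
            "model": fit.kind,
            "sigma_a2": fit.sigma_a2,
            "sigma_e2": fit.sigma_e2,
        },
    )


def gblup(
    yc: CorrectedPhenotypes,
    g_blend: RelationshipMatrix,
    sigma_g2: float,
    sigma_e2: float,
    training_ids=None,
) -> MixedModelFit:
    """GBLUP on corrected phenotypes: y_c = 1 mu + Z g + e, g ~ N(0, G* sigma_g^2).

    Only genotyped animals carry data; ``training_ids`` (default: all
    genotyped animals with a y_c) restricts the response for
    cross-validation while GEBV are still returned for every animal in G*.
    """
    g_ids = set(g_blend.ids)
    if training_ids is None:
        training_ids = [a for a in yc.values.index if a in g_ids]
    else:
        training_ids = [a for a in training_ids if a in g_ids]
    phen = pd.DataFrame(
        {"id": training_ids, "trait": yc.values.loc[training_ids].to_numpy()}
    )
    k_inv = RelationshipMatrix(
        ids=g_blend.ids,
        values=invert_psd(g_blend.values, "blended G"),
        kind="G_blended",
        omega=g_blend.omega,
    )
    return solve_mme(phen, ModelSpec.mean_only(), k_inv, sigma_g2, sigma_e2)


def ssgblup(
    yc: CorrectedPhenotypes,
    h_inv: RelationshipMatrix,
    sigma_a2: float,
    sigma_e2: float,
    training_ids=None,
) -> MixedModelFit:
    """Single-step GBLUP: same mean-only model solved with K^-1 = H^-1.

    H is never formed.  All phenotyped animals in the pedigree contribute
    (genotyped or not); GEBV are returned for every pedigree animal.
    """
    h_ids = set(h_inv.ids)
    if training_ids is None:
        training_ids = [a for a in yc.values.index if a in h_ids]
    else:
        training_ids = [a for a in training_ids if a in h_ids]
    phen = pd.DataFrame(
        {"id": training_ids, "trait": yc.values.loc[training_ids].to_numpy()}
    )
    return solve_mme(phen, ModelSpec.mean_only(), h_inv, sigma_a2, sigma_e2)
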