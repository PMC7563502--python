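"""AIREML variance components and heritability for the single-trait animal model.

Estimates (sigma_a^2, sigma_e^2) by restricted maximum likelihood with
average-information (AI) updates.  The phenotypic covariance is
V = R sigma_a^2 + I sigma_e^2 with R = Z K Z' the relationship matrix
restricted to phenotyped records, so a single eigendecomposition
R = U L U' performed up front diagonalises V for every iteration: all
likelihoods, gradients and AI terms are then O(n p^2) per iteration.

Updates are EM-guarded: when an AI step leaves the parameter space or
decreases the restricted likelihood, the step is replaced by a damped
EM-type step and/or halved until the likelihood is non-decreasing, with a
variance floor of 1e-8 * Var(y).  Standard errors come from the inverse AI
matrix at convergence; the heritability SE uses the first-order delta
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .containers import RelationshipMatrix
from .kinship import invert_psd
from .models import ModelSpec, build_design

__all__ = ["VarianceComponents", "aireml", "heritability", "RemlError"]


class RemlError(RuntimeError):
    """AIREML failed to converge or inputs are unusable."""


@dataclass
class VarianceComponents:
    """Variance components with standard errors (one trait, one matrix)."""

    sigma_a2: float
    sigma_e2: float
    se_a2: float
    se_e2: float
    kind: str = "A"
    n_iter: int = 0
    converged: bool = True
    boundary: bool = False
    loglik: float = np.nan
    cov: np.ndarray | None = field(default=None, repr=False)
    trace: list = field(default_factory=list, repr=False)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def se_p2(self) -> float:
        if self.cov is None:
            return np.nan
        return float(np.sqrt(self.cov.sum()))

    @property
    def h2(self) -> float:
        return heritability(self.sigma_a2, self.sigma_e2)[0]

    @property
    def se_h2(self) -> float:
        return heritability(self.sigma_a2, self.sigma_e2, self.cov)[1]

    @classmethod
    def from_components(
        cls, sigma_a2: float, sigma_e2: float, kind: str = "A"
    ) -> "VarianceComponents":
        """Build from known components (worked-example identities only)."""
        return cls(sigma_a2=sigma_a2, sigma_e2=sigma_e2, se_a2=np.nan,
                   se_e2=np.nan, kind=kind)

    def to_dict(self) -> dict:
        return {
            "sigma_a2": self.sigma_a2,
            "se_a2": self.se_a2,
            "sigma_e2": self.sigma_e2,
            "se_e2": self.se_e2,
            "sigma_p2": self.sigma_p2,
            "se_p2": self.se_p2,
            "h2": self.h2,
            "se_h2": self.se_h2,
            "kind": self.kind,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "boundary": self.boundary,
            "loglik": self.loglik,
        }


def heritability(
    sigma_a2: float, sigma_e2: float, cov: np.ndarray | None = None
) -> tuple[float, float]:
    """h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2) with delta-method SE.

    ``cov`` is the 2x2 covariance of (sigma_a^2, sigma_e^2); without it the
    SE is NaN.  Raises on zero phenotypic variance.
    """
    sp2 = sigma_a2 + sigma_e2
    if sp2 <= 0:
        raise ValueError("phenotypic variance must be positive")
    h2 = sigma_a2 / sp2
    if cov is None:
        return h2, np.nan
    grad = np.array([sigma_e2, -sigma_a2]) / sp2**2
    return h2, float(np.sqrt(grad @ cov @ grad))


def _relationship_submatrix(
    k_matrix: RelationshipMatrix, ids
) -> np.ndarray:
    """R = K restricted to phenotyped ids; inverts *_inverse kinds first."""
    if k_matrix.kind.endswith("_inverse"):
        full = invert_psd(k_matrix.values, k_matrix.kind)
        k = RelationshipMatrix(ids=k_matrix.ids, values=full,
                               kind="A" if k_matrix.kind == "A_inverse" else "G")
    else:
        k = k_matrix
    idx = k.index_of(ids)
    return k.values[np.ix_(idx, idx)]


def aireml(
    phen: pd.DataFrame,
    spec: ModelSpec,
    k_matrix: RelationshipMatrix,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """AIREML for y = Xb + Za + e, a ~ N(0, K sigma_a^2).

    ``k_matrix`` may be the relationship matrix itself (kind A, A22, G,
    G_blended) or an inverse (A_inverse, H_inverse), which is inverted
    once up front.  ``init`` defaults to an even split of Var(y).
    """
    y = phen[spec.trait].to_numpy(dtype=float)
    n = len(y)
    x, _, _ = build_design(phen, spec)
    p = x.shape[1]
    if n <= p + 2:
        raise RemlError(f"need more than {p + 2} records, got {n}")

    r = _relationship_submatrix(k_matrix, phen["id"])
    lam_r, u = eigh(r)
    lam_r = np.clip(lam_r, 0.0, None)
    yr = u.T @ y
    xr = u.T @ x

    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    theta = np.array(init, dtype=float) if init is not None else np.array(
        [vary / 2.0, vary / 2.0]
    )
    theta = np.maximum(theta, floor)

    ones = np.ones(n)

    def evaluate(th):
        d = th[0] * lam_r + th[1]
        if np.any(d <= 0):
            return None
        w = xr / d[:, None]
        s = xr.T @ w
        try:
            cs = cho_factor(s, lower=True)
        except np.linalg.LinAlgError:
            return None
        beta = cho_solve(cs, w.T @ yr)
        py = yr / d - w @ beta
        ypy = float(yr @ py)
        _, logdet_s = np.linalg.slogdet(s)
        logl = -0.5 * (float(np.sum(np.log(d))) + logdet_s + ypy)

        def p_apply(v):
            return v / d - w @ cho_solve(cs, w.T @ v)

        # gradients: dV/dsigma_a2 = R (rotated: diag lam_r), dV/dsigma_e2 = I
        score = np.empty(2)
        quad = np.empty(2)
        for i, g in enumerate((lam_r, ones)):
            tr_pg = float(np.sum(g / d)) - float(
                np.trace(cho_solve(cs, w.T @ (g[:, None] * w)))
            )
            quad[i] = float(np.sum(g * py * py))
            score[i] = -0.5 * (tr_pg - quad[i])

        ua, ue = lam_r * py, py
        pua = p_apply(ua)
        ai = 0.5 * np.array(
            [[float(ua @ pua), float(ue @ pua)],
             [float(pua @ ue), float(ue @ p_apply(ue))]]
        )
        return {"logl": logl, "score": score, "ai": ai, "quad": quad,
                "tr_term": score, "d": d}

    state = evaluate(theta)
    if state is None:
        raise RemlError("invalid starting point for AIREML")
    history = []
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        ai, score = state["ai"], state["score"]
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            step = 2.0 * theta**2 * score / n  # damped EM-type ascent step

        candidate = np.maximum(theta + step, floor)
        # EM-guard: fall back / halve until likelihood does not decrease
        new_state = evaluate(candidate)
        halvings = 0
        while (new_state is None or new_state["logl"] < state["logl"] - 1e-10) \
                and halvings < 30:
            if halvings == 0 and new_state is None:
                # AI step left the parameter space: EM-type step instead
                candidate = np.maximum(theta + 2.0 * theta**2 * score / n, floor)
            else:
                candidate = np.maximum(theta + 0.5 * (candidate - theta), floor)
            new_state = evaluate(candidate)
            halvings += 1
        if new_state is None:
            raise RemlError("AIREML could not find an uphill step")

        rel_change = np.max(np.abs(candidate - theta) / (np.abs(theta) + floor))
        theta, state = candidate, new_state
        history.append(
            {"iter": n_iter, "sigma_a2": theta[0], "sigma_e2": theta[1],
             "loglik": state["logl"], "halvings": halvings}
        )
        if rel_change < tol:
            converged = True
            break

    if not converged and max_iter > 0:
        # quadratic AI convergence usually gets far below tol; treat a tiny
        # final step as converged, otherwise report failure with the trace
        last_steps = [abs(h2_ - h1_) for h1_, h2_ in zip(
            [h["loglik"] for h in history[:-1]], [h["loglik"] for h in history[1:]]
        )]
        if not (last_steps and last_steps[-1] < 1e-8):
            raise RemlError(
                f"AIREML did not converge in {max_iter} iterations "
                f"(final loglik {state['logl']:.6f}); trace attached"
            )
        converged = True

    boundary = bool(theta[0] <= floor * 1.01 or theta[1] <= floor * 1.01)
    try:
        cov = np.linalg.inv(state["ai"])
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return VarianceComponents(
        sigma_a2=float(theta[0]),
        sigma_e2=float(theta[1]),
        se_a2=float(se[0]) if not boundary else float("nan"),
        se_e2=float(se[1]),
        kind=k_matrix.kind,
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        loglik=float(state["logl"]),
        cov=cov,
        trace=history,
    )
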