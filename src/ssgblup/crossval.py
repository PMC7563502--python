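"""Replicated k-fold cross-validation of genomic prediction accuracy.

The genotyped animals are partitioned into five nearly equal folds, five
independent times.  Per fold, validation animals' corrected phenotypes are
removed from the training response, breeding values are re-predicted, and
the fold contributes n_i and r_i = corr(GEBV, y_c) over validation
animals.  The replicate-level accuracy is the n_i-weighted mean
correlation divided by sqrt(h^2) (the h^2-denominator variant is available
for sensitivity analysis); reported accuracy is the mean +/- SE over the
five replicate accuracies.  Dispersion bias is the OLS slope of y_c on
GEBV: 1 = unbiased, < 1 = over-dispersed predictions.

GBLUP trains on genotyped animals only; ssGBLUP additionally carries every
non-genotyped phenotyped animal in the reference through H^-1.  Both
methods reuse identical fold plans so their comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RelationshipMatrix
from .models import CorrectedPhenotypes, gblup, ssgblup

__all__ = [
    "FoldPlan",
    "CVData",
    "CVResult",
    "make_folds",
    "run_cv",
    "accuracy",
    "bias",
    "compare_methods",
]


@dataclass
class FoldPlan:
    """One validation set of one replicate."""

    replicate: int
    fold: int
    validation_ids: np.ndarray
    seed: int


@dataclass
class CVData:
    """Everything run_cv needs: response and relationship structures."""

    yc: CorrectedPhenotypes
    g_blend: RelationshipMatrix
    h_inv: RelationshipMatrix
    genotyped_ids: np.ndarray


@dataclass
class CVResult:
    """Per-fold statistics of one method over all replicates."""

    method: str
    folds: pd.DataFrame  # replicate, fold, n, r, slope, intercept
    plan_key: tuple = field(default=(), repr=False)

    @property
    def replicates(self) -> np.ndarray:
        return np.unique(self.folds["replicate"])


def make_folds(
    genotyped_ids, k: int = 5, replicates: int = 5, seed: int = 0
) -> list[FoldPlan]:
    """Random partitions into k folds with sizes differing by at most 1."""
    ids = np.asarray(genotyped_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} genotyped animals")
    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    plans = []
    for rep, ss in enumerate(child_seeds, start=1):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(ids)
        for fold, chunk in enumerate(np.array_split(perm, k), start=1):
            plans.append(
                FoldPlan(
                    replicate=rep,
                    fold=fold,
                    validation_ids=np.sort(chunk),
                    seed=seed,
                )
            )
    return plans


def _plan_key(plans: list[FoldPlan]) -> tuple:
    return tuple(
        (p.replicate, p.fold, tuple(p.validation_ids)) for p in plans
    )


def run_cv(
    method: str,
    data: CVData,
    plans: list[FoldPlan],
    sigma_a2: float,
    sigma_e2: float,
) -> CVResult:
    """Evaluate one method over all fold plans with fixed variance components.

    Validation animals' y_c are masked from the training response; GEBV
    for validation animals come from the refitted model (through
    relationships only) and are correlated with their held-out y_c.
    """
    if method not in ("gblup", "ssgblup"):
        raise ValueError("method must be 'gblup' or 'ssgblup'")
    yc_ids = np.asarray(data.yc.values.index)
    genotyped = set(data.genotyped_ids)
    rows = []
    for plan in plans:
        val = np.asarray(plan.validation_ids)
        val_set = set(val)
        if method == "gblup":
            training = [a for a in yc_ids if a in genotyped and a not in val_set]
            fit = gblup(data.yc, data.g_blend, sigma_a2, sigma_e2,
                        training_ids=training)
        else:
            training = [a for a in yc_ids if a not in val_set]
            fit = ssgblup(data.yc, data.h_inv, sigma_a2, sigma_e2,
                          training_ids=training)
        val_with_yc = [a for a in val if a in set(yc_ids)]
        if len(val_with_yc) < 3:
            raise ValueError(
                f"fold {plan.fold} of replicate {plan.replicate} has "
                f"{len(val_with_yc)} validation animals with phenotypes (<3)"
            )
        gebv = fit.breeding_values.loc[val_with_yc].to_numpy()
        ycv = data.yc.values.loc[val_with_yc].to_numpy()
        if np.var(gebv) == 0:
            raise ValueError("validation GEBV have zero variance; slope undefined")
        r = float(np.corrcoef(gebv, ycv)[0, 1])
        slope, intercept = np.polyfit(gebv, ycv, 1)
        rows.append(
            {
                "replicate": plan.replicate,
                "fold": plan.fold,
                "n": len(val_with_yc),
                "r": r,
                "slope": float(slope),
                "intercept": float(intercept),
            }
        )
    return CVResult(
        method=method, folds=pd.DataFrame(rows), plan_key=_plan_key(plans)
    )


def accuracy(
    cv: CVResult, h2: float, denominator: str = "sqrt_h2"
) -> tuple[float, float]:
    """Weighted cross-validation accuracy, mean +/- SE over replicates.

    Per replicate: sum_i n_i r_i / sum_i n_i, divided by sqrt(h^2)
    (default) or h^2.  The SE is over the replicate-level accuracies.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if denominator not in ("sqrt_h2", "h2"):
        raise ValueError("denominator must be 'sqrt_h2' or 'h2'")
    denom = np.sqrt(h2) if denominator == "sqrt_h2" else h2
    per_rep = []
    for rep, grp in cv.folds.groupby("replicate"):
        wr = np.average(grp["r"], weights=grp["n"])
        per_rep.append(wr / denom)
    per_rep = np.asarray(per_rep)
    se = per_rep.std(ddof=1) / np.sqrt(len(per_rep)) if len(per_rep) > 1 else np.nan
    return float(per_rep.mean()), float(se)


def bias(cv: CVResult) -> tuple[float, float]:
    """Dispersion-bias slope: n_i-weighted mean over all fold cells,
    SE over replicate-level weighted means."""
    per_rep = []
    for rep, grp in cv.folds.groupby("replicate"):
        per_rep.append(np.average(grp["slope"], weights=grp["n"]))
    per_rep = np.asarray(per_rep)
    overall = float(np.average(cv.folds["slope"], weights=cv.folds["n"]))
    se = per_rep.std(ddof=1) / np.sqrt(len(per_rep)) if len(per_rep) > 1 else np.nan
    return overall, float(se)


def compare_methods(
    res_gblup: CVResult, res_ssgblup: CVResult, h2: float,
    denominator: str = "sqrt_h2", trait: str = "trait",
) -> pd.DataFrame:
    """Paired comparison table: accuracy, bias and % improvement.

    Improvement is 100 * (acc_ssGBLUP - acc_GBLUP) / acc_GBLUP.  Requires
    both results to have been computed on identical fold plans.
    """
    if res_gblup.plan_key != res_ssgblup.plan_key:
        raise ValueError("fold plans differ between methods; comparison unpaired")
    rows = []
    accs = {}
    for res in (res_gblup, res_ssgblup):
        acc, acc_se = accuracy(res, h2, denominator)
        slope, slope_se = bias(res)
        accs[res.method] = acc
        rows.append(
            {
                "trait": trait,
                "method": res.method,
                "accuracy": acc,
                "accuracy_se": acc_se,
                "bias_slope": slope,
                "bias_slope_se": slope_se,
                "h2_used": h2,
            }
        )
    improvement = 100.0 * (accs["ssgblup"] - accs["gblup"]) / accs["gblup"]
    for row in rows:
        row["improvement_pct"] = improvement if row["method"] == "ssgblup" else 0.0
    return pd.DataFrame(rows)
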