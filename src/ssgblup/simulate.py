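"""Synthetic Duroc-like dataset generator.

Produces the three inputs of a single-step genomic evaluation — a deep
pedigree, SNP genotypes and phenotypes with a herd/slaughter-year/
slaughter-month + covariate fixed-effect structure — together with the
ground truth (true breeding values, true SNP effects, realized
heritability) needed for parameter-recovery tests.

The default profile mirrors the cohort the package is designed around:
a pedigree of 4498 animals built from 1498 founders plus three discrete
non-overlapping generations of 500 matings x 2 offspring, 1237 phenotyped
animals drawn from the two most recent generations, a genotyped subset of
~654 of the phenotyped animals, and a lightness-like trait
(sigma_p = 9.10, h2 = 0.45).  Mating is random with no selection; SNPs are
unlinked ("gene dropping"), so the genotypes carry pedigree relatedness
but no LD structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING_CODE, UNKNOWN_PARENT, GenotypeMatrix, Pedigree

__all__ = [
    "ConfigError",
    "FixedEffectSpec",
    "SimConfig",
    "TruthRecord",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "mask_genotyped_subset",
    "simulate_dataset",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class FixedEffectSpec:
    """Levels and effect sizes for the fixed part of the animal model.

    Effects for herd (5 levels), slaughter year (8) and slaughter month
    (12) are drawn once per simulation from centered normals with the
    given SDs (trait units), unless explicit per-level effect vectors are
    supplied.  The single covariate emulates slaughter weight: drawn
    N(covariate_mean, covariate_sd^2) and entering the phenotype centered,
    scaled by ``covariate_slope``.
    """

    n_herds: int = 5
    n_years: int = 8
    n_months: int = 12
    herd_sd: float = 1.5
    year_sd: float = 1.0
    month_sd: float = 0.5
    herd_effects: list[float] | None = None
    year_effects: list[float] | None = None
    month_effects: list[float] | None = None
    covariate_slope: float = 0.1
    covariate_mean: float = 97.25
    covariate_sd: float = 8.78
    intercept: float = 49.24


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    The pedigree has ``n_founders`` unrelated founders (generation 0) and
    ``n_generations`` further generations, each produced by
    ``matings_per_generation`` random sire x dam pairs from the previous
    generation with ``offspring_per_mating`` offspring each.
    """

    n_founders: int = 1498
    n_generations: int = 3
    matings_per_generation: int = 500
    offspring_per_mating: int = 2
    n_snps: int = 10_000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    h2_true: float = 0.45
    sigma_p_true: float = 9.10
    fixed_effect_spec: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    n_phenotyped: int = 1237
    genotyped_fraction: float = 654 / 1237
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders must be at least 2")
        if self.n_snps < 1:
            raise ConfigError("need at least one SNP")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("founder_freq_range must lie inside (0, 1)")
        if not 0.0 <= self.h2_true < 1.0:
            raise ConfigError("h2_true must be in [0, 1)")
        if self.sigma_p_true <= 0:
            raise ConfigError("sigma_p_true must be positive")
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ConfigError("genotyped_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream ``stream`` of the configured seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset (for recovery tests/reports)."""

    true_breeding_values: pd.Series
    true_snp_effects: np.ndarray
    true_fixed_effects: dict
    sigma_a2_true: float
    sigma_e2_true: float
    realized_h2: float

    def write_json(self, path: str | Path) -> None:
        payload = {
            "sigma_a2_true": self.sigma_a2_true,
            "sigma_e2_true": self.sigma_e2_true,
            "realized_h2": self.realized_h2,
            "true_fixed_effects": {
                k: (list(v) if isinstance(v, (list, np.ndarray)) else v)
                for k, v in self.true_fixed_effects.items()
            },
            "true_breeding_values": {
                str(k): float(v) for k, v in self.true_breeding_values.items()
            },
            "true_snp_effects": [float(u) for u in self.true_snp_effects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree, topologically ordered."""
    rng = cfg.rng(0)
    sires: list[int] = [UNKNOWN_PARENT] * cfg.n_founders
    dams: list[int] = [UNKNOWN_PARENT] * cfg.n_founders
    gens: list[int] = [0] * cfg.n_founders
    prev_gen = list(range(cfg.n_founders))

    for g in range(1, cfg.n_generations + 1):
        this_gen: list[int] = []
        for _ in range(cfg.matings_per_generation):
            sire, dam = rng.choice(len(prev_gen), size=2, replace=False)
            for _ in range(cfg.offspring_per_mating):
                sires.append(prev_gen[sire])
                dams.append(prev_gen[dam])
                gens.append(g)
                this_gen.append(len(sires) - 1)
        prev_gen = this_gen

    n = len(sires)
    width = len(str(n))
    ids = np.array([f"ID{str(i + 1).zfill(width)}" for i in range(n)])
    return Pedigree(
        ids=ids,
        sire=np.array(sires),
        dam=np.array(dams),
        generation=np.array(gens),
    )


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop unlinked SNPs through the pedigree.

    Founders draw two alleles independently at frequency
    p_j ~ Uniform(founder_freq_range); every non-founder inherits one
    allele from each parent, chosen uniformly at heterozygous sites.
    The drawn founder frequencies are stored in ``freq``.
    """
    rng = cfg.rng(1)
    n, m = len(ped), cfg.n_snps
    p = rng.uniform(*cfg.founder_freq_range, size=m)
    codes = np.empty((n, m), dtype=np.int8)

    def gamete(parent_row: np.ndarray) -> np.ndarray:
        out = (parent_row == 2).astype(np.int8)
        het = parent_row == 1
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        return out

    for i in range(n):
        if ped.sire[i] == UNKNOWN_PARENT and ped.dam[i] == UNKNOWN_PARENT:
            codes[i] = rng.binomial(2, p).astype(np.int8)
        else:
            codes[i] = gamete(codes[ped.sire[i]]) + gamete(codes[ped.dam[i]])

    return GenotypeMatrix(
        ids=ped.ids,
        snp_ids=np.array([f"SNP{j + 1}" for j in range(m)]),
        codes=codes,
        freq=p,
    )


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes under an additive animal model with fixed effects.

    SNP effects are drawn N(0, sigma_a2 / sum 2 p_j (1 - p_j)) at the
    founder frequencies, so true breeding values (centered genotypes times
    effects) have variance ~ h2_true * sigma_p_true on the same scale as
    the genomic relationship matrix.  Phenotypes are assigned to the
    ``n_phenotyped`` animals sampled from the two most recent generations.
    """
    if geno.n_animals != len(ped):
        raise ConfigError("genotypes must cover all pedigree animals")
    rng = cfg.rng(2)
    fx = cfg.fixed_effect_spec
    m = geno.n_snps
    p = geno.freq if geno.freq is not None else geno.allele_frequencies()

    sigma_a2 = cfg.h2_true * cfg.sigma_p_true
    sigma_e2 = (1.0 - cfg.h2_true) * cfg.sigma_p_true
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    u = (
        rng.normal(0.0, np.sqrt(sigma_a2 / denom), size=m)
        if sigma_a2 > 0
        else np.zeros(m)
    )
    tbv = (geno.codes.astype(float) - 2.0 * p) @ u

    # phenotyped subset: recent generations first
    if ped.generation is not None and cfg.n_generations >= 1:
        recent = np.nonzero(ped.generation >= max(1, cfg.n_generations - 1))[0]
    else:
        recent = np.arange(len(ped))
    n_phen = min(cfg.n_phenotyped, len(recent))
    phen_idx = np.sort(rng.choice(recent, size=n_phen, replace=False))

    herd_eff = (
        np.asarray(fx.herd_effects, dtype=float)
        if fx.herd_effects is not None
        else rng.normal(0.0, fx.herd_sd, size=fx.n_herds)
    )
    year_eff = (
        np.asarray(fx.year_effects, dtype=float)
        if fx.year_effects is not None
        else rng.normal(0.0, fx.year_sd, size=fx.n_years)
    )
    month_eff = (
        np.asarray(fx.month_effects, dtype=float)
        if fx.month_effects is not None
        else rng.normal(0.0, fx.month_sd, size=fx.n_months)
    )

    herd = rng.integers(0, len(herd_eff), size=n_phen)
    year = rng.integers(0, len(year_eff), size=n_phen)
    month = rng.integers(0, len(month_eff), size=n_phen)
    covariate = rng.normal(fx.covariate_mean, fx.covariate_sd, size=n_phen)
    resid = rng.normal(0.0, np.sqrt(sigma_e2), size=n_phen)

    y = (
        fx.intercept
        + herd_eff[herd]
        + year_eff[year]
        + month_eff[month]
        + fx.covariate_slope * (covariate - fx.covariate_mean)
        + tbv[phen_idx]
        + resid
    )

    phen = pd.DataFrame(
        {
            "id": ped.ids[phen_idx],
            "trait": y,
            "herd": [f"H{h + 1}" for h in herd],
            "year": [f"Y{v + 1}" for v in year],
            "month": [f"M{mo + 1}" for mo in month],
            "covariate": covariate,
        }
    )

    var_tbv = float(np.var(tbv[phen_idx], ddof=1)) if n_phen > 1 else 0.0
    truth = TruthRecord(
        true_breeding_values=pd.Series(tbv, index=ped.ids),
        true_snp_effects=u,
        true_fixed_effects={
            "intercept": fx.intercept,
            "herd": herd_eff,
            "year": year_eff,
            "month": month_eff,
            "covariate_slope": fx.covariate_slope,
        },
        sigma_a2_true=sigma_a2,
        sigma_e2_true=sigma_e2,
        realized_h2=var_tbv / (var_tbv + sigma_e2) if var_tbv + sigma_e2 > 0 else 0.0,
    )
    return phen, truth


# ---------------------------------------------------------------------------
# genotyped subset / missingness


def mask_genotyped_subset(
    geno: GenotypeMatrix, cfg: SimConfig, phenotyped_ids=None
) -> GenotypeMatrix:
    """Restrict to the genotyped subset and inject missing calls.

    The genotyped animals are a uniform random draw of
    ``genotyped_fraction`` of ``phenotyped_ids`` (or of all animals when no
    phenotype list is given — the cohort membership is the only criterion,
    mirroring a study where which animals got chipped is unrecorded).
    Missing codes are then injected uniformly at ``missing_rate``.
    """
    rng = cfg.rng(3)
    pool = (
        np.asarray(phenotyped_ids)
        if phenotyped_ids is not None
        else np.asarray(geno.ids)
    )
    n_geno = int(round(cfg.genotyped_fraction * len(pool)))
    chosen = np.sort(rng.choice(len(pool), size=n_geno, replace=False))
    chosen_ids = set(pool[chosen])
    keep = np.array([a in chosen_ids for a in geno.ids])
    sub = geno.subset(animals=keep)

    if cfg.missing_rate > 0:
        mask = rng.random(sub.codes.shape) < cfg.missing_rate
        codes = sub.codes.copy()
        codes[mask] = MISSING_CODE
        sub = GenotypeMatrix(
            ids=sub.ids,
            snp_ids=sub.snp_ids,
            codes=codes,
            chrom=sub.chrom,
            pos=sub.pos,
        )
    return sub


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: pedigree, full genotypes, phenotypes, truth and
    the masked genotyped subset, in one call."""
    ped = simulate_pedigree(cfg)
    geno_full = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, geno_full, cfg)
    geno = mask_genotyped_subset(geno_full, cfg, phenotyped_ids=phen["id"].to_numpy())
    return ped, geno_full, phen, truth, geno


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["founder_freq_range"] = list(cfg.founder_freq_range)
    return d
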