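"""Genotype quality control: call rate, MAF and exact Hardy-Weinberg filters.

Filters and default thresholds follow routine SNP-chip practice for
livestock panels: drop high-missingness animals first (call rate < 0.90),
then drop SNPs with call rate < 0.90, minor allele frequency < 0.01, or an
exact Hardy-Weinberg test p-value < 1e-7.  All comparisons are strict
("lower than"), so a SNP sitting exactly on a threshold is retained.

The HWE test is the exact conditional test (Wigginton, Cutler & Abecasis
2005): given the observed allele counts, the distribution of the
heterozygote count under Hardy-Weinberg equilibrium is computed exactly and
the two-sided p-value sums the probabilities of all configurations no more
probable than the observed one.  A chi-square approximation would be
useless at p = 1e-7 with rare alleles, which is why the exact test is the
field default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING_CODE, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "snp_call_rate",
    "animal_call_rate",
    "minor_allele_frequency",
    "hwe_exact_test",
    "apply_qc",
    "EmptyAfterQCError",
]


class EmptyAfterQCError(ValueError):
    """Every animal or every SNP was removed by quality control."""


@dataclass
class QCThresholds:
    """Strict lower bounds: entities *below* a threshold are removed."""

    min_snp_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_p_min: float = 1e-7
    min_animal_call_rate: float = 0.90

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_maf", "hwe_p_min", "min_animal_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-stage counts and per-SNP statistics for an apply_qc run.

    ``steps`` rows record, in application order (animal call rate, SNP call
    rate, MAF, HWE), how many animals/SNPs survived each filter.  The
    animal call-rate rule runs first — standard practice, since sample-level
    missingness otherwise contaminates every SNP statistic.
    """

    steps: pd.DataFrame
    snp_stats: pd.DataFrame
    removed_animals: list = field(default_factory=list)
    removed_snps: dict = field(default_factory=dict)

    @property
    def n_snps_before(self) -> int:
        return int(self.steps["n_snps_before"].iloc[0])

    @property
    def n_snps_after(self) -> int:
        return int(self.steps["n_snps_after"].iloc[-1])

    @property
    def n_animals_before(self) -> int:
        return int(self.steps["n_animals_before"].iloc[0])

    @property
    def n_animals_after(self) -> int:
        return int(self.steps["n_animals_after"].iloc[-1])

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# genotype QC report; filter order: animal call rate, "
                     "SNP call rate, MAF, HWE exact test\n")
            fh.write("# note: the animal call-rate rule is the package's "
                     "inference for sample exclusions, applied before SNP stats\n")
            self.steps.to_csv(fh, index=False)


def snp_call_rate(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    if geno.n_animals == 0:
        raise ValueError("genotype matrix has no animals")
    return (geno.codes != MISSING_CODE).mean(axis=0)


def animal_call_rate(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per animal."""
    if geno.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    return (geno.codes != MISSING_CODE).mean(axis=1)


def minor_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """min(p, 1-p) per SNP from observed calls; NaN for all-missing SNPs."""
    p = geno.allele_frequencies()
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes its conditional probability under HWE by a stable
    two-directional recurrence from the most probable configuration, and
    returns the summed probability of all configurations at most as
    probable as the observed one.  Always in (0, 1]; monomorphic input has
    a single possible configuration and returns exactly 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")

    obs_hets = n_Aa
    rare = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    if rare == 0 or rare == 2 * n:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0

    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het > 1:
        probs[het - 2] = probs[het] * het * (het - 1.0) / (
            4.0 * (homr + 1.0) * (homc + 1.0)
        )
        het -= 2
        homr += 1
        homc += 1

    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * homr * homc / (
            (het + 2.0) * (het + 1.0)
        )
        het += 2
        homr -= 1
        homc -= 1

    probs /= probs.sum()
    p = float(probs[probs <= probs[obs_hets] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per SNP (NaN for all-missing SNPs)."""
    out = np.empty(geno.n_snps)
    for j in range(geno.n_snps):
        col = geno.codes[:, j]
        n0 = int(np.sum(col == 0))
        n1 = int(np.sum(col == 1))
        n2 = int(np.sum(col == 2))
        out[j] = hwe_exact_test(n0, n1, n2) if n0 + n1 + n2 > 0 else np.nan
    return out


def apply_qc(
    geno: GenotypeMatrix, thr: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full filter cascade and return (filtered, report).

    Order: animals below ``min_animal_call_rate`` are removed first; SNP
    call rate, MAF and HWE are then computed on the surviving animals and
    applied in that sequence.  A SNP with no observed calls fails the
    call-rate rule (rate 0) unless the threshold is 0, in which case its
    undefined MAF flags it for removal there.
    """
    thr = thr or QCThresholds()
    steps = []
    n_animals0, n_snps0 = geno.n_animals, geno.n_snps

    acr = animal_call_rate(geno)
    keep_animals = acr >= thr.min_animal_call_rate
    removed_animals = list(geno.ids[~keep_animals])
    geno1 = geno.subset(animals=keep_animals)
    steps.append(("animal_call_rate", n_animals0, geno1.n_animals, n_snps0, n_snps0))
    if geno1.n_animals == 0:
        raise EmptyAfterQCError("no animals left after call-rate filter")

    scr = snp_call_rate(geno1)
    maf = minor_allele_frequency(geno1)
    removed_snps: dict[str, list] = {}

    keep = scr >= thr.min_snp_call_rate
    removed_snps["call_rate"] = list(geno1.snp_ids[~keep])
    n_before = geno1.n_snps
    geno2 = geno1.subset(snps=keep)
    maf2 = maf[keep]
    steps.append(("snp_call_rate", geno1.n_animals, geno1.n_animals, n_before, geno2.n_snps))

    keep = ~np.isnan(maf2) & (maf2 >= thr.min_maf)
    if thr.min_maf == 0:
        keep = ~np.isnan(maf2)  # undefined MAF still flags removal
    removed_snps["maf"] = list(geno2.snp_ids[~keep])
    n_before = geno2.n_snps
    geno3 = geno2.subset(snps=keep)
    steps.append(("maf", geno2.n_animals, geno2.n_animals, n_before, geno3.n_snps))

    hwe = hwe_pvalues(geno3)
    keep = hwe >= thr.hwe_p_min
    removed_snps["hwe"] = list(geno3.snp_ids[~keep])
    n_before = geno3.n_snps
    geno4 = geno3.subset(snps=keep)
    steps.append(("hwe", geno3.n_animals, geno3.n_animals, n_before, geno4.n_snps))

    if geno4.n_snps == 0:
        raise EmptyAfterQCError("no SNPs left after quality control")

    snp_stats = pd.DataFrame(
        {
            "snp": geno1.snp_ids,
            "call_rate": scr,
            "maf": maf,
        }
    )
    hwe_map = dict(zip(geno3.snp_ids, hwe))
    snp_stats["hwe_p"] = [hwe_map.get(s, np.nan) for s in geno1.snp_ids]

    report = QCReport(
        steps=pd.DataFrame(
            steps,
            columns=[
                "stage",
                "n_animals_before",
                "n_animals_after",
                "n_snps_before",
                "n_snps_after",
            ],
        ),
        snp_stats=snp_stats,
        removed_animals=removed_animals,
        removed_snps=removed_snps,
    )
    return geno4, report
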