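"""Core data containers shared across the evaluation pipeline.

Three in-memory objects flow through every stage:

* :class:`Pedigree` — animal/sire/dam triples in topological order, the
  substrate for the numerator relationship matrix A and its inverse.
* :class:`GenotypeMatrix` — animals x SNPs allele-count codes (0/1/2,
  ``-1`` = missing), the substrate for the VanRaden genomic relationship
  matrix G.
* :class:`RelationshipMatrix` — a dense square symmetric matrix tagged with
  its kind (A, A_inverse, A22, G, G_blended, H_inverse) and indexed by
  animal id.

Phenotypes travel as a plain :class:`pandas.DataFrame` with one row per
record and columns ``id``, the trait value, the categorical fixed effects
(herd / slaughter year / slaughter month) and a numeric covariate; no
wrapper class is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN_PARENT = -1
MISSING_CODE = -1

__all__ = [
    "UNKNOWN_PARENT",
    "MISSING_CODE",
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "PedigreeError",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    ids
        Animal identifiers, in an order where every parent precedes its
        offspring.
    sire, dam
        Integer positions (into ``ids``) of each animal's parents, or
        :data:`UNKNOWN_PARENT` for unknown.
    generation
        Optional generation number per animal (founders = 0).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == n):
            raise PedigreeError("ids, sire and dam must have equal length")
        if len(np.unique(self.ids)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        for parents in (self.sire, self.dam):
            known = parents != UNKNOWN_PARENT
            if np.any(parents[known] < 0) or np.any(parents[known] >= n):
                raise PedigreeError("parent index out of range")
            # topological order: parents strictly precede offspring
            if np.any(parents[known] >= np.nonzero(known)[0]):
                raise PedigreeError(
                    "pedigree not topologically ordered (parent after offspring)"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(
            np.sum((self.sire == UNKNOWN_PARENT) & (self.dam == UNKNOWN_PARENT))
        )

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` within the pedigree ordering."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in np.asarray(ids)], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame with 0 = unknown parent (file convention)."""
        sire_id = np.zeros(len(self.ids), dtype=object)
        dam_id = np.zeros(len(self.ids), dtype=object)
        known_s = self.sire != UNKNOWN_PARENT
        known_d = self.dam != UNKNOWN_PARENT
        sire_id[known_s] = self.ids[self.sire[known_s]]
        dam_id[known_d] = self.ids[self.dam[known_d]]
        return pd.DataFrame({"id": self.ids, "sire": sire_id, "dam": dam_id})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from an (id, sire, dam) table; 0 or NA = unknown parent."""
        ids = frame["id"].to_numpy()
        lookup = {a: i for i, a in enumerate(ids)}

        def resolve(col: pd.Series) -> np.ndarray:
            out = np.full(len(frame), UNKNOWN_PARENT, dtype=np.int64)
            for i, v in enumerate(col):
                if pd.isna(v) or v == 0 or v == "0":
                    continue
                if v not in lookup:
                    raise PedigreeError(f"parent {v!r} has no own pedigree row")
                out[i] = lookup[v]
            return out

        return cls(ids=ids, sire=resolve(frame["sire"]), dam=resolve(frame["dam"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-count codes with missingness.

    ``codes[i, j]`` counts copies of the second (B) allele at SNP ``j`` for
    animal ``i``: 0, 1 or 2, with :data:`MISSING_CODE` for no-calls.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    freq: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snp_ids)} SNPs"
            )
        valid = np.isin(self.codes, (MISSING_CODE, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.chrom is None:
            self.chrom = np.ones(len(self.snp_ids), dtype=np.int64)
        if self.pos is None:
            self.pos = np.arange(1, len(self.snp_ids) + 1, dtype=np.int64)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING_CODE

    def allele_frequencies(self) -> np.ndarray:
        """Observed B-allele frequency per SNP (NaN where all calls missing)."""
        obs = self.codes != MISSING_CODE
        n_obs = obs.sum(axis=0)
        totals = np.where(obs, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, totals / (2.0 * n_obs), np.nan)

    def subset(self, *, animals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer positions."""
        ai = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ai.dtype == bool:
            ai = np.nonzero(ai)[0]
        if si.dtype == bool:
            si = np.nonzero(si)[0]
        return GenotypeMatrix(
            ids=self.ids[ai],
            snp_ids=self.snp_ids[si],
            codes=self.codes[np.ix_(ai, si)],
            chrom=self.chrom[si],
            pos=self.pos[si],
        )


@dataclass
class RelationshipMatrix:
    """Dense square symmetric relationship matrix indexed by animal id.

    ``kind`` tags the matrix role: ``A``, ``A_inverse``, ``A22``, ``G``,
    ``G_blended`` or ``H_inverse``.  ``omega`` records the blending weight
    for ``G_blended`` (and is carried through to ``H_inverse``).
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str
    omega: float | None = None

    _KINDS = ("A", "A_inverse", "A22", "G", "G_blended", "H_inverse")

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over ids")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {self._KINDS}")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")
        # enforce exact symmetry so downstream Cholesky factorisations are clean
        self.values = 0.5 * (self.values + self.values.T)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        return np.array([lookup[a] for a in np.asarray(ids)], dtype=np.int64)

    def submatrix(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            ids=self.ids[idx],
            values=self.values[np.ix_(idx, idx)],
            kind=kind or self.kind,
            omega=self.omega,
        )

    def write_triplets(self, path: str | Path, *, tol: float = 0.0) -> None:
        """Export as (id_i, id_j, value) triplet CSV, lower triangle only."""
        i, j = np.tril_indices(len(self.ids))
        v = self.values[i, j]
        keep = np.abs(v) > tol
        pd.DataFrame(
            {"id_i": self.ids[i[keep]], "id_j": self.ids[j[keep]], "value": v[keep]}
        ).to_csv(path, index=False)

    @classmethod
    def read_triplets(
        cls, path: str | Path, kind: str, ids=None
    ) -> "RelationshipMatrix":
        df = pd.read_csv(path)
        if ids is None:
            ids = pd.unique(pd.concat([df["id_i"], df["id_j"]]))
        ids = np.asarray(ids)
        lookup = {a: i for i, a in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        ii = df["id_i"].map(lookup).to_numpy()
        jj = df["id_j"].map(lookup).to_numpy()
        vals[ii, jj] = df["value"].to_numpy()
        vals[jj, ii] = df["value"].to_numpy()
        return cls(ids=ids, values=vals, kind=kind)
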