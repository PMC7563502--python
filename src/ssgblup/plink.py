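"""Text PLINK PED/MAP reading and writing.

Genotypes are stored with alleles ``A`` (first) and ``B`` (second); the
allele-count code of :class:`~ssgblup.containers.GenotypeMatrix` counts
copies of ``B``, matching the "frequency of the second allele" convention
used when centering the genomic relationship matrix.  Missing genotypes are
written as ``0 0``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import MISSING_CODE, GenotypeMatrix

__all__ = ["write_ped_map", "read_ped_map"]

_CODE_TO_ALLELES = {MISSING_CODE: ("0", "0"), 0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}


def write_ped_map(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for chrom, snp, pos in zip(geno.chrom, geno.snp_ids, geno.pos):
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")

    with open(ped_path, "w") as fh:
        for animal, row in zip(geno.ids, geno.codes):
            fields = ["FAM", str(animal), "0", "0", "0", "-9"]
            for code in row:
                fields.extend(_CODE_TO_ALLELES[int(code)])
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read ``<prefix>.ped`` / ``<prefix>.map`` back into a GenotypeMatrix.

    Allele codes are recomputed per SNP: the lexicographically larger of the
    two observed allele symbols is counted (so files written by
    :func:`write_ped_map` round-trip exactly: ``B`` is counted).
    """
    prefix = Path(prefix)
    snp_ids, chroms, poss = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chroms.append(parts[0])
            snp_ids.append(parts[1])
            poss.append(int(parts[3]))
    m = len(snp_ids)

    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U2").reshape(len(ids), m, 2)

    codes = np.full((len(ids), m), MISSING_CODE, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        called = ~np.any(col == "0", axis=1)
        symbols = sorted(np.unique(col[called]).tolist())
        if len(symbols) > 2:
            raise ValueError(f"SNP {snp_ids[j]} has >2 alleles: {symbols}")
        if not symbols:
            continue
        counted = symbols[-1]  # lexicographically larger allele == "B"
        if len(symbols) == 1 and symbols[0] == "A":
            counted = "B"  # monomorphic reference SNP: count the absent allele

        codes[called, j] = (col[called] == counted).sum(axis=1)

    try:
        chrom_arr = np.array([int(c) for c in chroms], dtype=np.int64)
    except ValueError:
        chrom_arr = np.array(chroms)
    return GenotypeMatrix(
        ids=np.array(ids),
        snp_ids=np.array(snp_ids),
        codes=codes,
        chrom=chrom_arr,
        pos=np.array(poss, dtype=np.int64),
    )
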