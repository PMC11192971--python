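"""Shared data containers and errors.

Coordinate conventions
----------------------
Point positions are 1-based base pairs.  Intervals are half-open
``[start, end)`` with a 1-based start, so ``end - start`` equals the
interval length in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype / haplotype missing code


class SweepscanError(Exception):
    """Base class for package errors."""


class ConfigError(SweepscanError):
    """Invalid configuration or parameter values."""


class FormatError(SweepscanError):
    """Malformed input file."""


class ContractError(SweepscanError):
    """An operation was called with inputs violating its contract."""


class EstablishmentError(SweepscanError):
    """A conditioned sweep failed to reach its target frequency."""


class InsufficientFoundersError(SweepscanError):
    """Not enough founder haplotypes for pedigree simulation."""


@dataclass
class HaplotypeMatrix:
    """Phased alleles, sites x haplotypes, 0 = ref/ancestral, 1 = alt/derived.

    Haplotype columns come in sample order, two columns per sample
    (slots as written in the source VCF).  ``MISSING`` marks unknown
    alleles.
    """

    chrom: str
    positions: np.ndarray  # (n_sites,) int64, strictly increasing
    alleles: np.ndarray    # (n_sites, 2 * n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ContractError("alleles must be 2-D (sites x haplotypes)")
        if self.alleles.shape[0] != self.positions.shape[0]:
            raise ContractError("positions/alleles row mismatch")
        if self.alleles.shape[1] != 2 * len(self.samples):
            raise ContractError("haplotype count must be 2 x sample count")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ContractError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_haplotypes(self) -> int:
        return int(self.alleles.shape[1])

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse haplotype pairs into 0/1/2 dosages (MISSING if any allele is)."""
        a = self.alleles
        left, right = a[:, 0::2], a[:, 1::2]
        codes = (left + right).astype(np.int8)
        codes[(left == MISSING) | (right == MISSING)] = MISSING
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            codes=codes,
            samples=list(self.samples),
        )


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosages, sites x samples, codes 0/1/2 or MISSING."""

    chrom: str
    positions: np.ndarray  # (n_sites,) int64
    codes: np.ndarray      # (n_sites, n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != self.positions.shape[0]:
            raise ContractError("positions/codes shape mismatch")
        if self.codes.shape[1] != len(self.samples):
            raise ContractError("codes column count must equal sample count")

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.codes.shape[1])


VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ancestral", "n_called", "alt_count",
    "maf", "missing_rate", "hwe_p", "mean_depth", "pass_qc",
]


def empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        VARIANT_COLUMNS,
        ["object", "int64", "object", "object", "object", "int64", "int64",
         "float64", "float64", "float64", "float64", "bool"],
    )})


@dataclass
class ROHSegment:
    """One homozygous run in one individual.

    ``start``/``end`` are the first and last SNP positions of the run,
    so ``length == end - start``.
    """

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateRegion:
    """A merged interval supported by >= 1 scan method, with annotated genes."""

    chrom: str
    start: int
    end: int
    methods: frozenset[str]
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start
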