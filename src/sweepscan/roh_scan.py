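"""Runs-of-homozygosity detection (consecutive-runs style), per-SNP ROH
incidence, ROH islands and the F_ROH genomic inbreeding coefficient.

A run is a maximal stretch of consecutive SNPs in one individual with at
most ``max_het`` heterozygous and ``max_missing`` missing calls, no
inter-SNP gap above ``max_gap``, spanning at least ``min_length`` bp and
``min_snps`` SNPs.  ``max_gap`` is read as the largest allowed distance
between consecutive SNPs *within* a run (the consecutive-runs
convention).  Overlapping maximal candidates are resolved greedily left
to right, so emitted segments never overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, ContractError, GenotypeMatrix, ROHSegment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    min_length: int = 300_000
    max_gap: int = 500_000
    max_het: int = 1
    max_missing: int = 2
    min_snps: int = 88
    alpha_fp: float = 0.05

    def validate(self) -> None:
        if self.min_length <= 0:
            raise ContractError("min_length must be positive")
        if min(self.max_gap, self.max_het, self.max_missing,
               self.min_snps) < 0:
            raise ContractError("ROH parameters must be non-negative")


def lencz_min_snps(alpha_fp: float, ns: int, ni: int, het: float) -> int:
    """Minimum SNPs per run bounding the false-positive rate:
    ceil( ln(alpha / (ns * ni)) / ln(1 - het) )."""
    if not (0 < alpha_fp < 1):
        raise ContractError("alpha_fp must be in (0, 1)")
    if ns < 1 or ni < 1:
        raise ContractError("ns and ni must be >= 1")
    if not (0 < het < 1):
        raise ContractError("het must be in (0, 1)")
    val = math.log(alpha_fp / (ns * ni)) / math.log(1.0 - het)
    return max(0, math.ceil(val))


def _max_extents(codes: np.ndarray, pos: np.ndarray, params: ROHParams
                 ) -> np.ndarray:
    """For each start index a, the largest b such that [a, b] satisfies the
    het / missing budgets and the gap rule (two-pointer; b is
    nondecreasing in a)."""
    n = codes.size
    is_het = codes == 1
    is_mis = codes == MISSING
    gap_break = np.zeros(n, dtype=bool)
    gap_break[1:] = np.diff(pos) > params.max_gap
    bmax = np.empty(n, dtype=np.int64)
    b = -1
    het_c = 0
    mis_c = 0
    for a in range(n):
        if b < a - 1:
            b = a - 1
            het_c = 0
            mis_c = 0
        while b + 1 < n:
            nxt = b + 1
            if nxt > a and gap_break[nxt]:
                break
            h = het_c + int(is_het[nxt])
            m = mis_c + int(is_mis[nxt])
            if h > params.max_het or m > params.max_missing:
                break
            b = nxt
            het_c = h
            mis_c = m
        bmax[a] = b
        het_c -= int(is_het[a])
        mis_c -= int(is_mis[a])
    return bmax


def detect_runs(codes: np.ndarray, pos: np.ndarray, params: ROHParams,
                sample: str = "NA", chrom: str = "NA") -> list[ROHSegment]:
    """Detect ROH in one sample / chromosome genotype vector.

    Runs are emitted greedily left to right.  Each emitted run is
    budget-maximal within the not-yet-consumed suffix: it cannot be
    extended right, nor left past its start (up to the end of the
    previous emission) without breaking the het / missing / gap
    constraints; it must additionally pass ``min_length`` and
    ``min_snps``.
    """
    params.validate()
    codes = np.asarray(codes)
    pos = np.asarray(pos, dtype=np.int64)
    if codes.shape != pos.shape:
        raise ContractError("codes/positions length mismatch")
    if pos.size > 1 and not np.all(np.diff(pos) > 0):
        raise ContractError("positions must be strictly increasing")
    n = codes.size
    if n == 0:
        return []
    bmax = _max_extents(codes, pos, params)
    segs: list[ROHSegment] = []
    cursor = 0
    for a in range(n):
        if a < cursor:
            continue
        b = int(bmax[a])
        if b < a:
            continue
        # maximality within the unconsumed suffix: the run must not be
        # extendable leftward past a without breaking a budget (runs at or
        # before the cursor are anchored there by the previous emission)
        if a > cursor and int(bmax[a - 1]) >= b:
            continue
        n_snps = b - a + 1
        # run length = last SNP position - first SNP position
        length = int(pos[b]) - int(pos[a])
        if n_snps < params.min_snps or length < params.min_length:
            continue
        window = codes[a:b + 1]
        segs.append(ROHSegment(
            sample=sample, chrom=chrom,
            start=int(pos[a]), end=int(pos[b]),
            n_snps=n_snps,
            n_het=int((window == 1).sum()),
            n_missing=int((window == MISSING).sum()),
        ))
        cursor = b + 1
    return segs


def detect_runs_all(gm: GenotypeMatrix, params: ROHParams
                    ) -> list[ROHSegment]:
    """Run ROH detection for every sample of a genotype matrix."""
    out: list[ROHSegment] = []
    for s, name in enumerate(gm.samples):
        out.extend(detect_runs(gm.codes[:, s], gm.positions, params,
                               sample=name, chrom=gm.chrom))
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.length, s.n_snps, s.n_het,
          s.n_missing) for s in segments],
        columns=["sample", "chrom", "start", "end", "length", "n_snps",
                 "n_het", "n_missing"],
    )


def froh(segments: list[ROHSegment], autosome_total: int,
         samples: list[str]) -> pd.Series:
    """Per-sample fraction of the autosomes covered by ROH."""
    if autosome_total <= 0:
        raise ContractError("autosome_total must be positive")
    tot = {s: 0 for s in samples}
    for seg in segments:
        if seg.sample in tot:
            tot[seg.sample] += seg.length
    return pd.Series({s: tot[s] / autosome_total for s in samples},
                     name="froh")


def snp_incidence(segments: list[ROHSegment], positions: np.ndarray,
                  n_samples: int, chrom: str | None = None) -> np.ndarray:
    """Percentage of individuals with >= 1 ROH covering each SNP."""
    positions = np.asarray(positions, dtype=np.int64)
    covered: dict[str, np.ndarray] = {}
    for seg in segments:
        if chrom is not None and seg.chrom != chrom:
            continue
        mask = covered.setdefault(seg.sample,
                                  np.zeros(positions.size, dtype=bool))
        # seg.end is the last SNP position of the run; include it
        lo = np.searchsorted(positions, seg.start, side="left")
        hi = np.searchsorted(positions, seg.end, side="right")
        mask[lo:hi] = True
    counts = np.zeros(positions.size, dtype=np.int64)
    for mask in covered.values():
        counts += mask
    return 100.0 * counts / n_samples


def roh_islands(incidence: np.ndarray, positions: np.ndarray,
                top_fraction: float = 0.001, max_gap: int = 500_000
                ) -> list[tuple[int, int]]:
    """Intervals of top-incidence SNPs.

    Flags SNPs with incidence >= the k-th largest value
    (k = max(1, floor(top_fraction * n_snps)); ties included) and merges
    consecutive flagged SNPs separated by <= ``max_gap`` into half-open
    [first_pos, last_pos + 1) islands.  All-zero incidence yields no
    islands.
    """
    incidence = np.asarray(incidence, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if incidence.size == 0 or not (incidence > 0).any():
        log.warning("no SNP occurs in any ROH; no islands")
        return []
    k = max(1, int(math.floor(top_fraction * incidence.size)))
    threshold = np.sort(incidence)[::-1][k - 1]
    flagged = np.nonzero((incidence >= threshold) & (incidence > 0))[0]
    islands: list[tuple[int, int]] = []
    start = prev = flagged[0]
    for i in flagged[1:]:
        if positions[i] - positions[prev] > max_gap:
            islands.append((int(positions[start]), int(positions[prev]) + 1))
            start = i
        prev = i
    islands.append((int(positions[start]), int(positions[prev]) + 1))
    return islands
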