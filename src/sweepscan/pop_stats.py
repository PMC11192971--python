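"""Cohort descriptive statistics: heterozygosity, LD decay, GRM, PCA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, ContractError, GenotypeMatrix, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class HetSummary:
    he: np.ndarray          # per-site expected heterozygosity 2p(1-p)
    ho: np.ndarray          # per-site observed heterozygote fraction
    mean_he: float
    sd_he: float
    mean_ho: float
    sd_ho: float


def heterozygosity(gm: GenotypeMatrix) -> HetSummary:
    """Per-site He = 2p(1-p) and Ho = het fraction among called genotypes.

    Sites with zero called genotypes are excluded with a warning.
    """
    called = gm.codes != MISSING
    n_called = called.sum(axis=1)
    ok = n_called > 0
    if not ok.all():
        log.warning("excluding %d sites with no called genotypes",
                    int((~ok).sum()))
    codes = gm.codes[ok]
    n_called = n_called[ok]
    alt = np.where(called[ok], codes, 0).sum(axis=1)
    p = alt / (2.0 * n_called)
    he = 2 * p * (1 - p)
    ho = (codes == 1).sum(axis=1) / n_called
    return HetSummary(
        he=he, ho=ho,
        mean_he=float(he.mean()) if he.size else float("nan"),
        sd_he=float(he.std()) if he.size else float("nan"),
        mean_ho=float(ho.mean()) if ho.size else float("nan"),
        sd_ho=float(ho.std()) if ho.size else float("nan"),
    )


def ld_r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 between two phased 0/1 haplotype columns, from haplotype freqs."""
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (x * y).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_r2_decay(haps: HaplotypeMatrix, max_dist: int = 5_000_000,
                bin_width: int = 50_000) -> pd.DataFrame:
    """Mean r^2 of all intra-chromosome site pairs, binned by distance.

    Bins are half-open (lo, hi] covering (0, max_dist].  Pairs involving a
    monomorphic site are skipped.
    """
    pos = haps.positions
    X = haps.alleles.astype(np.float64)
    p = X.mean(axis=1)
    poly = (p > 0) & (p < 1)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n = pos.size
    for i in range(n - 1):
        if not poly[i]:
            continue
        hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        js = np.arange(i + 1, hi)
        js = js[poly[js]]
        if js.size == 0:
            continue
        pa, pb = p[i], p[js]
        pab = (X[i] * X[js]).mean(axis=1)
        d = pab - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        dist = pos[js] - pos[i]
        b = np.minimum((dist - 1) // bin_width, n_bins - 1)
        np.add.at(sums, b, r2)
        np.add.at(counts, b, 1)
    edges_lo = np.arange(n_bins, dtype=np.int64) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_start": edges_lo,
        "bin_end": edges_lo + bin_width,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def grm_yang(gm: GenotypeMatrix) -> np.ndarray:
    """Yang et al. SNP-based genomic relationship matrix.

    Off-diagonal jk: mean over sites of (x_j - 2p)(x_k - 2p) / (2p(1-p)).
    Diagonal jj: 1 + mean over sites of (x^2 - (1+2p)x + 2p^2) / (2p(1-p)).
    Sites with p in {0, 1} are excluded; missing genotypes are excluded
    pairwise.
    """
    if gm.n_samples < 2:
        raise ContractError("GRM needs >= 2 samples")
    called = gm.codes != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, gm.codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
    ok = (n_called > 0) & (p > 0) & (p < 1)
    X = gm.codes[ok].astype(np.float64)
    M = called[ok].astype(np.float64)
    p = p[ok]
    denom = 2 * p * (1 - p)

    Z = (X - 2 * p[:, None]) / np.sqrt(denom)[:, None]
    Z = np.where(M > 0, Z, 0.0)
    num = Z.T @ Z
    cnt = M.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        G = num / cnt
    # replace the diagonal with the inbreeding-corrected estimator
    diag_terms = (X * X - (1 + 2 * p[:, None]) * X + 2 * (p * p)[:, None]) \
        / denom[:, None]
    diag_terms = np.where(M > 0, diag_terms, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = 1.0 + diag_terms.sum(axis=0) / M.sum(axis=0)
    np.fill_diagonal(G, diag)
    return G


def pca(grm: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a GRM; returns (coordinates, variance fractions).

    Coordinates are eigenvectors scaled by sqrt(max(eigenvalue, 0));
    variance fractions are eigenvalue / trace, reported in descending
    eigenvalue order over all components (the first k coordinates are
    returned).
    """
    grm = np.asarray(grm, dtype=float)
    if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
        raise ContractError("GRM must be square")
    if not np.allclose(grm, grm.T, atol=1e-10):
        raise ContractError("GRM must be symmetric")
    if k > grm.shape[0]:
        raise ContractError("k exceeds sample count")
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    fractions = vals / np.trace(grm)
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    return coords, fractions
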