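"""Composite likelihood ratio scan for hard selective sweeps.

The sweep model follows the star-like hitchhiking approximation: at
distance ``d`` from the tested position each of the ``n`` sampled
lineages escapes the sweep independently with probability
``p_e = 1 - exp(-alpha * d)``; all non-escaping lineages coalesce into a
single swept ancestor.  The escapees plus that ancestor draw their
derived-allele count from the genome-wide background spectrum
hypergeometrically down-projected to their number, and the ancestor's
state is copied onto every non-escaping lineage.  Distances are physical
bp; a constant recombination rate is folded into ``alpha``.

The composite likelihood of the data near a tested position is the
product over sites of the site probability conditioned on polymorphism,
maximised over a log-spaced ``alpha`` grid that includes ``inf`` (the
neutral-equivalent limit, making CLR >= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .core import ContractError

log = logging.getLogger(__name__)


@dataclass
class BackgroundSFS:
    """Genome-wide frequency spectrum over derived counts 1..n-1."""

    n: int                 # sampled chromosome count
    probs: np.ndarray      # length n+1; probs[0] == probs[n] == 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n + 1,):
            raise ContractError("probs must have length n+1")
        if self.probs[0] != 0 or self.probs[self.n] != 0:
            raise ContractError("fixed classes must carry zero mass")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ContractError("probs must sum to 1")


def hypergeom_projection(j: int, n: int, m: int) -> np.ndarray:
    """Probabilities of drawing 0..m derived alleles in a subsample of m
    chromosomes from n carrying j derived copies (without replacement)."""
    if not (0 <= j <= n and 0 < m <= n):
        raise ContractError("need 0 <= j <= n and 0 < m <= n")
    return hypergeom.pmf(np.arange(m + 1), n, j, m)


def project_background(bg: BackgroundSFS, m: int) -> BackgroundSFS:
    """Down-project a background SFS to m chromosomes, re-conditioning on
    polymorphism in the subsample (fixed classes dropped, renormalized)."""
    if m > bg.n:
        raise ContractError("cannot project background upward")
    if m == bg.n:
        return bg
    out = np.zeros(m + 1)
    for j in range(1, bg.n):
        if bg.probs[j] > 0:
            out += bg.probs[j] * hypergeom_projection(j, bg.n, m)
    out[0] = 0.0
    out[m] = 0.0
    s = out.sum()
    if s <= 0:
        raise ContractError("projected spectrum has no polymorphic mass")
    return BackgroundSFS(m, out / s)


def background_sfs(derived: np.ndarray, n_chrom: np.ndarray,
                   known: np.ndarray | None = None) -> BackgroundSFS:
    """Estimate the background SFS from per-site derived counts.

    Sites with missing genotypes are down-projected to the largest common
    chromosome count by hypergeometric projection; mass landing in the
    fixed classes is dropped and the spectrum renormalized.  ``known``
    masks sites with a resolved ancestral state.
    """
    derived = np.asarray(derived, dtype=np.int64)
    n_chrom = np.asarray(n_chrom, dtype=np.int64)
    if known is None:
        known = np.ones(derived.shape, dtype=bool)
    use = known & (n_chrom > 0) & (derived > 0) & (derived < n_chrom)
    if not use.any():
        raise ContractError("no polymorphic sites with known ancestral state")
    derived = derived[use]
    n_chrom = n_chrom[use]
    n_common = int(n_chrom.min())
    counts = np.zeros(n_common + 1)
    full = n_chrom == n_common
    np.add.at(counts, derived[full], 1.0)
    for j, n_i in zip(derived[~full], n_chrom[~full]):
        counts += hypergeom_projection(int(j), int(n_i), n_common)
    counts[0] = 0.0
    counts[n_common] = 0.0
    total = counts.sum()
    if total <= 0:
        raise ContractError("no polymorphic mass after projection")
    return BackgroundSFS(n_common, counts / total)


def default_alpha_grid(size: int = 20, d_ref: int = 500_000,
                       pe_min: float = 1e-3, pe_max: float = 0.999
                       ) -> np.ndarray:
    """Log-spaced sweep intensities spanning p_e(d_ref) in [pe_min, pe_max],
    with inf appended as the neutral-equivalent limit."""
    a_min = -np.log1p(-pe_min) / d_ref
    a_max = -np.log1p(-pe_max) / d_ref
    return np.append(np.geomspace(a_min, a_max, size), np.inf)


class CLRModel:
    """Precomputed sweep-model machinery for a fixed background SFS."""

    def __init__(self, bg: BackgroundSFS):
        self.bg = bg
        self.n = bg.n
        n = bg.n
        q = bg.probs
        # M[k, j]: P(derived count j | k escapees), independent of d, alpha
        M = np.zeros((n + 1, n + 1))
        M[n] = q
        for k in range(n):
            ms = k + 1
            # distribution of derived count among the ms effective lineages
            Q = np.zeros(ms + 1)
            for j in np.nonzero(q)[0]:
                Q += q[j] * hypergeom_projection(int(j), n, ms)
            m_arr = np.arange(ms + 1)
            p_anc = m_arr / ms
            # ancestor derived -> its state copied to n-k swept lineages
            for m in m_arr:
                if Q[m] == 0:
                    continue
                M[k, m - 1 + (n - k)] += Q[m] * p_anc[m]
                M[k, m] += Q[m] * (1 - p_anc[m])
        self._M = M
        self._k = np.arange(n + 1)
        with np.errstate(divide="ignore"):
            self._log_q = np.log(q)

    def escape_prob(self, d, alpha):
        d = np.asarray(d, dtype=float)
        if np.isinf(alpha):
            return np.where(d > 0, 1.0, 0.0)
        return -np.expm1(-alpha * d)

    def site_probs(self, d: np.ndarray, alpha: float, j: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized P(j_i | d_i, alpha) and the polymorphism mass
        1 - P(0) - P(n) per site."""
        pe = self.escape_prob(d, alpha)
        B = binom.pmf(self._k[None, :], self.n, pe[:, None])  # (S, n+1)
        pj = np.einsum("sk,sk->s", B, self._M[:, j].T)
        p0 = B @ self._M[:, 0]
        pn = B @ self._M[:, self.n]
        return pj, 1.0 - p0 - pn

    def site_prob_full(self, d: float, alpha: float) -> np.ndarray:
        """P(j | d, alpha) for all j = 0..n (unconditioned; sums to 1)."""
        pe = float(self.escape_prob(np.array(d, dtype=float), alpha))
        B = binom.pmf(self._k, self.n, pe)
        return B @ self._M


def sweep_site_prob(j: int, n: int, d: float, alpha: float,
                    bg: BackgroundSFS) -> float:
    """Unconditioned sweep-model probability of derived count j at
    distance d from the swept site, for sweep intensity alpha."""
    if not 0 <= j <= n:
        raise ContractError("j outside 0..n")
    if d < 0 or alpha <= 0:
        raise ContractError("need d >= 0 and alpha > 0")
    if bg.n < n:
        raise ContractError("background n smaller than requested n")
    model = CLRModel(project_background(bg, n))
    return float(model.site_prob_full(d, alpha)[j])


@dataclass
class CLRResult:
    pos: int
    clr: float
    alpha_hat: float
    loglik_sweep: float
    loglik_neutral: float
    n_sites: int


class CLRScanner:
    """CLR evaluation against one background SFS.

    Sites with missing genotypes carry their own called chromosome count
    ``n_i``; the background is hypergeometrically projected to each
    distinct ``n_i`` (models cached), the SweepFinder convention.
    """

    def __init__(self, bg: BackgroundSFS,
                 alpha_grid: np.ndarray | None = None,
                 max_dist: int = 500_000):
        self.bg = bg
        self.alpha_grid = (default_alpha_grid() if alpha_grid is None
                           else np.asarray(alpha_grid, dtype=float))
        if self.alpha_grid.size == 0:
            raise ContractError("alpha grid must be non-empty")
        self.max_dist = max_dist
        self._models: dict[int, CLRModel] = {}

    def model_for(self, n: int) -> CLRModel:
        if n not in self._models:
            self._models[n] = CLRModel(project_background(self.bg, n))
        return self._models[n]

    def clr_at(self, pos: int, site_pos: np.ndarray, derived: np.ndarray,
               n_chrom: np.ndarray | None = None) -> CLRResult:
        """CLR = 2 * (max over alpha of sweep logCL - neutral logCL) at one
        tested position, over polymorphic sites within ``max_dist``.

        Sites beyond ``max_dist`` would contribute (nearly) identical
        terms to both models and are skipped.  Site probabilities are
        conditioned on polymorphism under both models.
        """
        site_pos = np.asarray(site_pos, dtype=np.int64)
        derived = np.asarray(derived, dtype=np.int64)
        if n_chrom is None:
            n_chrom = np.full(site_pos.shape, self.bg.n, dtype=np.int64)
        else:
            n_chrom = np.asarray(n_chrom, dtype=np.int64)
        poly = (derived > 0) & (derived < n_chrom) & (n_chrom >= 2)
        near = poly & (np.abs(site_pos - pos) <= self.max_dist)
        if not near.any():
            log.warning("no sites within %d bp of position %d",
                        self.max_dist, pos)
            return CLRResult(pos, 0.0, float("nan"), 0.0, 0.0, 0)
        # clamp d to >= 1 bp: a site exactly at the tested position would get
        # escape probability 0, forcing monomorphism and a degenerate 0/0
        # conditional likelihood
        d = np.maximum(np.abs(site_pos[near] - pos).astype(float), 1.0)
        j = derived[near].copy()
        nn = n_chrom[near].copy()
        # sites called on more chromosomes than the background supports are
        # rescaled onto the background sample size (frequency-preserving)
        over = nn > self.bg.n
        if over.any():
            j[over] = np.clip(
                np.rint(j[over] * self.bg.n / nn[over]).astype(np.int64),
                1, self.bg.n - 1)
            nn[over] = self.bg.n
        groups = [(int(v), np.nonzero(nn == v)[0]) for v in np.unique(nn)]
        ll_neutral = 0.0
        for v, idx in groups:
            ll_neutral += float(self.model_for(v)._log_q[j[idx]].sum())
        best = -np.inf
        best_alpha = float("nan")
        for alpha in self.alpha_grid:
            ll = 0.0
            for v, idx in groups:
                pj, pmass = self.model_for(v).site_probs(
                    d[idx], float(alpha), j[idx])
                with np.errstate(divide="ignore", invalid="ignore"):
                    ll += float(np.sum(np.log(pj) - np.log(pmass)))
            if not np.isfinite(ll):
                ll = -np.inf
            if ll > best:
                best = ll
                best_alpha = float(alpha)
        clr = 2.0 * (best - ll_neutral)
        return CLRResult(pos, clr, best_alpha, best, ll_neutral,
                         int(near.sum()))

    def scan(self, site_pos: np.ndarray, derived: np.ndarray,
             chrom_length: int, grid_spacing: int = 10_000,
             n_chrom: np.ndarray | None = None) -> pd.DataFrame:
        """Evaluate the CLR at evenly spaced test positions (interval
        midpoints: spacing/2, 3*spacing/2, ...).  A chromosome shorter
        than the spacing gets a single midpoint test position."""
        if grid_spacing <= 0:
            raise ContractError("grid_spacing must be positive")
        if chrom_length < grid_spacing:
            test_pos = np.array([max(1, chrom_length // 2)], dtype=np.int64)
        else:
            n_pos = chrom_length // grid_spacing
            test_pos = (np.arange(n_pos) * grid_spacing
                        + max(1, grid_spacing // 2)).astype(np.int64)
        rows = []
        for tp in test_pos:
            r = self.clr_at(int(tp), site_pos, derived, n_chrom)
            rows.append((int(tp), r.clr, r.alpha_hat, r.n_sites))
        return pd.DataFrame(rows, columns=["pos", "clr", "alpha_hat",
                                           "n_sites"])


def clr_at_position(pos: int, site_pos: np.ndarray, derived: np.ndarray,
                    bg: BackgroundSFS, alpha_grid: np.ndarray | None = None,
                    max_dist: int = 500_000,
                    n_chrom: np.ndarray | None = None) -> CLRResult:
    """Convenience wrapper around :meth:`CLRScanner.clr_at`."""
    return CLRScanner(bg, alpha_grid, max_dist).clr_at(
        pos, site_pos, derived, n_chrom)


def clr_grid_scan(site_pos: np.ndarray, derived: np.ndarray,
                  bg: BackgroundSFS, chrom_length: int,
                  grid_spacing: int = 10_000,
                  alpha_grid: np.ndarray | None = None,
                  max_dist: int = 500_000,
                  n_chrom: np.ndarray | None = None) -> pd.DataFrame:
    """Convenience wrapper around :meth:`CLRScanner.scan`."""
    return CLRScanner(bg, alpha_grid, max_dist).scan(
        site_pos, derived, chrom_length, grid_spacing, n_chrom)
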