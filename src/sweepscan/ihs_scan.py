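"""Extended haplotype homozygosity, iHH integration, iHS and its
two-sided Gaussian tail transform.

EHH at a flanking site is the probability that two random carriers of
the focal core allele are identical over every site between the core and
that flank: sum over extended-haplotype classes of C(n_h, 2) / C(n_c, 2).
iHH is the trapezoidal integral of the EHH curve against physical
position, both directions summed, truncated where EHH drops below a
cutoff (integrating down to the interpolated crossing).  Curves that hit
the chromosome end, or an inter-SNP gap larger than ``max_gap``, before
reaching the cutoff are flagged edge-censored and excluded from
standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import MISSING, ContractError, HaplotypeMatrix

log = logging.getLogger(__name__)

ANCESTRAL, DERIVED = 0, 1


@dataclass
class EHHCurve:
    core_index: int
    allele: int
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ehh: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_censored: bool = False


def _pair_homozygosity(class_sizes: np.ndarray, n_carriers: int) -> float:
    if n_carriers < 2:
        return 0.0
    num = (class_sizes * (class_sizes - 1) // 2).sum()
    den = n_carriers * (n_carriers - 1) // 2
    return float(num / den)


def ehh(haps: HaplotypeMatrix, core: int, allele: int, direction: int,
        cutoff: float = 0.05, max_gap: int = 200_000) -> EHHCurve:
    """EHH curve from the core site outward in one direction (+1 / -1).

    The curve starts at the core (EHH = 1) and is truncated at the first
    flanking site where EHH < cutoff; running off the chromosome end or
    across a gap > ``max_gap`` with EHH still >= cutoff marks the curve
    edge-censored.  Haplotypes with a missing allele drop out of the
    carrier set from that site onward.
    """
    if direction not in (+1, -1):
        raise ContractError("direction must be +1 or -1")
    carriers = np.nonzero(haps.alleles[core] == allele)[0]
    if carriers.size < 2:
        raise ContractError("need >= 2 carriers of the focal allele")
    n_sites = haps.n_sites
    pos = haps.positions
    ps = [pos[core]]
    es = [1.0]
    ids = np.zeros(carriers.size, dtype=np.int64)
    active = np.ones(carriers.size, dtype=bool)
    censored = False
    i = core
    while True:
        nxt = i + direction
        if nxt < 0 or nxt >= n_sites:
            censored = es[-1] >= cutoff
            break
        if abs(int(pos[nxt]) - int(pos[i])) > max_gap:
            censored = es[-1] >= cutoff
            break
        a = haps.alleles[nxt, carriers]
        newly_missing = active & (a == MISSING)
        if newly_missing.any():
            active &= ~newly_missing
        if active.sum() < 2:
            censored = es[-1] >= cutoff
            break
        ids = ids * 2 + np.where(a == MISSING, 0, a)
        _, ids = np.unique(ids, return_inverse=True)  # keep ids small
        _, sizes = np.unique(ids[active], return_counts=True)
        e = _pair_homozygosity(sizes, int(active.sum()))
        ps.append(int(pos[nxt]))
        es.append(e)
        i = nxt
        if e < cutoff:
            break
    return EHHCurve(core, allele, np.array(ps, dtype=np.int64),
                    np.array(es), edge_censored=censored)


def ihh_one_side(curve: EHHCurve, cutoff: float = 0.05) -> float:
    """Trapezoidal area of one EHH curve against |position - core|.

    Integration stops at the first point with EHH < cutoff, including
    the segment down to the linearly interpolated cutoff crossing.
    """
    x = np.abs(curve.positions.astype(float) - float(curve.positions[0]))
    y = curve.ehh
    if x.size < 2:
        return 0.0
    area = 0.0
    for k in range(1, x.size):
        if y[k] < cutoff:
            # integrate to the interpolated crossing y == cutoff
            if y[k - 1] <= cutoff:
                break
            frac = (y[k - 1] - cutoff) / (y[k - 1] - y[k])
            dx = (x[k] - x[k - 1]) * frac
            area += 0.5 * (y[k - 1] + cutoff) * dx
            break
        area += 0.5 * (y[k - 1] + y[k]) * (x[k] - x[k - 1])
    return float(area)


def ihh(haps: HaplotypeMatrix, core: int, allele: int,
        cutoff: float = 0.05, max_gap: int = 200_000
        ) -> tuple[float, bool]:
    """Two-sided integrated EHH for one core allele; returns
    (area, edge_censored)."""
    left = ehh(haps, core, allele, -1, cutoff=cutoff, max_gap=max_gap)
    right = ehh(haps, core, allele, +1, cutoff=cutoff, max_gap=max_gap)
    area = ihh_one_side(left, cutoff) + ihh_one_side(right, cutoff)
    return area, left.edge_censored or right.edge_censored


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """ln(iHH_ancestral / iHH_derived); undefined for zero areas."""
    if ihh_a <= 0 or ihh_d <= 0:
        raise ContractError("iHH areas must be positive")
    return float(np.log(ihh_a / ihh_d))


def pihs(ihs: float | np.ndarray) -> float | np.ndarray:
    """Two-sided Gaussian tail transform: -log10(1 - 2|Phi(iHS) - 0.5|)."""
    z = np.abs(np.asarray(ihs, dtype=float))
    # 1 - 2|Phi(z) - 0.5| = 2 * sf(z); use logsf for tail accuracy
    out = -(np.log10(2.0) + norm.logsf(z) / np.log(10.0))
    out = np.maximum(out, 0.0)
    if np.isscalar(ihs) or np.ndim(ihs) == 0:
        return float(out)
    return out


try:
    from numba import njit

    @njit(cache=True)
    def _ehh_area_fast(alleles, pos, core, allele_code, direction,
                       cutoff, max_gap):  # pragma: no cover - jitted
        n_sites, n_haps = alleles.shape
        active = np.zeros(n_haps, dtype=np.bool_)
        n_act = 0
        for h in range(n_haps):
            if alleles[core, h] == allele_code:
                active[h] = True
                n_act += 1
        if n_act < 2:
            return -1.0, False
        ids = np.zeros(n_haps, dtype=np.int64)
        area = 0.0
        prev_e = 1.0
        prev_pos = pos[core]
        i = core
        while True:
            nxt = i + direction
            if nxt < 0 or nxt >= n_sites:
                return area, prev_e >= cutoff
            gap = pos[nxt] - pos[i]
            if gap < 0:
                gap = -gap
            if gap > max_gap:
                return area, prev_e >= cutoff
            for h in range(n_haps):
                if active[h] and alleles[nxt, h] < 0:
                    active[h] = False
                    n_act -= 1
            if n_act < 2:
                return area, prev_e >= cutoff
            # refine partition: new class = (old class, allele at nxt)
            for h in range(n_haps):
                if active[h]:
                    ids[h] = ids[h] * 2 + alleles[nxt, h]
                else:
                    ids[h] = -1
            keys = np.empty(n_act, dtype=np.int64)
            kk = 0
            for h in range(n_haps):
                if active[h]:
                    keys[kk] = ids[h]
                    kk += 1
            keys.sort()
            pairs = 0
            run = 1
            uniq = np.empty(n_act, dtype=np.int64)
            uniq[0] = keys[0]
            nu = 1
            for t in range(1, n_act):
                if keys[t] == keys[t - 1]:
                    run += 1
                else:
                    pairs += run * (run - 1) // 2
                    run = 1
                    uniq[nu] = keys[t]
                    nu += 1
            pairs += run * (run - 1) // 2
            # compact ids (rank in sorted unique keys) to keep them small
            for h in range(n_haps):
                if active[h]:
                    v = ids[h]
                    lo = 0
                    hi = nu - 1
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if uniq[mid] < v:
                            lo = mid + 1
                        else:
                            hi = mid
                    ids[h] = lo
            e = pairs / (n_act * (n_act - 1) / 2.0)
            dx = pos[nxt] - prev_pos
            if dx < 0:
                dx = -dx
            if e < cutoff:
                if prev_e > cutoff:
                    frac = (prev_e - cutoff) / (prev_e - e)
                    area += 0.5 * (prev_e + cutoff) * dx * frac
                return area, False
            area += 0.5 * (prev_e + e) * dx
            prev_e = e
            prev_pos = pos[nxt]
            i = nxt

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _ihh_fast(haps: HaplotypeMatrix, core: int, allele: int,
              cutoff: float, max_gap: int) -> tuple[float, bool]:
    total = 0.0
    censored = False
    for direction in (-1, +1):
        a, c = _ehh_area_fast(haps.alleles, haps.positions, core, allele,
                              direction, cutoff, max_gap)
        if a < 0:
            raise ContractError("need >= 2 carriers of the focal allele")
        total += a
        censored = censored or c
    return total, censored


def ihs_scan(haps: HaplotypeMatrix, derived_is_alt: np.ndarray,
             anc_known: np.ndarray | None = None,
             cutoff: float = 0.05, max_gap: int = 200_000,
             min_maf: float = 0.05) -> pd.DataFrame:
    """Per-site uniHS over all usable core sites.

    ``derived_is_alt`` says, per site, whether the alternate allele is the
    derived one (ancestral == REF); at sites where it is false the allele
    coding is flipped for the EHH computation.  Sites without a resolved
    ancestral state, with < 2 carriers of either allele, or with minor
    derived-allele frequency below ``min_maf`` are skipped.
    """
    derived_is_alt = np.asarray(derived_is_alt, dtype=bool)
    if anc_known is None:
        anc_known = np.ones(haps.n_sites, dtype=bool)
    rows = []
    for i in range(haps.n_sites):
        if not anc_known[i]:
            continue
        col = haps.alleles[i]
        called = col != MISSING
        if not derived_is_alt[i]:
            col = np.where(called, 1 - col, MISSING).astype(np.int8)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        n_der = int((col == 1).sum())
        freq_d = n_der / n_called
        if min(freq_d, 1 - freq_d) < min_maf:
            continue
        if n_der < 2 or n_called - n_der < 2:
            continue
        # EHH depends only on haplotype identity, not flank polarity, so
        # flipped sites just swap which stored allele is "derived"
        dcode = DERIVED if derived_is_alt[i] else ANCESTRAL
        compute = _ihh_fast if _HAVE_NUMBA else ihh
        ihh_a, cens_a = compute(haps, i, 1 - dcode, cutoff, max_gap)
        ihh_d, cens_d = compute(haps, i, dcode, cutoff, max_gap)
        if ihh_a <= 0 or ihh_d <= 0:
            log.debug("site %d dropped: zero iHH area", i)
            continue
        rows.append((int(haps.positions[i]), freq_d, ihh_a, ihh_d,
                     float(np.log(ihh_a / ihh_d)), cens_a or cens_d))
    return pd.DataFrame(rows, columns=["pos", "derived_freq", "ihh_a",
                                       "ihh_d", "unihs", "edge_censored"])


def standardize_ihs(results: pd.DataFrame, freq_bin_width: float = 0.025,
                    min_bin_count: int = 10) -> pd.DataFrame:
    """Standardize uniHS within derived-allele-frequency bins.

    iHS = (uniHS - bin mean) / bin SD with the sample (n-1) SD.  Bins
    below ``min_bin_count`` are merged with their lower neighbour
    (cascading); edge-censored sites are excluded from bin statistics
    and left unscored.  Adds iHS and PiHS columns.
    """
    out = results.copy()
    out["ihs"] = np.nan
    out["pihs"] = np.nan
    usable = ~out["edge_censored"].to_numpy(dtype=bool)
    if usable.sum() == 0:
        return out
    freq = out["derived_freq"].to_numpy()
    n_bins = int(np.ceil(1.0 / freq_bin_width))
    raw_bin = np.minimum((freq / freq_bin_width).astype(int), n_bins - 1)
    # merge sparse bins downward so each effective bin has enough sites
    counts = np.bincount(raw_bin[usable], minlength=n_bins)
    mapping = np.arange(n_bins)
    acc = 0
    start = 0
    last_closed = -1
    for b in range(n_bins):
        mapping[b] = start
        acc += counts[b]
        if acc >= min_bin_count:
            last_closed = start
            start = b + 1
            acc = 0
    if acc > 0 and last_closed >= 0:
        # trailing underfull group joins the last closed effective bin
        mapping[mapping == start] = last_closed
    eff = mapping[raw_bin]
    for b in np.unique(eff):
        sel = (eff == b) & usable
        vals = out.loc[sel, "unihs"].to_numpy()
        if vals.size < 2:
            log.warning("frequency bin %d has < 2 usable sites; unscored", b)
            continue
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd < 1e-9:  # numerically constant bin
            log.warning("constant uniHS in bin %d; sites left unscored", b)
            continue
        out.loc[sel, "ihs"] = (vals - vals.mean()) / sd
    scored = out["ihs"].notna()
    out.loc[scored, "pihs"] = pihs(out.loc[scored, "ihs"].to_numpy())
    return out
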