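"""VCF input and post-calling SNP quality control.

Reads VCFv4.2 into the internal variant table / genotype / haplotype
matrices (via :mod:`cyvcf2`) and applies the cohort-level site filters:
mean depth, missing rate, minor allele frequency, Hardy-Weinberg exact
test and biallelic-only.  Threshold inequalities are strict in the
direction stated by ``QCThresholds``; values equal to a threshold fail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    HaplotypeMatrix,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Site filters; defaults follow the standard resequencing recipe:
    mean depth > 2, missing rate < 0.05, MAF > 0.05, HWE p > 1e-6,
    biallelic SNPs only."""

    min_mean_depth: float = 2.0
    max_missing: float = 0.05
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6
    biallelic_only: bool = True


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditional on allele counts.

    Sums the probabilities of all heterozygote configurations whose
    conditional probability does not exceed the observed one
    (Wigginton-style mid-free exact test).  Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("empty genotype counts")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0  # monomorphic
    # P(het = h | rare, n) over h with the parity of rare, 0 <= h <= rare
    # and (rare - h) / 2 + (2n - rare - h)/2 homs. Use log-gamma weights.
    hs = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_r = (rare - hs) // 2
    hom_c = n - hs - hom_r
    logw = (
        math.lgamma(n + 1)
        - np.array([math.lgamma(v + 1) for v in hs])
        - np.array([math.lgamma(v + 1) for v in hom_r])
        - np.array([math.lgamma(v + 1) for v in hom_c])
        + hs * math.log(2.0)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    obs = int(np.where(hs == n_het)[0][0])
    return float(min(1.0, w[w <= w[obs] * (1 + 1e-12)].sum()))


def _site_stats(codes: np.ndarray) -> tuple[np.ndarray, ...]:
    called = codes != MISSING
    n_called = called.sum(axis=1)
    alt_count = np.where(called, codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_count / (2.0 * n_called)
    maf = np.minimum(p, 1 - p)
    missing_rate = 1.0 - n_called / codes.shape[1]
    return n_called, alt_count, maf, missing_rate


def _hwe_column(codes: np.ndarray) -> np.ndarray:
    out = np.ones(codes.shape[0])
    for i in range(codes.shape[0]):
        row = codes[i]
        row = row[row != MISSING]
        if row.size == 0:
            continue
        out[i] = hwe_exact_p(
            int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
        )
    return out


def read_vcf(path, require_phased: bool = False
             ) -> tuple[pd.DataFrame, GenotypeMatrix, HaplotypeMatrix | None]:
    """Read a VCF into (VariantTable, GenotypeMatrix, HaplotypeMatrix | None).

    Multiallelic records are dropped.  A haplotype matrix is returned
    only if every retained genotype is phased (or missing); with
    ``require_phased`` set, sites carrying unphased calls are dropped
    instead of disabling phased output.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    genos = []
    haps = []
    phased_ok = True
    dropped_unphased = 0
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            continue
        if samples:
            g = rec.genotypes
            if g is None:
                raise FormatError("record without GT field")
            if len(g) != len(samples):
                raise FormatError("header/body sample count mismatch")
            codes = np.empty(len(samples), dtype=np.int8)
            hrow = np.empty(2 * len(samples), dtype=np.int8)
            site_phased = True
            for j, (a0, a1, *rest) in enumerate(g):
                ph = bool(rest[0]) if rest else False
                if a0 < 0 or a1 < 0:
                    codes[j] = MISSING
                    hrow[2 * j] = hrow[2 * j + 1] = MISSING
                else:
                    codes[j] = a0 + a1
                    hrow[2 * j] = a0
                    hrow[2 * j + 1] = a1
                    if not ph and a0 != a1:
                        site_phased = False
            if not site_phased:
                if require_phased:
                    dropped_unphased += 1
                    continue
                phased_ok = False
        else:
            codes = np.empty(0, dtype=np.int8)
            hrow = np.empty(0, dtype=np.int8)
        aa = rec.INFO.get("AA")
        try:
            dp = rec.format("DP") if samples else None
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp, dtype=float).ravel()
            dp = dp[dp >= 0]
            mean_depth = float(dp.mean()) if dp.size else np.nan
        else:
            mean_depth = np.nan
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                     aa if aa else None, mean_depth))
        genos.append(codes)
        haps.append(hrow)
    if dropped_unphased:
        log.warning("dropped %d unphased sites", dropped_unphased)

    chroms = sorted({r[0] for r in rows}) if rows else []
    if len(chroms) > 1:
        raise FormatError(
            "read_vcf handles one chromosome per call; split the VCF "
            f"(found {chroms})"
        )
    chrom = chroms[0] if chroms else "NA"
    positions = np.array([r[1] for r in rows], dtype=np.int64)
    codes = (np.vstack(genos) if rows else
             np.empty((0, len(samples)), dtype=np.int8))
    gm = GenotypeMatrix(chrom, positions, codes, samples)
    hm = None
    if phased_ok:
        hmat = (np.vstack(haps) if rows else
                np.empty((0, 2 * len(samples)), dtype=np.int8))
        hm = HaplotypeMatrix(chrom, positions.copy(), hmat, samples)

    n_called, alt_count, maf, missing_rate = _site_stats(codes)
    vt = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": [r[2] for r in rows],
        "alt": [r[3] for r in rows],
        "ancestral": [r[4] for r in rows],
        "n_called": n_called,
        "alt_count": alt_count,
        "maf": maf,
        "missing_rate": missing_rate,
        "hwe_p": _hwe_column(codes),
        "mean_depth": [r[5] for r in rows],
        "pass_qc": True,
    })
    return vt, gm, hm


def read_ancestral_table(path) -> pd.DataFrame:
    """3-column tab-separated (chrom, pos, ancestral_base)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "ancestral"],
                     dtype={"chrom": str, "pos": np.int64, "ancestral": str})
    return df


def resolve_ancestral(vt: pd.DataFrame, table: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """Fill missing ancestral alleles from an external table, if given.

    Sites whose ancestral base matches neither REF nor ALT are reset to
    unknown (they are unusable for allele polarization).
    """
    vt = vt.copy()
    if table is not None:
        key = table.set_index(["chrom", "pos"])["ancestral"]
        need = vt["ancestral"].isna()
        idx = pd.MultiIndex.from_frame(vt.loc[need, ["chrom", "pos"]])
        vt.loc[need, "ancestral"] = key.reindex(idx).to_numpy()
    bad = vt["ancestral"].notna() & ~(
        (vt["ancestral"] == vt["ref"]) | (vt["ancestral"] == vt["alt"])
    )
    if bad.any():
        log.warning("%d sites have ancestral allele matching neither REF nor "
                    "ALT; treated as unknown", int(bad.sum()))
        vt.loc[bad, "ancestral"] = None
    return vt


def apply_qc(vt: pd.DataFrame, gm: GenotypeMatrix,
             hm: HaplotypeMatrix | None = None,
             thresholds: QCThresholds | None = None,
             ) -> tuple[pd.DataFrame, GenotypeMatrix, HaplotypeMatrix | None,
                        pd.DataFrame]:
    """Apply conjunctive site filters; returns filtered data + a QC report.

    The depth filter is skipped (with a warning) when no site has depth
    information.  The report lists, per filter, the number of sites it
    would remove on its own.
    """
    th = thresholds or QCThresholds()
    n = len(vt)
    keep = np.ones(n, dtype=bool)
    report = []

    depth = vt["mean_depth"].to_numpy(dtype=float)
    if np.isnan(depth).all():
        log.warning("no depth information; depth filter skipped")
        report.append(("mean_depth", 0))
    else:
        f = ~(depth > th.min_mean_depth)
        keep &= ~f
        report.append(("mean_depth", int(f.sum())))

    f = ~(vt["missing_rate"].to_numpy() < th.max_missing)
    keep &= ~f
    report.append(("missing_rate", int(f.sum())))

    f = ~(vt["maf"].to_numpy() > th.min_maf)
    keep &= ~f
    report.append(("maf", int(f.sum())))

    f = ~(vt["hwe_p"].to_numpy() > th.min_hwe_p)
    keep &= ~f
    report.append(("hwe", int(f.sum())))

    # biallelic-only is enforced at read time (multiallelics dropped)
    report.append(("biallelic", 0))

    if not keep.any():
        log.warning("all %d sites removed by QC", n)
    vt_out = vt.loc[keep].reset_index(drop=True)
    vt_out["pass_qc"] = True
    gm_out = GenotypeMatrix(gm.chrom, gm.positions[keep], gm.codes[keep],
                            list(gm.samples))
    hm_out = None
    if hm is not None:
        hm_out = HaplotypeMatrix(hm.chrom, hm.positions[keep],
                                 hm.alleles[keep], list(hm.samples))
    rep = pd.DataFrame(report, columns=["filter", "n_removed"])
    return vt_out, gm_out, hm_out, rep


def derived_counts(vt: pd.DataFrame, gm: GenotypeMatrix
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived-allele count, called chromosome count, and a mask of
    sites with a resolved ancestral state.

    Derived = ALT where ancestral == REF, REF where ancestral == ALT.
    """
    known = vt["ancestral"].notna().to_numpy()
    anc_is_ref = (vt["ancestral"] == vt["ref"]).to_numpy()
    called = gm.codes != MISSING
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, gm.codes, 0).sum(axis=1)
    derived = np.where(anc_is_ref, alt, n_chrom - alt)
    return derived.astype(np.int64), n_chrom.astype(np.int64), known
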