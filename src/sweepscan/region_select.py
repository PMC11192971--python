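"""Window construction, empirical outlier thresholds, per-method region
merging, multi-method intersection and gene annotation.

Windows are half-open ``[start, end)`` with 1-based starts, 500 kb long
with a 250 kb step by default, so successive windows overlap by half and
``end - start`` is the window length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import gffutils
import numpy as np
import pandas as pd

from .core import CandidateRegion, ContractError

log = logging.getLogger(__name__)

WINDOW_SIZE = 500_000
WINDOW_STEP = 250_000


@dataclass
class GenomicWindow:
    chrom: str
    start: int  # 1-based, inclusive
    end: int    # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict[str, int], size: int = WINDOW_SIZE,
                 step: int = WINDOW_STEP) -> list[GenomicWindow]:
    """Tile each chromosome with overlapping windows.

    Starts run 1, 1+step, 1+2*step, ... while start <= chromosome
    length; the final window is clipped at the chromosome end.  A
    chromosome shorter than the step gets a single clipped window.
    """
    if not (size >= step > 0):
        raise ContractError("need size >= step > 0")
    out: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ContractError(f"non-positive length for {chrom}")
        start = 1
        while start <= length:
            out.append(GenomicWindow(chrom, start, min(start + size,
                                                       length + 1)))
            start += step
    return out


def aggregate(positions: np.ndarray, values: np.ndarray,
              windows: list[GenomicWindow], reducer: str,
              chrom: str | None = None, min_sites: int = 2) -> pd.DataFrame:
    """Window statistics: reducer ('max' | 'mean_abs') over values whose
    position falls in [start, end).  Windows with fewer than
    ``min_sites`` contributing values get a NaN statistic."""
    if reducer not in ("max", "mean_abs"):
        raise ContractError("reducer must be 'max' or 'mean_abs'")
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if positions.size > 1 and not np.all(np.diff(positions) >= 0):
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        values = values[order]
    ok = np.isfinite(values)
    positions = positions[ok]
    values = values[ok]
    rows = []
    for w in windows:
        if chrom is not None and w.chrom != chrom:
            continue
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="left")
        vals = values[lo:hi]
        if vals.size < min_sites:
            stat = float("nan")
        elif reducer == "max":
            stat = float(vals.max())
        else:
            stat = float(np.abs(vals).mean())
        rows.append((w.chrom, w.start, w.end, stat, int(vals.size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value",
                                       "n_sites"])


def empirical_outliers(stats: pd.DataFrame, top_fraction: float = 0.01
                       ) -> tuple[pd.DataFrame, float]:
    """Flag windows in the top ``top_fraction`` of the empirical statistic
    distribution (k = max(1, floor(fraction * N)); value ties at the
    threshold are all flagged)."""
    out = stats.copy()
    vals = out["value"].to_numpy(dtype=float)
    scored = np.isfinite(vals)
    n = int(scored.sum())
    out["outlier"] = False
    if n == 0:
        log.warning("no scored windows; nothing to flag")
        return out, float("nan")
    if n < 1.0 / top_fraction:
        log.warning("only %d scored windows for top fraction %g; k=1",
                    n, top_fraction)
    k = max(1, int(math.floor(top_fraction * n)))
    threshold = float(np.sort(vals[scored])[::-1][k - 1])
    out.loc[scored & (vals >= threshold), "outlier"] = True
    return out, threshold


def merge_intervals(intervals: list[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Merge overlapping or book-ended half-open intervals per chromosome."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def merge_flagged(flagged: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge outlier windows of one method into maximal intervals."""
    ivs = [(r.chrom, int(r.start), int(r.end))
           for r in flagged.itertuples(index=False)
           if getattr(r, "outlier", True)]
    if not ivs:
        return []
    return merge_intervals(ivs)


def intersect_methods(method_regions: dict[str, list[tuple[str, int, int]]],
                      min_methods: int = 2
                      ) -> tuple[list[CandidateRegion], pd.DataFrame]:
    """Maximal intervals covered by >= ``min_methods`` distinct methods.

    Each candidate is labelled with every method overlapping it.  Also
    returns the pairwise overlap totals (bp) between the per-method
    region sets.
    """
    methods = sorted(method_regions)
    merged = {m: merge_intervals(method_regions[m]) for m in methods}
    # pairwise overlap totals
    pair_rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            tot = 0
            for c1, s1, e1 in merged[m1]:
                for c2, s2, e2 in merged[m2]:
                    if c1 == c2:
                        tot += max(0, min(e1, e2) - max(s1, s2))
            pair_rows.append((m1, m2, tot))
    pairs = pd.DataFrame(pair_rows, columns=["method_a", "method_b",
                                             "overlap_bp"])

    # sweep line per chromosome over method coverage counts
    chroms = sorted({c for ivs in merged.values() for c, _, _ in ivs})
    candidates: list[CandidateRegion] = []
    for chrom in chroms:
        events: list[tuple[int, int, str]] = []
        for m in methods:
            for c, s, e in merged[m]:
                if c == chrom:
                    events.append((s, +1, m))
                    events.append((e, -1, m))
        cuts = sorted({p for p, _, _ in events})
        active: dict[str, int] = {}
        segs: list[tuple[int, int, frozenset[str]]] = []
        ei = 0
        events.sort(key=lambda t: (t[0], t[1]))
        for ci in range(len(cuts) - 1):
            p = cuts[ci]
            while ei < len(events) and events[ei][0] == p:
                _, delta, m = events[ei]
                active[m] = active.get(m, 0) + delta
                if active[m] == 0:
                    del active[m]
                ei += 1
            if len(active) >= min_methods:
                segs.append((p, cuts[ci + 1], frozenset(active)))
        # merge touching qualifying segments into maximal intervals
        for s, e, ms in segs:
            if candidates and candidates[-1].chrom == chrom \
                    and candidates[-1].end == s:
                prev = candidates[-1]
                candidates[-1] = CandidateRegion(
                    chrom, prev.start, e, prev.methods | ms)
            else:
                candidates.append(CandidateRegion(chrom, s, e, ms))
    return candidates, pairs


def read_genes_gff3(path) -> pd.DataFrame:
    """Gene features from a GFF3 file: (chrom, start, end, name);
    start is 1-based inclusive, end exclusive (GFF3 end + 1)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for g in db.features_of_type("gene"):
        name = (g.attributes.get("Name") or g.attributes.get("gene_name")
                or g.attributes.get("ID") or [g.id])[0]
        rows.append((g.seqid, g.start, g.end + 1, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def extend_and_annotate(regions: list[CandidateRegion], genes: pd.DataFrame,
                        chrom_lengths: dict[str, int], pad: int = 50_000
                        ) -> list[CandidateRegion]:
    """Pad each region by ``pad`` bp both sides (clipped to the
    chromosome) and attach every gene overlapping the padded interval.

    Regions on chromosomes absent from the gene table are annotated
    empty with a warning.
    """
    known_chroms = set(genes["chrom"].unique())
    out: list[CandidateRegion] = []
    for r in regions:
        if r.chrom not in chrom_lengths:
            raise ContractError(f"unknown chromosome {r.chrom}")
        s = max(1, r.start - pad)
        e = min(chrom_lengths[r.chrom] + 1, r.end + pad)
        if r.chrom not in known_chroms:
            log.warning("chromosome %s absent from gene annotation", r.chrom)
            out.append(CandidateRegion(r.chrom, s, e, r.methods, []))
            continue
        sub = genes[genes["chrom"] == r.chrom]
        hit = sub[(sub["start"] < e) & (sub["end"] > s)]
        out.append(CandidateRegion(r.chrom, s, e, r.methods,
                                   sorted(hit["name"].tolist())))
    return out


def region_span(regions: pd.DataFrame,
                methods: set[str] | frozenset[str] | None = None) -> float:
    """Total length in Mb (2 decimals) of regions, optionally restricted to
    rows whose supporting-method set equals ``methods`` exactly."""
    df = regions
    if methods is not None:
        want = frozenset(methods)
        sel = df["methods"].map(
            lambda m: frozenset(str(m).split(",")) == want)
        df = df[sel]
    total = int((df["end"] - df["start"]).sum()) if len(df) else 0
    return round(total / 1e6, 2)


def candidates_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, ",".join(sorted(r.methods)),
          ";".join(r.genes)) for r in regions],
        columns=["chrom", "start", "end", "methods", "genes"],
    )


def load_bundled_regions() -> pd.DataFrame:
    """Bundled example candidate-region table (chrom, start, end, methods,
    genes) used by the documentation and the acceptance checks."""
    with resources.files("sweepscan.data").joinpath(
            "example_candidate_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
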