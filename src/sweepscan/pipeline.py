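"""End-to-end orchestration: simulate/read -> QC -> CLR + iHS + ROH ->
window statistics -> outlier regions -> intersection -> annotation.

All thresholds live in :class:`PipelineConfig`; the config (and its
hash) is serialized into the output directory, every table is stamped
with the hash, and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clr_scan, genotype_io, ihs_scan, pop_stats, \
    region_select, roh_scan, synthetic_data
from .core import ConfigError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # input: either a VCF or a simulation
    vcf: str | None = None
    sim: synthetic_data.SimConfig | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    gff3: str | None = None
    ancestral_table: str | None = None
    out_dir: str = "sweepscan_out"
    seed: int = 0
    # QC
    qc: genotype_io.QCThresholds = field(
        default_factory=genotype_io.QCThresholds)
    # windows / thresholds
    window_size: int = 500_000
    window_step: int = 250_000
    top_fraction: float = 0.01
    min_sites_per_window: int = 2
    min_methods: int = 2
    pad: int = 50_000
    # CLR
    clr_grid_spacing: int = 10_000
    clr_alpha_grid_size: int = 20
    clr_max_dist: int = 500_000
    # iHS
    ehh_cutoff: float = 0.05
    ehh_max_gap: int = 200_000
    freq_bin_width: float = 0.025
    # ROH
    roh: roh_scan.ROHParams | None = None
    roh_top_fraction: float = 0.001

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded, so
        the same analysis run from a different directory hashes alike)."""
        d = self.to_dict()
        for key in ("vcf", "gff3", "ancestral_table", "out_dir"):
            d.pop(key, None)
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={tag}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full scan; returns the output directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # ------------------------------------------------------------------ input
    stage = "input"
    try:
        if config.sim is not None:
            sim = config.sim
            if sim.sweep_pos is not None:
                hm, vt, truth = synthetic_data.simulate_sweep(sim)
            else:
                hm, vt, truth = synthetic_data.simulate_neutral(sim)
            if sim.inbreeding_generations > 0:
                hm, tr2 = synthetic_data.simulate_inbred(sim, hm)
                truth.pedigree_inbred_ids = tr2.pedigree_inbred_ids
                vt = vt.copy()
                vt["n_called"] = len(hm.samples)
                vt["alt_count"] = hm.alleles.sum(axis=1)
            vcf_path = out / "input.vcf"
            synthetic_data.write_vcf(hm, vt, vcf_path,
                                     chrom_length=sim.chrom_length,
                                     seed=sim.seed)
            synthetic_data.write_truth(truth, hm.samples, out / "truth.tsv")
            chrom_lengths = dict(config.chrom_lengths) or \
                {sim.chrom: sim.chrom_length}
        elif config.vcf is not None:
            vcf_path = Path(config.vcf)
            chrom_lengths = dict(config.chrom_lengths)
            if not chrom_lengths:
                raise ConfigError("chrom_lengths required with VCF input")
        else:
            raise ConfigError("either vcf or sim must be provided")

        stage = "read"
        vt, gm, hmat = genotype_io.read_vcf(vcf_path)
        anc = (genotype_io.read_ancestral_table(config.ancestral_table)
               if config.ancestral_table else None)
        vt = genotype_io.resolve_ancestral(vt, anc)

        stage = "qc"
        vt, gm, hmat, qc_report = genotype_io.apply_qc(
            vt, gm, hmat, config.qc)
        _write_table(qc_report, out / "qc_report.tsv", tag)
        _write_table(vt.drop(columns=["pass_qc"]), out / "variants.tsv", tag)
        chrom = gm.chrom
        chrom_len = chrom_lengths.get(chrom)
        if chrom_len is None:
            raise ConfigError(f"no length for chromosome {chrom}")

        stage = "pop_stats"
        het = pop_stats.heterozygosity(gm)
        windows = region_select.make_windows(
            {chrom: chrom_len}, config.window_size, config.window_step)

        stage = "clr"
        derived, n_chrom, known = genotype_io.derived_counts(vt, gm)
        bg = clr_scan.background_sfs(derived, n_chrom, known)
        scanner = clr_scan.CLRScanner(
            bg,
            alpha_grid=clr_scan.default_alpha_grid(
                size=config.clr_alpha_grid_size),
            max_dist=config.clr_max_dist)
        pos = vt["pos"].to_numpy(dtype=np.int64)
        clr = scanner.scan(pos[known], derived[known], chrom_len,
                           config.clr_grid_spacing,
                           n_chrom=n_chrom[known])
        clr.insert(0, "chrom", chrom)
        _write_table(clr, out / "clr.tsv", tag)

        stage = "ihs"
        if hmat is None:
            raise ConfigError("iHS requires fully phased genotypes")
        derived_is_alt = (vt["ancestral"] == vt["ref"]).to_numpy()
        ihs = ihs_scan.ihs_scan(hmat, derived_is_alt, known,
                                cutoff=config.ehh_cutoff,
                                max_gap=config.ehh_max_gap)
        ihs = ihs_scan.standardize_ihs(ihs, config.freq_bin_width)
        ihs.insert(0, "chrom", chrom)
        _write_table(ihs, out / "ihs.tsv", tag)

        stage = "roh"
        roh_params = config.roh
        if roh_params is None:
            min_snps = roh_scan.lencz_min_snps(
                0.05, max(1, gm.n_sites), max(1, gm.n_samples),
                max(min(het.mean_ho, 0.99), 1e-6))
            roh_params = roh_scan.ROHParams(min_snps=min_snps)
        segments = roh_scan.detect_runs_all(gm, roh_params)
        _write_table(roh_scan.segments_frame(segments),
                     out / "roh_segments.tsv", tag)
        incidence = roh_scan.snp_incidence(segments, gm.positions,
                                           gm.n_samples, chrom=chrom)
        _write_table(pd.DataFrame({"chrom": chrom, "pos": gm.positions,
                                   "pct": incidence}),
                     out / "roh_incidence.tsv", tag)
        islands = roh_scan.roh_islands(incidence, gm.positions,
                                       config.roh_top_fraction,
                                       roh_params.max_gap)
        _write_table(pd.DataFrame(
            [(chrom, s - 1, e - 1) for s, e in islands],
            columns=["chrom", "bed_start", "bed_end"]),
            out / "roh_islands.bed.tsv", tag)
        fr = roh_scan.froh(segments, chrom_len, gm.samples)
        _write_table(fr.rename_axis("sample").reset_index(),
                     out / "froh.tsv", tag)

        stage = "windows"
        clr_w = region_select.aggregate(
            clr["pos"].to_numpy(), clr["clr"].to_numpy(), windows, "max",
            chrom=chrom, min_sites=1)
        scored = ihs[ihs["ihs"].notna()]
        ihs_w = region_select.aggregate(
            scored["pos"].to_numpy(), scored["ihs"].to_numpy(), windows,
            "mean_abs", chrom=chrom,
            min_sites=config.min_sites_per_window)
        clr_w, clr_thr = region_select.empirical_outliers(
            clr_w, config.top_fraction)
        ihs_w, ihs_thr = region_select.empirical_outliers(
            ihs_w, config.top_fraction)
        clr_w["method"] = "CLR"
        ihs_w["method"] = "iHS"
        _write_table(pd.concat([clr_w, ihs_w], ignore_index=True),
                     out / "window_stats.tsv", tag)

        stage = "regions"
        method_regions = {
            "CLR": region_select.merge_flagged(clr_w),
            "iHS": region_select.merge_flagged(ihs_w),
            "ROH": [(chrom, s, e) for s, e in islands],
        }
        region_rows = [(m, c, s, e) for m, ivs in method_regions.items()
                       for c, s, e in ivs]
        _write_table(pd.DataFrame(region_rows,
                                  columns=["method", "chrom", "start",
                                           "end"]),
                     out / "method_regions.tsv", tag)
        candidates, pairs = region_select.intersect_methods(
            method_regions, config.min_methods)
        _write_table(pairs, out / "method_pair_overlap.tsv", tag)

        stage = "annotate"
        if config.gff3:
            genes = region_select.read_genes_gff3(config.gff3)
            candidates = region_select.extend_and_annotate(
                candidates, genes, chrom_lengths, config.pad)
        _write_table(region_select.candidates_frame(candidates),
                     out / "candidates.tsv", tag)

        manifest = {
            "version": __version__,
            "config_hash": tag,
            "seed": config.seed,
            "n_sites_post_qc": int(gm.n_sites),
            "n_samples": int(gm.n_samples),
            "mean_he": het.mean_he,
            "mean_ho": het.mean_ho,
            "clr_threshold": clr_thr,
            "ihs_threshold": ihs_thr,
            "n_candidates": len(candidates),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        log.error("pipeline failed in stage %r (partial outputs kept in %s)",
                  stage, out)
        raise
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return out
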