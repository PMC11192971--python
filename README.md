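# sweepscan

Within-population selection-signature scanning in one reusable package:

- **CLR sweep scan** — a re-implementation of the composite likelihood
  ratio test for hard sweeps against the genome-wide background site
  frequency spectrum (star-like hitchhiking model with per-lineage escape
  probabilities, maximised over a log-spaced sweep-intensity grid).
- **iHS scan** — extended haplotype homozygosity (EHH), trapezoidal iHH
  integration, uniHS = ln(iHH_A / iHH_D), frequency-bin standardization,
  and the two-sided Gaussian tail transform
  PiHS = −log10(1 − 2|Φ(iHS) − 0.5|).
- **ROH scan** — consecutive-runs detection of runs of homozygosity
  (length / SNP-count / het / missing / gap constraints, with the
  false-positive-bound minimum SNP count), per-SNP ROH incidence,
  top-fraction ROH islands and the F_ROH inbreeding coefficient.
- **Region selection** — 500 kb / 250 kb-step sliding windows, per-window
  statistics (max CLR, mean |iHS|), empirical top-1 % outlier thresholds
  with tie inclusion, per-method interval merging, multi-method
  intersection (≥ 2 methods), ± 50 kb extension and GFF3 gene annotation.
- **Cohort statistics** — He/Ho, LD decay r² from phased haplotype
  frequencies, Yang's SNP-based genomic relationship matrix, PCA.
- **Built-in simulator** — a forward-in-time Wright–Fisher diploid
  simulator (discrete generations, infinite-sites mutation, Poisson
  crossovers) with conditioned hard sweeps and full-sib inbreeding
  pedigrees, emitting phased VCFv4.2 plus truth metadata, so the whole
  stack is testable without any external data.

Coordinates are 1-based for points; intervals are half-open
`[start, end)` so `end − start` is the length.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes exhaustive oracles (HWE exact test vs full
enumeration, ROH detection vs maximal-subsequence enumeration, the CLR
sweep-model site probabilities vs explicit 2ⁿ escape-configuration
enumeration, EHH vs pairwise-identity counting) and simulation-based
power/false-positive checks. The simulation-heavy acceptance tests live
in `tests/test_acceptance.py` and take the bulk of the runtime.

## CLI

```bash
sweepscan simulate --n-diploids 60 --chrom-length 2500000 --mu 1e-6 \
    --rec 2e-7 --pop-size 60 --generations 600 --sweep-pos 1250000 \
    --sweep-s 0.5 --sweep-target-freq 0.95 --seed 1 --out sim

sweepscan qc sim.vcf --out qc_report.tsv
sweepscan clr-scan sim.vcf --chrom-length 2500000 --out clr.tsv
sweepscan ihs-scan sim.vcf --out ihs.tsv
sweepscan roh-scan sim.vcf --out roh
sweepscan run-all --config pipeline.yaml
```

`run-all` executes simulate/read → QC → CLR + iHS + ROH → windows →
outliers → intersection → annotation, writing tab-separated tables, a
config-hash-stamped manifest, and (for simulated input) the truth table.
Reruns with the same config and seed are byte-identical.

A minimal `pipeline.yaml`:

```yaml
sim:
  n_diploids: 60
  chrom_length: 2500000
  mu: 1.0e-6
  rec: 2.0e-7
  pop_size: 60
  generations: 600
  sweep_pos: 1250000
  sweep_s: 0.5
  sweep_target_freq: 0.95
  seed: 1
out_dir: out
seed: 1
```

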