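"""Forward-in-time Wright-Fisher haplotype simulator.

Discrete generations, multinomial parent resampling, infinite-sites
mutation at integer positions and Poisson crossovers with uniform
breakpoints.  This is a compact emulator intended to exercise the scan
stack on phased data with realistic local LD — not a coalescent engine.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical configs therefore produce bit-identical
output, including the VCF bytes written by :func:`write_vcf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    ContractError,
    EstablishmentError,
    HaplotypeMatrix,
    InsufficientFoundersError,
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated chromosome."""

    n_diploids: int = 50
    chrom_length: int = 1_000_000
    mu: float = 2.5e-7          # per bp per generation
    rec: float = 1e-8           # per bp per generation
    pop_size: int = 100
    generations: int = 800
    sweep_pos: int | None = None
    sweep_s: float = 0.0
    sweep_target_freq: float = 1.0
    inbreeding_generations: int = 0
    n_inbred: int = 10
    seed: int = 0
    chrom: str = "1"
    max_sweep_retries: int = 1000
    sweep_max_generations: int | None = None  # default 20 * pop_size

    def validate(self) -> None:
        if self.pop_size <= 0 or self.chrom_length <= 0:
            raise ConfigError("pop_size and chrom_length must be positive")
        if self.n_diploids <= 0 or self.n_diploids > self.pop_size:
            raise ConfigError("need 0 < n_diploids <= pop_size")
        if min(self.mu, self.rec) < 0:
            raise ConfigError("rates must be non-negative")
        if self.sweep_pos is not None:
            if not (1 <= self.sweep_pos <= self.chrom_length):
                raise ConfigError("sweep_pos outside chromosome")
            if self.sweep_s <= 0:
                raise ConfigError("sweep_s must be > 0 when sweep_pos is set")
            if not (0 < self.sweep_target_freq <= 1):
                raise ConfigError("sweep_target_freq must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated haplotypes."""

    sweep_pos: int | None = None
    final_beneficial_freq: float = 0.0
    pedigree_inbred_ids: list[str] = field(default_factory=list)
    realized_het: float = 0.0
    seed: int = 0


class _Population:
    """2N haplotypes, each a sorted int64 array of derived-mutation positions."""

    def __init__(self, pop_size: int, chrom_length: int, mu: float, rec: float,
                 rng: np.random.Generator):
        self.N = pop_size
        self.L = chrom_length
        self.mu = mu
        self.rec = rec
        self.rng = rng
        self.haps: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(2 * pop_size)
        ]
        self._used: set[int] = set()

    # -- gamete construction ------------------------------------------------
    def _new_mutations(self) -> np.ndarray:
        k = self.rng.poisson(self.mu * self.L)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        out = []
        while len(out) < k:
            p = int(self.rng.integers(1, self.L + 1))
            if p not in self._used:
                self._used.add(p)
                out.append(p)
        return np.array(out, dtype=np.int64)

    def gamete(self, parent: int) -> np.ndarray:
        h = [self.haps[2 * parent], self.haps[2 * parent + 1]]
        cur = int(self.rng.integers(2))
        nx = self.rng.poisson(self.rec * self.L)
        if nx == 0:
            child = h[cur]
        else:
            cuts = np.sort(self.rng.integers(1, self.L + 1, size=nx))
            pieces = []
            lo = 0
            for c in cuts:
                src = h[cur]
                i0 = np.searchsorted(src, lo, side="left")
                i1 = np.searchsorted(src, c, side="left")
                pieces.append(src[i0:i1])
                cur ^= 1
                lo = c
            src = h[cur]
            pieces.append(src[np.searchsorted(src, lo, side="left"):])
            child = np.concatenate(pieces)
        mut = self._new_mutations()
        if mut.size:
            child = np.sort(np.concatenate([child, mut]))
        else:
            child = child.copy()
        return child

    # -- generation advance -------------------------------------------------
    def step(self, fitness: np.ndarray | None = None) -> None:
        N = self.N
        if fitness is None:
            parents = self.rng.integers(0, N, size=2 * N)
        else:
            p = fitness / fitness.sum()
            parents = self.rng.choice(N, size=2 * N, p=p)
        self.haps = [self.gamete(int(par)) for par in parents]

    def dosages(self, pos: int) -> np.ndarray:
        """Per-diploid derived-allele dosage at one position."""
        carrier = np.array(
            [np.searchsorted(h, pos) < h.size and h[np.searchsorted(h, pos)] == pos
             for h in self.haps],
            dtype=np.int64,
        )
        return carrier[0::2] + carrier[1::2]

    def derived_freq(self, pos: int) -> float:
        n = sum(
            1 for h in self.haps
            if (i := np.searchsorted(h, pos)) < h.size and h[i] == pos
        )
        return n / (2 * self.N)

    def purge(self, keep: int | None = None) -> None:
        """Drop mutations fixed in the whole population (except ``keep``)."""
        if not any(h.size for h in self.haps):
            return
        allpos, counts = np.unique(np.concatenate(self.haps), return_counts=True)
        fixed = set(allpos[counts == 2 * self.N].tolist())
        fixed.discard(keep)
        if fixed:
            arr = np.array(sorted(fixed), dtype=np.int64)
            self.haps = [h[~np.isin(h, arr)] for h in self.haps]

    def snapshot(self) -> list[np.ndarray]:
        return [h.copy() for h in self.haps]

    def restore(self, snap: list[np.ndarray]) -> None:
        self.haps = [h.copy() for h in snap]


def _sample_matrix(pop: _Population, cfg: SimConfig, rng: np.random.Generator,
                   force_keep: int | None = None) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    idx = np.sort(rng.choice(pop.N, size=cfg.n_diploids, replace=False))
    hap_idx = np.empty(2 * cfg.n_diploids, dtype=np.int64)
    hap_idx[0::2] = 2 * idx
    hap_idx[1::2] = 2 * idx + 1
    haps = [pop.haps[i] for i in hap_idx]
    if any(h.size for h in haps):
        allpos, counts = np.unique(np.concatenate(haps), return_counts=True)
    else:
        allpos = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    n_haps = 2 * cfg.n_diploids
    seg = (counts > 0) & (counts < n_haps)
    if force_keep is not None:
        seg |= allpos == force_keep
    pos = allpos[seg]
    mat = np.zeros((pos.size, n_haps), dtype=np.int8)
    for col, h in enumerate(haps):
        hits = h[np.isin(h, pos)]
        mat[np.searchsorted(pos, hits), col] = 1

    ref_idx = rng.integers(0, 4, size=pos.size)
    alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
    vt = pd.DataFrame({
        "chrom": cfg.chrom,
        "pos": pos,
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "ancestral": _BASES[ref_idx],  # reference is the true ancestral state
        "n_called": cfg.n_diploids,
        "alt_count": mat.sum(axis=1),
        "mean_depth": np.nan,
    })
    samples = [f"s{i}" for i in range(cfg.n_diploids)]
    return HaplotypeMatrix(cfg.chrom, pos, mat, samples), vt


def _realized_het(hm: HaplotypeMatrix) -> float:
    if hm.n_sites == 0:
        return 0.0
    p = hm.alleles.mean(axis=1)
    return float(np.mean(2 * p * (1 - p)))


def simulate_neutral(config: SimConfig) -> tuple[HaplotypeMatrix, pd.DataFrame, SimTruth]:
    """Run a neutral WF population and sample ``n_diploids`` individuals."""
    config.validate()
    if config.sweep_pos is not None:
        raise ConfigError("sweep_pos must be absent for neutral simulation")
    rng = np.random.default_rng(config.seed)
    pop = _Population(config.pop_size, config.chrom_length, config.mu, config.rec, rng)
    for g in range(config.generations):
        pop.step()
        if g % 25 == 24:
            pop.purge()
    pop.purge()
    hm, vt = _sample_matrix(pop, config, rng)
    truth = SimTruth(realized_het=_realized_het(hm), seed=config.seed)
    return hm, vt, truth


def simulate_sweep(config: SimConfig) -> tuple[HaplotypeMatrix, pd.DataFrame, SimTruth]:
    """Neutral burn-in, then a conditioned hard sweep at ``sweep_pos``.

    The beneficial mutation is injected on one random haplotype and the
    selection phase re-run (fresh draws) until its frequency reaches
    ``sweep_target_freq``; sampling happens at the first generation the
    target is met.  Retries are capped by ``max_sweep_retries``.
    """
    config.validate()
    if config.sweep_pos is None:
        raise ConfigError("sweep_pos required")
    rng = np.random.default_rng(config.seed)
    pop = _Population(config.pop_size, config.chrom_length, config.mu, config.rec, rng)
    for g in range(config.generations):
        pop.step()
        if g % 25 == 24:
            pop.purge()
    pop.purge()
    snap = pop.snapshot()
    used_snap = set(pop._used)
    b = int(config.sweep_pos)
    s = config.sweep_s
    max_gen = config.sweep_max_generations or 20 * config.pop_size

    for _ in range(config.max_sweep_retries):
        pop.restore(snap)
        pop._used = set(used_snap)
        pop._used.add(b)
        # inject on one random haplotype (it may already be monomorphic there:
        # positions are unique by construction, so b is never pre-occupied)
        i = int(rng.integers(2 * config.pop_size))
        pop.haps[i] = np.sort(np.append(pop.haps[i], b))
        ok = False
        for g in range(max_gen):
            dos = pop.dosages(b)
            w = 1.0 + s * dos.astype(float)
            pop.step(fitness=w)
            freq = pop.derived_freq(b)
            if freq >= config.sweep_target_freq:
                ok = True
                break
            if freq == 0.0:
                break
            if g % 25 == 24:
                pop.purge(keep=b)
        if ok:
            hm, vt = _sample_matrix(pop, config, rng, force_keep=b)
            truth = SimTruth(
                sweep_pos=b,
                final_beneficial_freq=pop.derived_freq(b),
                realized_het=_realized_het(hm),
                seed=config.seed,
            )
            return hm, vt, truth
    raise EstablishmentError(
        f"sweep did not reach {config.sweep_target_freq} in "
        f"{config.max_sweep_retries} attempts"
    )


def simulate_inbred(config: SimConfig, base: HaplotypeMatrix
                    ) -> tuple[HaplotypeMatrix, SimTruth]:
    """Append offspring of repeated full-sib matings to ``base``.

    Each inbred individual descends from its own founder pair drawn from
    ``base``: the pair produces two full sibs, and sib x sib matings are
    iterated ``inbreeding_generations`` times before the final offspring
    is emitted (one full-sib generation gives pedigree F = 0.25).
    Recombination uses ``config.rec``; no new mutations are introduced,
    so every offspring allele traces to a founder allele.
    """
    config.validate()
    if config.inbreeding_generations == 0:
        return base, SimTruth(seed=config.seed)
    if base.n_haplotypes < 4:
        raise InsufficientFoundersError("need >= 4 founder haplotypes")
    rng = np.random.default_rng(config.seed + 0x1B)
    pos = base.positions
    L = config.chrom_length

    def gamete(dip: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        cur = int(rng.integers(2))
        nx = rng.poisson(config.rec * L)
        if nx == 0:
            return dip[cur].copy()
        cuts = np.sort(rng.integers(1, L + 1, size=nx))
        child = dip[cur].copy()
        idx = np.searchsorted(pos, cuts)
        for j, i0 in enumerate(idx):
            cur ^= 1
            child[i0:] = dip[cur][i0:]
        return child

    def child(pair):
        (m1, m2), (f1, f2) = pair
        return (gamete((m1, m2)), gamete((f1, f2)))

    n_found = base.n_haplotypes // 2
    new_cols = []
    ids = []
    for k in range(config.n_inbred):
        a, bb = rng.choice(n_found, size=2, replace=False)
        pair = (
            (base.alleles[:, 2 * a].copy(), base.alleles[:, 2 * a + 1].copy()),
            (base.alleles[:, 2 * bb].copy(), base.alleles[:, 2 * bb + 1].copy()),
        )
        for _ in range(config.inbreeding_generations):
            pair = (child(pair), child(pair))
        off = child(pair)
        new_cols.extend(off)
        ids.append(f"inbred{k}")

    alleles = np.column_stack([base.alleles] + [c for c in new_cols]).astype(np.int8)
    hm = HaplotypeMatrix(base.chrom, pos.copy(), alleles, list(base.samples) + ids)
    return hm, SimTruth(pedigree_inbred_ids=ids, realized_het=_realized_het(hm),
                        seed=config.seed)


def write_vcf(haps: HaplotypeMatrix, variants: pd.DataFrame, path,
              chrom_length: int | None = None, seed: int | None = None) -> None:
    """Write phased VCFv4.2 with the ancestral allele in INFO/AA."""
    if len(variants) != haps.n_sites:
        raise ContractError("variant table / haplotype matrix length mismatch")
    p = np.asarray(variants["pos"], dtype=np.int64)
    if p.size > 1 and not np.all(np.diff(p) > 0):
        raise ContractError("refusing to write unsorted positions")
    clen = chrom_length or (int(p[-1]) if p.size else 1)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sweepscan" + (f" seed={seed}" if seed is not None else ""),
        f"##contig=<ID={haps.chrom},length={clen}>",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if haps.samples:
        header += "\tFORMAT\t" + "\t".join(haps.samples)
    lines.append(header)
    sym = {0: "0", 1: "1"}
    for i, row in enumerate(variants.itertuples(index=False)):
        rec = [str(row.chrom), str(row.pos), ".", str(row.ref), str(row.alt),
               ".", "PASS", f"AA={row.ancestral}"]
        if haps.samples:
            a = haps.alleles[i]
            gts = [
                f"{sym.get(int(a[2 * j]), '.')}|{sym.get(int(a[2 * j + 1]), '.')}"
                for j in range(len(haps.samples))
            ]
            rec.append("GT")
            rec.extend(gts)
        lines.append("\t".join(rec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_truth(truth: SimTruth, samples: list[str], path) -> None:
    """Tab-separated truth metadata (one row per sample plus a header comment)."""
    inbred = set(truth.pedigree_inbred_ids)
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed} sweep_pos={truth.sweep_pos} "
                 f"final_beneficial_freq={truth.final_beneficial_freq:.6g} "
                 f"realized_het={truth.realized_het:.6g}\n")
        fh.write("sample_id\tpedigree_inbred\n")
        for s in samples:
            fh.write(f"{s}\t{int(s in inbred)}\n")
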