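import numpy as np
import pytest

from sweepscan import synthetic_data as sd
from sweepscan.core import HaplotypeMatrix


@pytest.fixture(scope="session")
def neutral_sim():
    """One small neutral simulation shared across tests."""
    cfg = sd.SimConfig(n_diploids=30, chrom_length=400_000, mu=1e-6,
                       rec=3e-7, pop_size=40, generations=400, seed=11)
    hm, vt, truth = sd.simulate_neutral(cfg)
    return cfg, hm, vt, truth


@pytest.fixture(scope="session")
def sweep_sim():
    """One small conditioned-sweep simulation shared across tests."""
    cfg = sd.SimConfig(n_diploids=40, chrom_length=1_000_000, mu=1e-6,
                       rec=3e-7, pop_size=50, generations=400, seed=5,
                       sweep_pos=500_000, sweep_s=0.5,
                       sweep_target_freq=0.95)
    hm, vt, truth = sd.simulate_sweep(cfg)
    return cfg, hm, vt, truth


def make_haps(rows: list[str], positions=None, chrom="1") -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from strings of per-site haplotype alleles.

    Each entry of ``rows`` is one site, e.g. "0011" = four haplotypes.
    """
    mat = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
    if positions is None:
        positions = 1000 * (np.arange(len(rows)) + 1)
    n_samp = mat.shape[1] // 2
    return HaplotypeMatrix(chrom, np.asarray(positions, dtype=np.int64),
                           mat, [f"s{i}" for i in range(n_samp)])
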