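import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import roh_scan as rs
from sweepscan.core import MISSING, ContractError, ROHSegment


def runs_oracle(codes, pos, params):
    """Exhaustive greedy left-to-right enumeration of maximal runs,
    independent of the two-pointer implementation: from the current
    cursor, emit the leftmost interval that is budget-maximal within the
    remaining suffix and passes the length/SNP minima, then continue
    after it."""
    n = len(codes)

    def budgets_ok(a, b):
        window = codes[a:b + 1]
        if sum(1 for c in window if c == 1) > params.max_het:
            return False
        if sum(1 for c in window if c == MISSING) > params.max_missing:
            return False
        for t in range(a + 1, b + 1):
            if pos[t] - pos[t - 1] > params.max_gap:
                return False
        return True

    chosen = []
    cursor = 0
    while cursor < n:
        emitted = None
        for a in range(cursor, n):
            # brute-force the budget-maximal right extension
            b = a - 1
            for bb in range(a, n):
                if budgets_ok(a, bb):
                    b = bb
                else:
                    break
            if b < a:
                continue
            if a > cursor and budgets_ok(a - 1, b):
                continue  # extendable left within the suffix
            if b - a + 1 >= params.min_snps and \
                    pos[b] - pos[a] >= params.min_length:
                emitted = (a, b)
                break
        if emitted is None:
            break
        chosen.append(emitted)
        cursor = emitted[1] + 1
    return chosen


def segs_to_idx(segs, pos):
    lookup = {int(p): i for i, p in enumerate(pos)}
    return [(lookup[s.start], lookup[s.end]) for s in segs]


class TestLenczMinSnps:
    def test_near_forced_zero(self):
        # as alpha approaches ns * ni the numerator approaches ln(1) = 0
        # and the ceiling collapses to (at most) a single SNP
        assert rs.lencz_min_snps(0.5, 1, 1, 0.25) == \
            pytest.approx(np.ceil(np.log(0.5) / np.log(0.75)))
        assert rs.lencz_min_snps(0.9999999, 1, 1, 0.25) <= 1

    def test_worked_example(self):
        assert rs.lencz_min_snps(0.05, 1_000_000, 100, 0.25) == 75

    def test_zero_het_rejected(self):
        with pytest.raises(ContractError):
            rs.lencz_min_snps(0.05, 100, 10, 0.0)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ContractError):
            rs.lencz_min_snps(1.5, 100, 10, 0.25)


def params_small(**kw):
    base = dict(min_length=1, max_gap=500_000, max_het=1, max_missing=2,
                min_snps=1)
    base.update(kw)
    return rs.ROHParams(**base)


class TestDetectRuns:
    def test_clean_long_run(self):
        pos = np.arange(200) * 2010 + 1  # spans ~400 kb
        codes = np.zeros(200, dtype=np.int8)
        params = rs.ROHParams(min_length=300_000, min_snps=88)
        segs = rs.detect_runs(codes, pos, params)
        assert len(segs) == 1
        s = segs[0]
        assert s.n_snps == 200
        assert s.length == int(pos[-1] - pos[0])
        assert s.n_het == 0 and s.n_missing == 0

    def test_two_hets_split_run(self):
        pos = np.arange(200) * 2010 + 1
        codes = np.zeros(200, dtype=np.int8)
        codes[90] = 1
        codes[110] = 1
        params = rs.ROHParams(min_length=100_000, min_snps=30, max_het=1)
        segs = rs.detect_runs(codes, pos, params)
        oracle = runs_oracle(codes.tolist(), pos.tolist(), params)
        assert segs_to_idx(segs, pos) == oracle
        assert len(segs) >= 2
        for s in segs:
            assert s.n_het <= 1

    def test_gap_breaks_run(self):
        pos = np.concatenate([np.arange(100) * 3100 + 1,
                              np.arange(100) * 3100 + 1_000_000])
        codes = np.zeros(200, dtype=np.int8)
        params = rs.ROHParams(min_length=200_000, min_snps=50,
                              max_gap=500_000)
        segs = rs.detect_runs(codes, pos, params)
        assert len(segs) == 2
        assert segs[0].end <= int(pos[99])
        assert segs[1].start == 1_000_000

    def test_unsorted_rejected(self):
        with pytest.raises(ContractError):
            rs.detect_runs(np.zeros(3, dtype=np.int8),
                           np.array([5, 3, 10]), params_small())

    def test_emitted_counters_match_raw_genotypes(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2, MISSING], size=400,
                           p=[0.55, 0.07, 0.3, 0.08]).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 400,
                                 replace=False))
        params = rs.ROHParams(min_length=50_000, min_snps=10)
        segs = rs.detect_runs(codes, pos, params)
        for s in segs:
            a = int(np.searchsorted(pos, s.start))
            b = int(np.searchsorted(pos, s.end))
            window = codes[a:b + 1]
            assert s.n_snps == b - a + 1
            assert s.n_het == int((window == 1).sum())
            assert s.n_missing == int((window == MISSING).sum())
            assert s.n_het <= params.max_het
            assert s.n_missing <= params.max_missing
            assert s.length >= params.min_length
            assert s.n_snps >= params.min_snps

    def test_segments_never_overlap(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            codes = rng.choice([0, 1, 2, MISSING], size=120,
                               p=[0.5, 0.1, 0.3, 0.1]).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 500_000), 120,
                                     replace=False))
            segs = rs.detect_runs(codes, pos,
                                  params_small(min_snps=5, min_length=5000))
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.end < s2.start


@given(
    codes=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1,
                   max_size=30),
    gaps=st.lists(st.integers(min_value=1, max_value=2000), min_size=30,
                  max_size=30),
    max_het=st.integers(min_value=0, max_value=2),
    max_missing=st.integers(min_value=0, max_value=2),
    min_snps=st.integers(min_value=1, max_value=6),
    min_length=st.integers(min_value=1, max_value=4000),
    max_gap=st.integers(min_value=500, max_value=1500),
)
@settings(max_examples=150, deadline=None)
def test_detect_runs_matches_oracle(codes, gaps, max_het, max_missing,
                                    min_snps, min_length, max_gap):
    n = len(codes)
    pos = np.cumsum(gaps[:n]).astype(np.int64)
    params = rs.ROHParams(min_length=min_length, max_gap=max_gap,
                          max_het=max_het, max_missing=max_missing,
                          min_snps=min_snps)
    segs = rs.detect_runs(np.array(codes, dtype=np.int8), pos, params)
    assert segs_to_idx(segs, pos) == runs_oracle(codes, pos.tolist(), params)


class TestFroh:
    def test_no_segments_zero(self):
        fr = rs.froh([], 1_000_000, ["a", "b"])
        assert (fr == 0).all()

    def test_direct_ratio(self):
        segs = [ROHSegment("a", "1", 1, 24_500_001, 10, 0, 0)]
        fr = rs.froh(segs, 2_450_000_000, ["a"])
        assert fr["a"] == pytest.approx(0.01)

    def test_bounded(self, neutral_sim):
        _, hm, _, _ = neutral_sim
        gm = hm.to_genotypes()
        segs = rs.detect_runs_all(gm, params_small(min_snps=3))
        fr = rs.froh(segs, 400_000, gm.samples)
        assert ((fr >= 0) & (fr <= 1)).all()

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ContractError):
            rs.froh([], 0, ["a"])


class TestSnpIncidence:
    def test_full_coverage(self):
        pos = np.array([100, 200, 300])
        segs = [ROHSegment(f"s{i}", "1", 50, 400, 3, 0, 0)
                for i in range(4)]
        inc = rs.snp_incidence(segs, pos, 4)
        assert np.allclose(inc, 100.0)

    def test_partial_coverage(self):
        pos = np.array([100, 200, 300])
        segs = [ROHSegment(f"s{i}", "1", 150, 250, 1, 0, 0)
                for i in range(3)]
        inc = rs.snp_incidence(segs, pos, 10)
        assert np.allclose(inc, [0.0, 30.0, 0.0])

    def test_outside_all_segments_zero(self):
        pos = np.array([1000])
        segs = [ROHSegment("s0", "1", 100, 200, 2, 0, 0)]
        inc = rs.snp_incidence(segs, pos, 2)
        assert inc[0] == 0.0

    def test_interval_stabbing_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        segs = []
        for i in range(8):
            for _ in range(rng.integers(1, 4)):
                a = int(rng.integers(1, 90_000))
                b = a + int(rng.integers(1000, 20_000))
                segs.append(ROHSegment(f"s{i}", "1", a, b, 1, 0, 0))
        inc = rs.snp_incidence(segs, pos, 8)
        for k, p in enumerate(pos):
            hit = {s.sample for s in segs if s.start <= p <= s.end}
            assert inc[k] == pytest.approx(100.0 * len(hit) / 8)

    def test_duplicate_segments_same_sample_count_once(self):
        pos = np.array([100])
        segs = [ROHSegment("s0", "1", 50, 150, 1, 0, 0),
                ROHSegment("s0", "1", 90, 110, 1, 0, 0)]
        inc = rs.snp_incidence(segs, pos, 2)
        assert inc[0] == pytest.approx(50.0)


class TestRohIslands:
    def test_single_top_snp(self):
        inc = np.zeros(1000)
        inc[123] = 40.0
        inc[5] = 1.0
        pos = np.arange(1000) * 100 + 1
        islands = rs.roh_islands(inc, pos, top_fraction=0.001)
        assert islands == [(int(pos[123]), int(pos[123]) + 1)]

    def test_nearby_flagged_snps_merge(self):
        inc = np.zeros(2000)
        inc[100] = 50.0
        inc[101] = 50.0
        pos = np.arange(2000) * 1000 + 1
        islands = rs.roh_islands(inc, pos, top_fraction=0.001)
        assert len(islands) == 1
        assert islands[0] == (int(pos[100]), int(pos[101]) + 1)

    def test_distant_flagged_snps_stay_separate(self):
        inc = np.zeros(2000)
        inc[10] = 50.0
        inc[1800] = 50.0
        pos = np.arange(2000) * 1000 + 1
        islands = rs.roh_islands(inc, pos, top_fraction=0.001,
                                 max_gap=500_000)
        assert len(islands) == 2

    def test_ties_at_threshold_all_flagged(self):
        inc = np.zeros(1000)
        inc[[3, 400, 800]] = 25.0  # k = 1 but three tied SNPs
        pos = np.arange(1000) * 100 + 1
        islands = rs.roh_islands(inc, pos, top_fraction=0.001)
        covered = {p for s, e in islands for p in range(s, e)}
        assert int(pos[3]) in covered
        assert int(pos[400]) in covered
        assert int(pos[800]) in covered

    def test_all_zero_incidence_empty(self):
        assert rs.roh_islands(np.zeros(10), np.arange(10) * 100 + 1) == []

    def test_islands_disjoint(self):
        rng = np.random.default_rng(2)
        inc = rng.random(5000) * 30
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), 5000,
                                 replace=False))
        islands = rs.roh_islands(inc, pos, top_fraction=0.002)
        for (s1, e1), (s2, e2) in zip(islands, islands[1:]):
            assert e1 <= s2
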