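import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sweepscan import ihs_scan as ih
from sweepscan.core import ContractError

from conftest import make_haps


def ehh_pairwise_oracle(haps, core, allele, direction, stop_below=None):
    """EHH by direct pairwise identity tracking (independent of the
    partition-refinement implementation).  ``stop_below`` truncates the
    curve after the first value under that threshold."""
    carriers = np.nonzero(haps.alleles[core] == allele)[0]
    n = carriers.size
    pairs = list(itertools.combinations(range(n), 2))
    identical = {p: True for p in pairs}
    out = [(int(haps.positions[core]), 1.0)]
    i = core + direction
    while 0 <= i < haps.n_sites:
        row = haps.alleles[i][carriers]
        for (a, b) in pairs:
            if identical[(a, b)] and row[a] != row[b]:
                identical[(a, b)] = False
        e = sum(identical.values()) / (n * (n - 1) / 2)
        out.append((int(haps.positions[i]), e))
        if stop_below is not None and e < stop_below:
            break
        i += direction
    return out


class TestEhh:
    def test_core_value_is_one(self):
        hm = make_haps(["0011", "0101"])
        curve = ih.ehh(hm, 0, 1, +1, cutoff=0.0)
        assert curve.ehh[0] == 1.0

    def test_two_two_split(self):
        # 4 carriers splitting 2/2 at the first flank: (1+1)/C(4,2) = 1/3
        hm = make_haps(["1111", "0011"])
        curve = ih.ehh(hm, 0, 1, +1, cutoff=0.0)
        assert curve.ehh[1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        hm = make_haps(["1111", "0000", "1111", "0000"])
        curve = ih.ehh(hm, 0, 1, +1, cutoff=0.0)
        assert np.allclose(curve.ehh, 1.0)

    def test_single_carrier_rejected(self):
        hm = make_haps(["1000", "0011"])
        with pytest.raises(ContractError):
            ih.ehh(hm, 0, 1, +1)

    def test_monotone_non_increasing(self, neutral_sim):
        _, hm, _, _ = neutral_sim
        for core in range(0, hm.n_sites, max(1, hm.n_sites // 10)):
            for allele in (0, 1):
                if (hm.alleles[core] == allele).sum() < 2:
                    continue
                for direction in (+1, -1):
                    c = ih.ehh(hm, core, allele, direction, cutoff=0.0,
                               max_gap=10 ** 9)
                    assert np.all(np.diff(c.ehh) <= 1e-12)

    def test_matches_pairwise_oracle(self, neutral_sim):
        _, hm, _, _ = neutral_sim
        rng = np.random.default_rng(0)
        cores = rng.choice(hm.n_sites, size=5, replace=False)
        for core in cores:
            for allele in (0, 1):
                if (hm.alleles[core] == allele).sum() < 2:
                    continue
                got = ih.ehh(hm, int(core), allele, +1, cutoff=0.0,
                             max_gap=10 ** 9)
                want = ehh_pairwise_oracle(hm, int(core), allele, +1)
                want_vals = [v for _, v in want[:len(got.ehh)]]
                assert np.allclose(got.ehh, want_vals, atol=1e-12)

    def test_gap_censors_curve(self):
        hm = make_haps(["1111", "0011"], positions=[1000, 500_000])
        curve = ih.ehh(hm, 0, 1, +1, cutoff=0.05, max_gap=200_000)
        assert curve.edge_censored
        assert len(curve.ehh) == 1


class TestIhh:
    def test_triangle_area(self):
        curve = ih.EHHCurve(0, 1, np.array([0, 1000, 2000]),
                            np.array([1.0, 0.5, 0.0]))
        assert ih.ihh_one_side(curve, cutoff=0.0) == pytest.approx(1000.0)

    def test_rectangle_area(self):
        curve = ih.EHHCurve(0, 1, np.array([0, 1000]), np.array([1.0, 1.0]))
        assert ih.ihh_one_side(curve, cutoff=0.0) == pytest.approx(1000.0)

    def test_cutoff_crossing_interpolated(self):
        # drops from 1.0 to 0.0 over 1000 bp with cutoff 0.5: integrate
        # trapezoid down to the crossing at 500 bp: (1+0.5)/2 * 500 = 375
        curve = ih.EHHCurve(0, 1, np.array([0, 1000]), np.array([1.0, 0.0]))
        assert ih.ihh_one_side(curve, cutoff=0.5) == pytest.approx(375.0)

    def test_two_sided_symmetric(self):
        hm = make_haps(["0011", "1111", "0011"])
        area, censored = ih.ihh(hm, 1, 1, cutoff=0.0, max_gap=10 ** 9)
        left = ih.ihh_one_side(ih.ehh(hm, 1, 1, -1, cutoff=0.0), 0.0)
        assert area == pytest.approx(2 * left)

    def test_dense_riemann_agreement(self):
        rng = np.random.default_rng(1)
        y = np.sort(rng.random(50))[::-1]
        y[0] = 1.0
        x = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        x[0] = 0
        curve = ih.EHHCurve(0, 1, x, y)
        got = ih.ihh_one_side(curve, cutoff=0.0)
        want = np.trapezoid(y, x)
        assert got == pytest.approx(want, rel=1e-6)

    def test_fast_kernel_matches_python_path(self, neutral_sim):
        _, hm, _, _ = neutral_sim
        if not ih._HAVE_NUMBA:
            pytest.skip("numba unavailable")
        for core in range(0, hm.n_sites, max(1, hm.n_sites // 15)):
            for allele in (0, 1):
                if min((hm.alleles[core] == a).sum() for a in (0, 1)) < 2:
                    continue
                slow = ih.ihh(hm, core, allele, 0.05, 200_000)
                fast = ih._ihh_fast(hm, core, allele, 0.05, 200_000)
                assert fast[0] == pytest.approx(slow[0], rel=1e-9)
                assert fast[1] == slow[1]


class TestFullScanAgreement:
    def test_unihs_correlates_with_pairwise_route(self, sweep_sim):
        """Dual-route check: the production scan against uniHS computed
        from pairwise-identity EHH curves (independent algorithm)."""
        _, hm, _, _ = sweep_sim
        scan = ih.ihs_scan(hm, np.ones(hm.n_sites, dtype=bool))
        scan = scan[~scan["edge_censored"]]
        if len(scan) > 25:
            scan = scan.sample(25, random_state=0)
        assert len(scan) >= 10
        pos_to_idx = {int(p): i for i, p in enumerate(hm.positions)}
        oracle_vals = []
        for p in scan["pos"]:
            core = pos_to_idx[int(p)]
            areas = {}
            for allele in (0, 1):
                total = 0.0
                for direction in (-1, +1):
                    curve = ehh_pairwise_oracle(hm, core, allele, direction,
                                                stop_below=0.05)
                    xs = np.abs(np.array([x for x, _ in curve], dtype=float)
                                - curve[0][0])
                    ys = np.array([v for _, v in curve])
                    total += ih.ihh_one_side(
                        ih.EHHCurve(core, allele, xs.astype(np.int64), ys),
                        cutoff=0.05)
                areas[allele] = total
            oracle_vals.append(np.log(areas[0] / areas[1]))
        r = np.corrcoef(scan["unihs"], oracle_vals)[0, 1]
        assert r > 0.95


class TestUnstandardizedIhs:
    def test_equal_areas_zero(self):
        assert ih.unstandardized_ihs(1000.0, 1000.0) == 0.0

    def test_log_two(self):
        assert ih.unstandardized_ihs(2000.0, 1000.0) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_antisymmetry(self):
        a = ih.unstandardized_ihs(1234.0, 777.0)
        b = ih.unstandardized_ihs(777.0, 1234.0)
        assert a == pytest.approx(-b)

    def test_zero_area_rejected(self):
        with pytest.raises(ContractError):
            ih.unstandardized_ihs(0.0, 100.0)


class TestStandardize:
    def _frame(self, unihs, freq=None, censored=False):
        n = len(unihs)
        return pd.DataFrame({
            "pos": np.arange(n) * 1000 + 1,
            "derived_freq": freq if freq is not None else np.full(n, 0.5),
            "ihh_a": 1.0, "ihh_d": 1.0,
            "unihs": unihs,
            "edge_censored": censored,
        })

    def test_single_bin_sample_sd_convention(self):
        out = ih.standardize_ihs(self._frame([-1.0, 0.0, 1.0]),
                                 min_bin_count=1)
        assert np.allclose(out["ihs"], [-1.0, 0.0, 1.0])

    def test_bin_mean_zero_sd_one(self, sweep_sim):
        _, hm, _, _ = sweep_sim
        tab = ih.ihs_scan(hm, np.ones(hm.n_sites, dtype=bool))
        out = ih.standardize_ihs(tab)
        scored = out[out["ihs"].notna()].copy()
        scored["bin"] = (scored["derived_freq"] / 0.025).astype(int)
        # bins may have been merged; verify the coarse moments instead
        assert scored["ihs"].mean() == pytest.approx(0.0, abs=0.2)
        assert scored["ihs"].std() == pytest.approx(1.0, abs=0.2)

    def test_constant_bin_left_unscored(self):
        out = ih.standardize_ihs(self._frame([0.7, 0.7, 0.7]),
                                 min_bin_count=1)
        assert out["ihs"].isna().all()

    def test_censored_sites_not_scored(self):
        df = self._frame([-1.0, 0.0, 1.0, 5.0])
        df.loc[3, "edge_censored"] = True
        out = ih.standardize_ihs(df, min_bin_count=1)
        assert np.isnan(out.loc[3, "ihs"])
        assert np.allclose(out.loc[:2, "ihs"], [-1.0, 0.0, 1.0])

    def test_sparse_bins_merged(self):
        # two frequency clusters, the upper one below min count: merged
        unihs = [0.0, 1.0, 2.0, 3.0, 10.0]
        freq = [0.10, 0.11, 0.12, 0.13, 0.90]
        out = ih.standardize_ihs(self._frame(unihs, freq), min_bin_count=5)
        assert out["ihs"].notna().all()


class TestPihs:
    def test_zero(self):
        assert ih.pihs(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_95th_two_sided(self):
        assert ih.pihs(1.959964) == pytest.approx(1.30103, abs=1e-4)

    def test_symmetry(self):
        for x in (0.3, 1.1, 2.7):
            assert ih.pihs(x) == pytest.approx(ih.pihs(-x))

    def test_matches_direct_formula(self):
        for x in (0.1, 0.5, 1.0, 2.0, 3.0):
            direct = -np.log10(1 - 2 * abs(norm.cdf(x) - 0.5))
            assert ih.pihs(x) == pytest.approx(direct, rel=1e-9)

    def test_monotone_in_magnitude(self):
        xs = np.linspace(0, 6, 50)
        vals = ih.pihs(xs)
        assert np.all(np.diff(vals) > 0)
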