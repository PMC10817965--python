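import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from loxscan.io_core import CentromereTable, Interval, IntervalSet, LoxSite, LoxSiteTable
from loxscan.junctions import CountsTable
from loxscan.scenarios import (
    arr_null_study,
    draw_null_counts,
    null_intra_fraction_study,
    rw_distance_calibration_study,
)
from loxscan.simulate import sparse_strain_table
from loxscan.stats import (
    RWMatrix,
    compute_arr,
    compute_rr,
    compute_rw,
    contact_correlation,
    contact_ratio_map,
    export_network,
    find_outliers,
    group_tests,
    intra_pair_fraction,
    observed_intra_fraction,
    read_network,
    rw_distance_regression,
)


def _counts(spec_norm: dict, spec_pairs: dict) -> CountsTable:
    loci = sorted(set(spec_norm) | {l for p in spec_pairs for l in p})
    c = CountsTable.empty(loci)
    c.nnorm.update(spec_norm)
    for pair, n in spec_pairs.items():
        c.nre_pair[frozenset(pair)] = n
        for l in pair:
            c.nre[l] = c.nre.get(l, 0) + n
    return c


class TestRR:
    @pytest.mark.parametrize("nnorm,nre,expected", [
        (4, 2, 0.2), (0, 5, 1.0), (7, 0, 0.0),
    ])
    def test_formula(self, nnorm, nre, expected):
        c = CountsTable.empty(["a", "b"])
        c.nnorm["a"] = nnorm
        c.nre["a"] = nre
        c.nre_pair[frozenset(("a", "b"))] = nre
        c.nre["b"] = nre
        assert compute_rr(c)["a"] == pytest.approx(expected, abs=1e-12)

    def test_no_observations_is_missing(self):
        c = CountsTable.empty(["a"])
        assert np.isnan(compute_rr(c)["a"])


class TestARR:
    def test_partner_normalisation_hand_computed(self):
        # locus a: Nnorm=12, Nre=6 all inter, 70 inter partners:
        # ARR_inter = (6/30)/70
        sites = [LoxSite("a", "chr1", 100), LoxSite("x", "chr1", 5_000)]
        sites += [LoxSite(f"b{k}", "chr2", 100 + 200 * k) for k in range(35)]
        sites += [LoxSite(f"c{k}", "chr3", 100 + 200 * k) for k in range(35)]
        table = LoxSiteTable(sites)
        pairs = {("a", f"b{k}"): 1 for k in range(6)}
        c = _counts({"a": 12}, pairs)
        for l in table:
            c.nnorm.setdefault(l.site_id, 10)
            c.loci = [s.site_id for s in table]
        arr = compute_arr(c, table, "inter")
        assert arr["a"] == pytest.approx((6 / 30) / 70, abs=1e-9)

    def test_zero_class_events_is_zero(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 10), LoxSite("b", "c1", 500),
                              LoxSite("d", "c2", 10)])
        c = _counts({"a": 5, "b": 5, "d": 5}, {("a", "b"): 3})
        assert compute_arr(c, sites, "inter")["a"] == 0.0

    def test_no_intra_partner_is_missing(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 10), LoxSite("d", "c2", 10)])
        c = _counts({"a": 5, "d": 5}, {("a", "d"): 2})
        assert np.isnan(compute_arr(c, sites, "intra")["a"])

    def test_global_normalisation_switch(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 10), LoxSite("b", "c1", 500),
                              LoxSite("d", "c2", 10)])
        c = _counts({"a": 5, "b": 5, "d": 5}, {("a", "d"): 2})
        arr = compute_arr(c, sites, "inter", normalization="global")
        # 2 rearranged loci (a, d): (2/12)/2
        assert arr["a"] == pytest.approx((2 / 12) / 2, abs=1e-12)


class TestRW:
    def test_formula(self):
        c = _counts({"a": 1, "b": 4}, {("a", "b"): 1})
        c.nnorm["a"], c.nre["a"] = 1, 2  # Nall_a = 4
        c.nnorm["b"], c.nre["b"] = 4, 1  # Nall_b = 9
        c.nre_pair[frozenset(("a", "b"))] = 1
        rw = compute_rw(c)
        assert rw.rw("a", "b") == pytest.approx(1 / 6, abs=1e-9)

    def test_symmetry_diagonal_and_depth_invariance_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            loci = [f"l{k}" for k in range(4)]
            c = CountsTable.empty(loci)
            for l in loci:
                c.nnorm[l] = int(rng.integers(1, 50))
            for i, a in enumerate(loci):
                for b in loci[i + 1:]:
                    n = int(rng.integers(0, 5))
                    if n:
                        c.nre_pair[frozenset((a, b))] = n
                        c.nre[a] += n
                        c.nre[b] += n
            rw = compute_rw(c)
            assert np.allclose(rw.values, rw.values.T)
            assert np.all(np.diag(rw.values) == 0)
            scaled = compute_rw(c.scaled(3.0))
            assert np.allclose(scaled.values, rw.values)

    def test_zero_pair_iff_zero_weight(self):
        c = _counts({"a": 2, "b": 2, "d": 2}, {("a", "b"): 1})
        rw = compute_rw(c)
        assert rw.rw("a", "d") == 0.0
        assert rw.rw("a", "b") > 0


class TestOutliers:
    def test_single_extreme_value(self):
        assert find_outliers({"a": 1, "b": 1, "c": 1, "d": 1, "e": 10}) == {"e"}

    def test_constant_values_give_none(self):
        assert find_outliers(dict(zip("abcde", [2.0] * 5))) == set()

    def test_uniform_spread_gives_none(self):
        assert find_outliers(dict(zip("abcde", [1, 2, 3, 4, 5]))) == set()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            find_outliers({"a": 1, "b": 2, "c": 3, "d": 4})


class TestDistanceRegression:
    def test_exact_inverse_distance_returns_unit_r2(self):
        res = rw_distance_calibration_study(slope=5.0)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert res["slope"] == pytest.approx(5.0, rel=1e-9)

    def test_permuted_weights_uncorrelated(self):
        rng = np.random.default_rng(0)
        sites = LoxSiteTable([
            LoxSite(f"X-{k}", "chrX", int(p), 1)
            for k, p in enumerate(sorted(rng.choice(180_000, 16, replace=False)), 1)
        ])
        cen = CentromereTable({"chrX": (190_000, 190_120)})
        loci = [s.site_id for s in sites]
        vals = np.zeros((16, 16))
        weights = rng.permutation(np.linspace(0.01, 0.2, 120))
        w = iter(weights)
        for i in range(16):
            for j in range(i + 1, 16):
                vals[i, j] = vals[j, i] = next(w)
        rw = RWMatrix(loci, vals)
        res = rw_distance_regression(rw, sites, cen)
        assert res.r_squared < 0.1
        assert res.p_value > 0.05

    def test_centromere_spanning_pairs_excluded(self):
        sites = LoxSiteTable([LoxSite("X-1", "chrX", 10_000),
                              LoxSite("X-2", "chrX", 20_000),
                              LoxSite("X-3", "chrX", 30_000),
                              LoxSite("X-4", "chrX", 90_000)])
        cen = CentromereTable({"chrX": (50_000, 50_120)})
        vals = np.full((4, 4), 0.1)
        np.fill_diagonal(vals, 0)
        rw = RWMatrix([s.site_id for s in sites], vals)
        res = rw_distance_regression(rw, sites, cen)
        assert res.n_pairs == 3  # only the three left-arm pairs


class TestGroupTests:
    def test_identical_groups_p_one(self):
        a = pd.Series([1.0, 1.0, 2.0, 2.0, 3.0])
        res = group_tests(a, a.copy())
        mw = res[0]
        assert mw.test == "mann_whitney"
        assert mw.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        sites = LoxSiteTable(
            [LoxSite(f"a{k}", "c1", 100 + 10_000 * k) for k in range(10)]
            + [LoxSite(f"b{k}", "c2", 100 + 10_000 * k) for k in range(10)])
        open_regions = IntervalSet([Interval("c1", 0, 200_000)])
        labels = [s.site_id for s in sites]
        arr_intra = pd.Series(0.0, index=labels)
        # inter ARR elevated at the open (c1) loci
        arr_inter = pd.Series(
            {f"a{k}": 1.0 + 0.001 * k for k in range(10)}
            | {f"b{k}": 0.001 * k for k in range(10)})
        res = group_tests(arr_intra, arr_inter, sites, open_regions)
        assert res[0].p_value < 1e-3
        assert res[1].test == "t_test_two_tailed"
        assert res[1].p_value < 1e-3

    def test_empty_group_named(self):
        with pytest.raises(ValueError, match="intra"):
            group_tests(pd.Series(dtype=float), pd.Series([1.0]))

    def test_open_chromatin_power_simulation(self):
        """2x elevation of inter ARR in open sites detected in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            closed = rng.gamma(4.0, 0.5, size=35)
            opened = rng.gamma(4.0, 1.0, size=40)  # doubled mean
            t = sps.ttest_ind(opened, closed, equal_var=True)
            hits += t.pvalue < 0.05
        assert hits >= 9


class TestContactOps:
    def _rw(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 100), LoxSite("b", "c2", 100),
                              LoxSite("d", "c3", 100), LoxSite("e", "c4", 100)])
        rng = np.random.default_rng(3)
        vals = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                vals[i, j] = vals[j, i] = rng.random()
        return RWMatrix(["a", "b", "d", "e"], vals), sites

    def test_identical_matrices_fully_correlated(self):
        rw, sites = self._rw()
        res = contact_correlation(rw, rw.values, sites)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_independent_contacts_uncorrelated(self):
        sites = LoxSiteTable([LoxSite(f"l{k}", f"c{k}", 100) for k in range(12)])
        rng = np.random.default_rng(11)
        n = 12
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = rng.random()
        rw = RWMatrix([f"l{k}" for k in range(n)], vals)
        contact = rng.random((n, n))
        contact = (contact + contact.T) / 2
        res = contact_correlation(rw, contact, sites)
        assert abs(res.statistic) < 0.25
        assert res.p_value > 0.05

    def test_constant_contacts_undefined(self):
        rw, sites = self._rw()
        res = contact_correlation(rw, np.ones_like(rw.values), sites)
        assert np.isnan(res.statistic)

    def test_shape_mismatch_rejected(self):
        rw, sites = self._rw()
        with pytest.raises(ValueError, match="shape"):
            contact_correlation(rw, np.ones((3, 3)), sites)

    def test_ratio_map_normalisation(self):
        a = np.abs(np.random.default_rng(5).random((6, 6))) + 0.1
        assert np.allclose(contact_ratio_map(a, a), 0.0)
        assert np.allclose(contact_ratio_map(2 * a, a), 0.0)
        b = a.copy()
        b[2, 3] *= 2
        out = contact_ratio_map(b, a)
        assert out[2, 3] > 0
        mask = np.ones_like(out, dtype=bool)
        mask[2, 3] = False
        assert np.allclose(out[mask], out[0, 0])


class TestNetworkExport:
    def _rw3(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 100), LoxSite("b", "c1", 900),
                              LoxSite("d", "c2", 100)])
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.28
        vals[0, 2] = vals[2, 0] = 0.01
        vals[1, 2] = vals[2, 1] = 0.05
        return RWMatrix(["a", "b", "d"], vals), sites

    def test_threshold_filters_edges(self, tmp_path):
        rw, sites = self._rw3()
        n_intra, n_inter = export_network(
            rw, sites, 0.02, tmp_path / "i.sif", tmp_path / "e.sif")
        assert n_intra + n_inter == 2
        assert n_intra == 1  # a-b on one chromosome

    def test_threshold_above_max_gives_empty(self, tmp_path):
        rw, sites = self._rw3()
        n_intra, n_inter = export_network(
            rw, sites, 0.5, tmp_path / "i.sif", tmp_path / "e.sif")
        assert (n_intra, n_inter) == (0, 0)

    def test_roundtrip_preserves_weights(self, tmp_path):
        rw, sites = self._rw3()
        export_network(rw, sites, 0.0, tmp_path / "i.sif", tmp_path / "e.sif")
        back = read_network(tmp_path / "i.sif")
        assert back["rw"].tolist() == pytest.approx([0.28])


class TestNullExpectations:
    def test_intra_fraction_converges_to_pair_fraction(self):
        res = null_intra_fraction_study(seed=0, n_events=20_000)
        assert res["expected"] == pytest.approx(210 / 2775, abs=1e-12)
        assert abs(res["observed"] - res["expected"]) < 0.01

    def test_uniform_recombination_arr_classes_equal_in_expectation(self):
        """Under uniform recombination the partner-normalised intra and inter
        ARR have identical per-locus expectations.  The rank test is
        anticonservative here (per-locus values share pair counts, so the 75
        values per class are not independent), so the check is on the pooled
        means plus the absence of consistent rank separation, not on every
        seed clearing the nominal threshold."""
        res = arr_null_study(seeds=range(10))
        assert res["n_nonsig"] >= 5
        assert abs(res["pooled_mean_intra"] - res["pooled_mean_inter"]) \
            < 0.05 * res["pooled_mean_inter"]

    def test_observed_fraction_on_constructed_counts(self):
        sites = LoxSiteTable([LoxSite("a", "c1", 10), LoxSite("b", "c1", 500),
                              LoxSite("d", "c2", 10)])
        c = _counts({}, {("a", "b"): 3, ("a", "d"): 1})
        assert observed_intra_fraction(c, sites) == pytest.approx(0.75)
        assert intra_pair_fraction(sites) == pytest.approx(1 / 3)


class TestPValueOracles:
    """Fixed-input p-values cross-checked against independent implementations."""

    def test_mann_whitney_exact_vs_enumeration(self):
        a = [1.3, 2.1, 4.7, 5.5, 9.0]
        b = [0.4, 2.8, 3.3, 6.1, 7.2, 8.4]
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        # enumerate all assignments of ranks to group a
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        u_obs = sum(ranks[v] for v in a) - len(a) * (len(a) + 1) / 2
        n, m = len(a), len(b)
        us = []
        for combo in itertools.combinations(range(1, n + m + 1), n):
            us.append(sum(combo) - n * (n + 1) / 2)
        us = np.array(us)
        mu = n * m / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert res.pvalue == pytest.approx(p_exact, abs=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_t_test_and_wilcoxon_match_r(self):
        a = [0.12, 0.35, 0.29, 0.51, 0.44, 0.19, 0.60]
        b = [0.55, 0.72, 0.48, 0.90, 0.66, 0.81]
        tt = sps.ttest_ind(a, b, equal_var=True)
        mw = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        script = (
            f"a <- c({','.join(map(str, a))}); b <- c({','.join(map(str, b))});"
            "cat(sprintf('%.10f %.10f', t.test(a, b, var.equal=TRUE)$p.value,"
            " wilcox.test(a, b, exact=TRUE)$p.value))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        assert tt.pvalue == pytest.approx(float(out[0]), abs=1e-6)
        assert mw.pvalue == pytest.approx(float(out[1]), abs=1e-6)

    def test_regression_p_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.random(30)
        y = 2 * x + rng.normal(0, 0.3, 30)
        res = sps.linregress(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.pvalue == pytest.approx(ols.pvalues[1], abs=1e-6)
        assert res.rvalue ** 2 == pytest.approx(ols.rsquared, abs=1e-9)
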