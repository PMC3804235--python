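import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from btiscan.io_formats import RunConfig, SyncRecord
from btiscan.pooled_scan import (
    SnpRecord,
    detect_outliers,
    filter_sites,
    fisher_exact_site,
    pairwise_fst,
    pool_allele_freq,
    run_scan,
    storey_qvalues,
)


def sync(pos, pool1, pool2):
    """Site with counts given as dicts like {'A': 10, 'G': 2}."""
    order = "ATCG"
    def tup(d):
        return tuple(d.get(b, 0) for b in order) + (0, 0)
    return SyncRecord("sc1", pos, "A", (tup(pool1), tup(pool2)))


def snp(m1, c1, m2, c2):
    return SnpRecord("sc1", 1, "A", "G", (m1, m2), (c1, c2))


class TestFilters:
    def test_low_coverage_pool_excluded(self, cfg):
        rec = sync(1, {"A": 7, "G": 2}, {"A": 20, "G": 20})  # pool1 cov 9
        assert filter_sites([rec], cfg) == []

    def test_single_supporting_read_excluded(self, cfg):
        rec = sync(1, {"A": 99, "G": 1}, {"A": 100})
        assert filter_sites([rec], cfg) == []

    def test_overall_maf_below_one_percent_excluded(self, cfg):
        # minor allele at 1/200 = 0.5% overall even though it has >= 2 reads
        rec = sync(1, {"A": 99, "G": 2}, {"A": 300})
        # 2/401 < 1% -> excluded
        assert filter_sites([rec], cfg) == []

    def test_passing_site_retained_with_counts(self, cfg):
        rec = sync(5, {"A": 30, "G": 10}, {"A": 10, "G": 30})
        (s,) = filter_sites([rec], cfg)
        assert (s.major_allele, s.minor_allele) in {("A", "G"), ("G", "A")}
        assert s.pool_coverages == (40, 40)
        assert sum(s.pool_minor_counts) == 40

    def test_triallelic_dropped(self, cfg):
        rec = sync(1, {"A": 30, "G": 10, "T": 5}, {"A": 30, "G": 10, "T": 5})
        assert filter_sites([rec], cfg) == []

    def test_wrong_pool_count_rejected(self, cfg):
        rec = SyncRecord("sc1", 1, "A", ((10, 0, 0, 0, 0, 0),))
        with pytest.raises(ValueError, match="2 pools"):
            filter_sites([rec], cfg)


class TestAlleleFreq:
    @pytest.mark.parametrize(
        "minor,cov,expected", [(0, 10, 0.0), (10, 10, 1.0), (3, 12, 0.25)]
    )
    def test_exact_ratios(self, minor, cov, expected):
        assert pool_allele_freq(minor, cov) == expected

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            pool_allele_freq(0, 0)


def _fst_oracle(m1, c1, m2, c2):
    """Independent computation of the corrected heterozygosity Fst."""
    def pi(m, c):
        p = m / c
        return 2 * p * (1 - p) * c / (c - 1)
    pi_s = (pi(m1, c1) + pi(m2, c2)) / 2
    pi_t = pi(m1 + m2, c1 + c2)
    return 0.0 if pi_t == 0 else (pi_t - pi_s) / pi_t


class TestFst:
    def test_fixed_difference_is_one(self):
        # pool1 fixed for the major allele, pool2 fixed for the minor
        s = snp(0, 100, 120, 120)
        assert pairwise_fst(s) == 1.0

    def test_identical_frequencies_zero(self):
        assert pairwise_fst(snp(5, 20, 10, 40)) == 0.0

    def test_matches_hand_computed_heterozygosities(self):
        s = snp(2, 10, 8, 10)  # pool1 8A/2G, pool2 2A/8G
        assert pairwise_fst(s) == pytest.approx(_fst_oracle(2, 10, 8, 10))

    def test_symmetric_in_pools(self, rng):
        for _ in range(50):
            c1, c2 = rng.integers(2, 200, size=2)
            m1, m2 = rng.integers(0, c1 + 1), rng.integers(0, c2 + 1)
            a = pairwise_fst(snp(m1, c1, m2, c2))
            b = pairwise_fst(snp(m2, c2, m1, c1))
            assert a == pytest.approx(b)
            assert 0.0 <= a <= 1.0

    def test_low_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            pairwise_fst(snp(0, 1, 5, 10))


class TestFisher:
    def test_diagonal_table_closed_form(self):
        # [[10,0],[0,10]]: only the two extreme tables are as extreme
        p = fisher_exact_site(snp(10, 10, 0, 10))
        from math import comb
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-10)

    def test_identical_rows_p_one(self):
        assert fisher_exact_site(snp(5, 10, 5, 10)) == 1.0

    def test_matches_enumeration_for_random_small_tables(self, rng):
        for _ in range(200):
            c1, c2 = rng.integers(1, 13, size=2)
            m1, m2 = rng.integers(0, c1 + 1), rng.integers(0, c2 + 1)
            expected = _fisher_enumeration(m1, c1 - m1, m2, c2 - m2)
            assert fisher_exact_site(snp(m1, c1, m2, c2)) == pytest.approx(expected)


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities over all
    tables with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestStoreyQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(storey_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_reduces_to_bh_when_pi0_forced(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=1000)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_qvalues_at_most_bh_scale(self, rng):
        # pi0 <= 1 means Storey q never exceeds the BH value
        p = rng.uniform(size=400)
        assert np.all(storey_qvalues(p) <= storey_qvalues(p, pi0=1.0) + 1e-12)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestOutliers:
    def _make(self, fst, q):
        s = snp(1, 10, 2, 10)
        s.fst, s.qvalue, s.fisher_p = fst, q, q
        return s

    def test_rule_composition(self, cfg):
        # 12 SNPs above the 99th percentile; only 9 of them have q < 0.005
        rng = np.random.default_rng(0)
        snps = [self._make(f, 0.5) for f in rng.uniform(0.0, 0.5, size=988)]
        high_q = [0.001] * 9 + [0.5] * 3
        snps += [self._make(0.9, q) for q in high_q]
        res = detect_outliers(snps, cfg)
        assert sum(s.outlier for s in res.snps) == 9
        assert res.fst_threshold == pytest.approx(0.9)

    def test_degenerate_distribution_flags_nothing(self, cfg):
        snps = [self._make(0.3, 0.0001) for _ in range(100)]
        res = detect_outliers(snps, cfg)
        assert sum(s.outlier for s in res.snps) == 0

    def test_empty_rejected(self, cfg):
        with pytest.raises(ValueError):
            detect_outliers([], cfg)


class TestProperties:
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2, max_size=200,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_qvalues_bounded_and_order_preserving(self, p):
        q = storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(np.asarray(p), kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(
        st.integers(min_value=2, max_value=500),
        st.integers(min_value=2, max_value=500),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_fst_in_unit_interval_and_symmetric(self, c1, c2, f1, f2):
        m1, m2 = int(round(f1 * c1)), int(round(f2 * c2))
        a = pairwise_fst(snp(m1, c1, m2, c2))
        b = pairwise_fst(snp(m2, c2, m1, c1))
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b)


class TestRunScan:
    def test_pipeline_populates_everything(self, cfg):
        recs = [
            sync(i, {"A": 30, "G": 10}, {"A": 10, "G": 30}) for i in range(1, 60)
        ] + [sync(100, {"A": 40}, {"G": 40})]
        res = run_scan(recs, cfg)
        df = res.to_frame()
        assert len(df) == 60
        assert df[["fst", "fisher_p", "qvalue"]].notna().all().all()
        fixed = df[df.pos == 100].iloc[0]
        assert fixed.fst == 1.0
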