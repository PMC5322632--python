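"""Allele-permutation test: conservation, enumeration oracle, calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import varspectrum as vs
from varspectrum.permutation_engine import scope_rng

from conftest import make_cohort, make_site


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration over hypergeometric outcomes
# ---------------------------------------------------------------------------

def enumerate_null(site_counts, statistic, observed):
    """Exact P(stat > obs) and P(stat >= obs) by product enumeration.

    ``site_counts``: list of (case_alt, case_n, ctrl_alt, ctrl_n).  Each
    site's permuted case count follows hypergeom(M=case_n+ctrl_n,
    n=case_alt+ctrl_alt, N=case_n); sites are independent.  ``statistic``
    maps a tuple of per-site (case_alt', case_n, total_alt) to an integer.
    """
    supports = []
    for ca, cn, oa, on in site_counts:
        total, pool = ca + oa, cn + on
        lo, hi = max(0, total - (pool - cn)), min(cn, total)
        vals = list(range(lo, hi + 1))
        pmf = [hypergeom.pmf(v, pool, total, cn) for v in vals]
        supports.append(list(zip(vals, pmf)))
    p_gt = p_ge = 0.0
    for combo in itertools.product(*supports):
        prob = math.prod(p for _, p in combo)
        stat = statistic([
            (v, cn, ca + oa) for (v, _), (ca, cn, oa, on) in zip(combo, site_counts)])
        if stat > observed:
            p_gt += prob
        if stat >= observed:
            p_ge += prob
    return p_gt, p_ge


def spec_stat(per_site):
    return sum(1 for v, _, total in per_site if v >= 1 and total - v == 0)


def rare_stat(per_site, thr_num=1, thr_den=100):
    return sum(1 for v, n, _ in per_site
               if v >= 1 and thr_den * min(v, n - v) <= thr_num * n)


def _cohorts_from_counts(site_counts):
    sites = [make_site(pos=100 + i) for i in range(len(site_counts))]
    case = make_cohort("CASE", max(cn for _, cn, _, _ in site_counts) // 2 + 1, {
        s.key: (ca, cn) for s, (ca, cn, _, _) in zip(sites, site_counts)})
    ctrl = make_cohort("CTRL", max(on for _, _, _, on in site_counts) // 2 + 1, {
        s.key: (oa, on) for s, (_, _, oa, on) in zip(sites, site_counts)})
    return sites, case, ctrl


class TestPermuteSite:
    def test_singleton_splits_half_half(self, rng):
        # 1 alt among 8 pooled chromosomes, 4 drawn: P(case gets it) = 0.5
        draws = np.array([vs.permute_site(1, 4, 0, 4, rng)[0] for _ in range(20_000)])
        assert set(np.unique(draws)) <= {0, 1}
        se = math.sqrt(0.25 / draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_empty_and_fixed_pools_are_deterministic(self, rng):
        assert vs.permute_site(0, 6, 0, 8, rng) == (0, 0)
        assert vs.permute_site(4, 4, 4, 4, rng) == (4, 4)

    @given(st.tuples(st.integers(1, 30), st.integers(1, 30)).flatmap(
        lambda ns: st.tuples(st.integers(0, ns[0]), st.just(ns[0]),
                             st.integers(0, ns[1]), st.just(ns[1]))))
    def test_conservation_of_totals(self, counts):
        ca, cn, oa, on = counts
        rng = np.random.default_rng(7)
        for _ in range(5):
            ca2, oa2 = vs.permute_site(ca, cn, oa, on, rng)
            assert ca2 + oa2 == ca + oa
            assert 0 <= ca2 <= cn and 0 <= oa2 <= on


class TestPermutationTest:
    def test_two_case_singletons_exact_null(self):
        """Two sites, each a case singleton in 2+2 chromosomes.

        Each singleton stays on the case side with probability 1/2,
        independently: the permuted case-specific count is Binomial(2, 1/2),
        so P(> 2) = 0 and the add-one P(>= 2) estimate targets 1/4.
        """
        site_counts = [(1, 2, 0, 2), (1, 2, 0, 2)]
        sites, case, ctrl = _cohorts_from_counts(site_counts)
        res = vs.permutation_test(case, ctrl, sites, "case_specific_count",
                                  n_perm=100_000, seed=11)
        assert res.observed == 2
        assert res.p_strict == 0.0
        se = math.sqrt(0.25 * 0.75 / res.n_perm)
        assert abs(res.p_ge - 0.25) < 3 * se + 1 / res.n_perm

    @pytest.mark.parametrize("statistic, stat_fn", [
        ("case_specific_count", spec_stat), ("rare_count", rare_stat)])
    @pytest.mark.parametrize("site_counts", [
        [(1, 4, 0, 4)],
        [(1, 4, 1, 4), (2, 4, 0, 4)],
        [(1, 6, 0, 6), (3, 6, 2, 6), (0, 6, 1, 6)],
        [(2, 4, 1, 8), (1, 4, 0, 8)],
    ])
    def test_matches_exhaustive_enumeration(self, statistic, stat_fn, site_counts):
        """Small pooled panels: Monte-Carlo agrees with exact enumeration."""
        sites, case, ctrl = _cohorts_from_counts(site_counts)
        res = vs.permutation_test(case, ctrl, sites, statistic,
                                  n_perm=100_000, seed=23, threshold=0.25)
        def stat(per_site):
            return stat_fn(per_site, 1, 4) if stat_fn is rare_stat else stat_fn(per_site)
        p_gt, p_ge = enumerate_null(site_counts, stat, res.observed)
        se_gt = math.sqrt(max(p_gt * (1 - p_gt), 1e-12) / res.n_perm)
        se_ge = math.sqrt(max(p_ge * (1 - p_ge), 1e-12) / res.n_perm)
        assert abs(res.p_strict - p_gt) <= 3 * se_gt + 1e-9
        assert abs(res.n_exceeding_or_equal / res.n_perm - p_ge) <= 3 * se_ge + 1e-9

    def test_all_sites_fixed_is_degenerate(self):
        site_counts = [(4, 4, 4, 4), (4, 4, 4, 4)]
        sites, case, ctrl = _cohorts_from_counts(site_counts)
        res = vs.permutation_test(case, ctrl, sites, "rare_count", n_perm=100, seed=0)
        assert res.degenerate
        assert res.p_value == 1.0 and res.p_strict == 1.0

    def test_empty_scope_is_degenerate(self):
        sites, case, ctrl = _cohorts_from_counts([(1, 4, 0, 4)])
        res = vs.permutation_test(case, ctrl, sites, "rare_count",
                                  scope="NO_SUCH_GENE", n_perm=100, seed=0)
        assert res.degenerate and res.observed == 0 and res.p_value == 1.0

    def test_reproducible_and_order_independent(self):
        cfg = vs.SimConfig(seed=4)
        case, ctrl, sites, panel = vs.generate_cohort_pair(cfg)
        a = vs.permutation_test(case, ctrl, sites, "rare_count", "TLR2",
                                panel=panel, n_perm=2_000, seed=9)
        # analysing another gene first must not disturb TLR2's substream
        vs.permutation_test(case, ctrl, sites, "rare_count", "TLR5",
                            panel=panel, n_perm=2_000, seed=9)
        b = vs.permutation_test(case, ctrl, sites, "rare_count", "TLR2",
                                panel=panel, n_perm=2_000, seed=9)
        assert a == b

    def test_global_sum_equals_gene_sums(self):
        cfg = vs.SimConfig(seed=8)
        case, ctrl, sites, panel = vs.generate_cohort_pair(cfg)
        per_gene = [vs.permutation_test(case, ctrl, sites, "case_specific_count",
                                        g, panel=panel, n_perm=10, seed=1).observed
                    for g in panel.gene_names]
        total = vs.global_test(case, ctrl, sites, "case_specific_count",
                               panel.gene_names, panel=panel, n_perm=10, seed=1)
        assert total.observed == sum(per_gene)

    def test_replicates_conserve_chromosome_pools(self):
        """Permuted counts stay within each cohort's chromosome totals."""
        site_counts = [(3, 6, 5, 10), (1, 6, 0, 10)]
        sites, case, ctrl = _cohorts_from_counts(site_counts)
        rng = scope_rng(3, "ALL")
        for _ in range(500):
            for ca, cn, oa, on in site_counts:
                ca2, oa2 = vs.permute_site(ca, cn, oa, on, rng)
                assert ca2 + oa2 == ca + oa
                assert 0 <= ca2 <= cn and 0 <= oa2 <= on


class TestBonferroni:
    def test_adjustment_and_cap(self):
        assert vs.bonferroni([0.00009, 0.03, 1.0], 20) == \
            pytest.approx([0.0018, 0.6, 1.0])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            vs.bonferroni([1.5], 20)
        with pytest.raises(ValueError):
            vs.bonferroni([0.5], 0)


@settings(max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_strict_p_never_exceeds_tie_counting_p(seed):
    site_counts = [(1, 4, 1, 4), (2, 4, 0, 4)]
    sites, case, ctrl = _cohorts_from_counts(site_counts)
    res = vs.permutation_test(case, ctrl, sites, "case_specific_count",
                              n_perm=200, seed=seed)
    assert res.n_exceeding <= res.n_exceeding_or_equal
    assert 0.0 <= res.p_strict <= 1.0 and 0.0 < res.p_ge <= 1.0
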