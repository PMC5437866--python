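"""Acceptance rules, bootstrap combination, and the confusion calculus."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surveyerr import records_io as rio
from surveyerr import survey_combiner as sc
from surveyerr.errors import DomainError, IntegrityError

from conftest import make_survey

ALL = sc.AcceptanceRule("all_of_k")
AT2 = sc.AcceptanceRule("at_least_m_of_k", 2)
UNION = sc.AcceptanceRule("union")


@pytest.fixture()
def three_surveys():
    return [
        make_survey("s", "v1", tp=["A a", "B b", "C c"]),
        make_survey("s", "v2", tp=["A a", "B b"]),
        make_survey("s", "v3", tp=["A a"], fp=["D d"]),
    ]


class TestRules:
    def test_rule_examples(self, three_surveys):
        assert sc.combine(three_surveys, ALL) == {"A a"}
        assert sc.combine(three_surveys, AT2) == {"A a", "B b"}
        assert sc.combine(three_surveys, UNION) == {"A a", "B b", "C c", "D d"}

    def test_cautious_records_never_count(self):
        surveys = [
            make_survey("s", "v1", tp=["A a"], cautious=["Carex"]),
            make_survey("s", "v2", cautious=["Carex"]),
        ]
        assert sc.combine(surveys, UNION) == {"A a"}

    def test_m_exceeding_k_rejected(self, three_surveys):
        with pytest.raises(DomainError):
            sc.combine(three_surveys[:1], AT2)

    def test_mixed_sites_rejected(self):
        surveys = [make_survey("s1", "v1", tp=["A a"]), make_survey("s2", "v2", tp=["A a"])]
        with pytest.raises(DomainError):
            sc.combine(surveys, UNION)

    def test_rule_parsing(self):
        assert sc.AcceptanceRule.parse("all") == ALL
        assert sc.AcceptanceRule.parse("atleast:2") == AT2
        assert sc.AcceptanceRule.parse("union") == UNION

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_rule_nesting_chain(self, data):
        """all_of_k accepted set is a subset of at_least_m, itself a subset
        of union, for any random survey collection."""
        pool = [f"S p{i}" for i in range(8)]
        k = data.draw(st.integers(2, 4))
        surveys = [
            make_survey("s", f"v{i}", tp=data.draw(st.lists(st.sampled_from(pool), unique=True)))
            for i in range(k)
        ]
        m = data.draw(st.integers(1, k))
        strict = sc.combine(surveys, ALL)
        mid = sc.combine(surveys, sc.AcceptanceRule("at_least_m_of_k", m))
        loose = sc.combine(surveys, UNION)
        assert strict <= mid <= loose


class TestBootstrap:
    def test_k1_equals_per_survey_average(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a", "B b", "C c"}), frozenset({"D d"}))
        res = sc.bootstrap_combination(three_surveys, ref, 1, ALL, 4000, seed=1)
        exact_tp, exact_fp, exact_fn = sc.exact_combination_means(three_surveys, ref, 1, ALL)
        assert exact_tp == pytest.approx((3 + 2 + 1) / 3)
        assert exact_fp == pytest.approx(1 / 3)
        # Monte-Carlo agreement at 3 SE
        assert abs(res.mean_fp - exact_fp) < 3 * 0.5 / np.sqrt(4000)
        assert res.mean_tp + res.mean_fn == pytest.approx(3.0)

    def test_pairs_match_exhaustive_enumeration(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a", "B b", "C c"}), frozenset({"D d"}))
        exact = sc.exact_combination_means(three_surveys, ref, 2, ALL)
        res = sc.bootstrap_combination(three_surveys, ref, 2, ALL, 10_000, seed=2)
        for got, want in zip((res.mean_tp, res.mean_fp, res.mean_fn), exact):
            assert abs(got - want) < 3 * 1.0 / np.sqrt(10_000) + 1e-9

    def test_bit_reproducible_given_seed(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a"}))
        a = sc.bootstrap_combination(three_surveys, ref, 2, AT2, 500, seed=7)
        b = sc.bootstrap_combination(three_surveys, ref, 2, AT2, 500, seed=7)
        assert (a.mean_tp, a.mean_fp, a.mean_fn) == (b.mean_tp, b.mean_fp, b.mean_fn)

    def test_k_exceeding_pool_rejected(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a"}))
        with pytest.raises(DomainError):
            sc.bootstrap_combination(three_surveys, ref, 4, ALL, 10, seed=0)

    def test_independent_fp_draws_rarely_collide(self):
        """Observers drawing FP species independently from a large pool:
        requiring agreement of two surveys nearly eliminates false
        positives (collision probability ~ f^2/pool)."""
        rng = np.random.default_rng(0)
        pool = [f"Gen{i:04d} sp" for i in range(1000)]
        surveys = [
            make_survey("s", f"v{i}", fp=list(rng.choice(pool, size=3, replace=False)))
            for i in range(20)
        ]
        ref = rio.SiteReference("s", frozenset(), frozenset().union(*[s.species_set() for s in surveys]))
        r1 = sc.bootstrap_combination(surveys, ref, 1, ALL, 3000, seed=1)
        r2 = sc.bootstrap_combination(surveys, ref, 2, ALL, 3000, seed=1)
        assert r1.mean_fp == pytest.approx(3.0)
        assert r2.mean_fp < 0.05 * r1.mean_fp


class TestConfusion:
    def test_sensitivity_definition(self):
        conf = sc.ConfusionSummary(tp=80, fp=0, fn=20, tn=10)
        assert conf.sensitivity == pytest.approx(0.80)

    def test_true_negative_pool_arithmetic(self):
        """A realistic cumulative FP pool of 86 species with a mean of 3
        false positives per combination leaves 83 true negatives."""
        ref = rio.SiteReference("s", frozenset({"A a"}), frozenset(f"F p{i}" for i in range(86)))
        res = sc.CombinationResult("s", 2, ALL, 100, 0, mean_tp=1.0, mean_fp=3.0, mean_fn=0.0)
        conf = sc.confusion(res, ref)
        assert conf.tn == pytest.approx(83.0)
        assert conf.specificity == pytest.approx(83 / 86)

    def test_zero_fp_gives_perfect_specificity(self):
        ref = rio.SiteReference("s", frozenset({"A a"}), frozenset({"F p"}))
        res = sc.CombinationResult("s", 1, ALL, 100, 0, mean_tp=1.0, mean_fp=0.0, mean_fn=0.0)
        assert sc.confusion(res, ref).specificity == pytest.approx(1.0)

    def test_fp_exceeding_pool_is_an_integrity_error(self):
        ref = rio.SiteReference("s", frozenset({"A a"}), frozenset({"F p"}))
        res = sc.CombinationResult("s", 1, ALL, 100, 0, mean_tp=1.0, mean_fp=2.0, mean_fn=0.0)
        with pytest.raises(IntegrityError):
            sc.confusion(res, ref)


class TestSweep:
    def test_sweep_is_tidy_and_reproducible(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a", "B b", "C c"}), frozenset({"D d"}))
        t1 = sc.threshold_sweep(three_surveys, ref, range(1, 4), [ALL, AT2, UNION], 400, seed=3)
        t2 = sc.threshold_sweep(three_surveys, ref, range(1, 4), [ALL, AT2, UNION], 400, seed=3)
        assert t1.equals(t2)
        assert set(t1.columns) == {
            "site_id", "k", "rule", "mean_tp", "mean_fp", "mean_fn",
            "tn", "sensitivity", "specificity",
        }
        # atleast:2 is undefined at k=1 and therefore absent
        assert not ((t1.k == 1) & (t1.rule == "atleast:2")).any()

    def test_all_of_k_fp_non_increasing_and_union_monotone(self, three_surveys):
        ref = rio.SiteReference("s", frozenset({"A a", "B b", "C c"}), frozenset({"D d"}))
        t = sc.threshold_sweep(three_surveys, ref, range(1, 4), [ALL, UNION], 2000, seed=5)
        fp_all = t[t.rule == "all"].sort_values("k")["mean_fp"].to_numpy()
        assert np.all(np.diff(fp_all) <= 1e-9)
        sens_union = t[t.rule == "union"].sort_values("k")["sensitivity"].to_numpy()
        spec_union = t[t.rule == "union"].sort_values("k")["specificity"].to_numpy()
        assert np.all(np.diff(sens_union) >= -1e-9)
        assert np.all(np.diff(spec_union) <= 1e-9)
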