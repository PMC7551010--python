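"""Median operator, entropy-linked similarity, index scores and rankings."""

import pytest
from hypothesis import given
import hypothesis.strategies as st

from ivifmea import (
    IVIFNumber,
    compare_rankings,
    element_similarity,
    entropy,
    index_table,
    median_operator,
    similarity,
)
from ivifmea.pipeline import (
    load_reference_index_table,
    load_reference_rank_comparison,
)
from ivifmea.scales import builtin_scales
from ivifmea.scoring import RiskProfile

from conftest import ivif_numbers

A = IVIFNumber(0.1, 0.2, 0.5, 0.6)
B = IVIFNumber(0.2, 0.3, 0.5, 0.6)


class TestMedianOperator:
    def test_worked_pair(self):
        m = median_operator(A, B)
        assert m.as_tuple() == pytest.approx((0.35, 0.45, 0.3, 0.4), abs=1e-12)

    def test_identical_certain_pair_is_maximally_vague(self):
        x = IVIFNumber(0.4, 0.4, 0.6, 0.6)  # zero hesitation
        assert median_operator(x, x).as_tuple() == pytest.approx(
            (0.5, 0.5, 0.5, 0.5), abs=1e-12
        )

    @given(x=ivif_numbers(), y=ivif_numbers())
    def test_symmetry(self, x, y):
        # some extreme pairs push M outside the IVIF domain, which raises;
        # the failure itself must then be symmetric too
        try:
            m_xy = median_operator(x, y)
        except ValueError:
            with pytest.raises(ValueError):
                median_operator(y, x)
            return
        assert m_xy.isclose(median_operator(y, x), abs_tol=1e-12)

    def test_out_of_domain_pair_raises_computation_error(self):
        # (0,0;0,1) vs (0,1;0,0) yields M = (0,1;0,0.5), mu_hi + nu_hi > 1
        with pytest.raises(ValueError, match="median operator"):
            median_operator(IVIFNumber(0, 0, 0, 1), IVIFNumber(0, 1, 0, 0))


class TestSimilarity:
    def test_worked_pair_both_routes(self):
        s = similarity(A, B)
        assert s == pytest.approx(4.8 / 5.2, abs=1e-12)
        assert round(s, 2) == 0.92
        # the entropy of the median must give the identical value (1.2/1.3)
        assert entropy(median_operator(A, B)) == pytest.approx(s, abs=1e-12)

    @given(data=st.data())
    def test_entropy_of_median_equals_direct_formula_on_shared_nu(self, data):
        # the two routes coincide exactly when the pair shares its
        # non-membership interval, as in the defining worked example
        x = data.draw(ivif_numbers())
        b2 = data.draw(st.floats(0.0, 1.0 - x.nu_hi))
        a2 = data.draw(st.floats(0.0, b2))
        y = IVIFNumber(a2, b2, x.nu_lo, x.nu_hi)
        assert entropy(median_operator(x, y)) == pytest.approx(
            similarity(x, y), abs=1e-12
        )

    def test_routes_diverge_when_nonmembership_differs(self):
        # with unequal non-membership bounds the dv terms enter the two
        # denominators with opposite signs; the direct form is the one
        # that reproduces the published index scores
        x, y = IVIFNumber(0.2, 0.3, 0.1, 0.2), IVIFNumber(0.2, 0.3, 0.3, 0.5)
        assert entropy(median_operator(x, y)) != pytest.approx(
            similarity(x, y), abs=1e-6
        )

    @given(x=ivif_numbers(), y=ivif_numbers())
    def test_axiom_range_and_symmetry(self, x, y):
        s = similarity(x, y)
        assert 0.0 <= s <= 1.0  # P1
        assert s == similarity(y, x)  # P3

    @given(x=ivif_numbers())
    def test_axiom_self_similarity(self, x):
        assert similarity(x, x) == pytest.approx(1.0, abs=1e-12)  # P2

    @given(data=st.data())
    def test_axiom_triangle_on_nested_triples(self, data):
        # construct A <= B <= C componentwise (rising membership, falling
        # non-membership) and check S(A,C) <= min(S(A,B), S(B,C))
        a = data.draw(ivif_numbers())
        b_hi = data.draw(st.floats(a.mu_hi, 1.0 - a.nu_hi))
        b = IVIFNumber(
            data.draw(st.floats(a.mu_lo, b_hi)),
            b_hi,
            data.draw(st.floats(0.0, min(a.nu_lo, 1.0 - b_hi))),
            min(a.nu_hi, 1.0 - b_hi),
        )
        c_hi = data.draw(st.floats(b.mu_hi, 1.0 - b.nu_hi))
        c = IVIFNumber(
            data.draw(st.floats(b.mu_lo, c_hi)),
            c_hi,
            data.draw(st.floats(0.0, min(b.nu_lo, 1.0 - c_hi))),
            min(b.nu_hi, 1.0 - c_hi),
        )
        s_ac = similarity(a, c)
        assert s_ac <= similarity(a, b) + 1e-12
        assert s_ac <= similarity(b, c) + 1e-12

    def test_reference_scores_from_published_pairs(self):
        ref = load_reference_index_table()
        for code, expected in (("L18", 0.638), ("ts", 0.723)):
            row = ref.loc[code]
            s = similarity(
                IVIFNumber(row.rpn_mu_lo, row.rpn_mu_hi, row.rpn_nu_lo, row.rpn_nu_hi),
                IVIFNumber(
                    row.ideal_mu_lo, row.ideal_mu_hi, row.ideal_nu_lo, row.ideal_nu_hi
                ),
            )
            assert s == pytest.approx(expected, abs=1e-3)


class TestElementSimilarity:
    def test_mean_over_pairs(self):
        s1, s2 = similarity(A, B), 0.638
        pair2 = (
            IVIFNumber(0.532, 0.657, 0.179, 0.343),
            IVIFNumber(0.0, 0.446, 0.323, 0.554),
        )
        got = element_similarity([(A, B), pair2])
        assert got == pytest.approx((s1 + similarity(*pair2)) / 2, abs=1e-12)
        assert got == pytest.approx((0.92 + s2) / 2, abs=2e-3)

    def test_single_pair(self):
        assert element_similarity([(A, B)]) == similarity(A, B)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            element_similarity([])


class TestIndexTable:
    def test_case_study_priorities(self, case_profiles, case_weights):
        rows = {r.error_code: r for r in index_table(case_profiles, case_weights)}
        assert rows["L17"].rank == 1  # least similar to its ideal case
        assert rows["L18"].rank == 2
        assert rows["ts"].rank == 18
        assert rows["ts"].index_score == pytest.approx(0.723, abs=1e-3)

    def test_all_rare_degenerates_to_tie_break_order(self, case_weights):
        rare = builtin_scales()["occurrence"].lookup("Rare")
        x = IVIFNumber(0.5, 0.6, 0.2, 0.3)
        profiles = [
            RiskProfile(code, x, x, rare) for code in ("b", "a", "c")
        ]
        rows = {r.error_code: r for r in index_table(profiles, case_weights)}
        scores = {c: r.index_score for c, r in rows.items()}
        assert len(set(scores.values())) == 1  # identical self-similarity
        assert [rows[c].rank for c in ("a", "b", "c")] == [1, 2, 3]

    def test_missing_occurrence_is_refused(self, case_weights):
        p = RiskProfile("x", A, B)
        with pytest.raises(ValueError, match="importance"):
            index_table([p], case_weights)


class TestCompareRankings:
    def test_reference_comparison(self):
        ref = load_reference_rank_comparison()
        cmp = compare_rankings(
            ref["reported_count_rank"].to_dict(),
            ref["index_rank"].to_dict(),
            threshold=5,
        )
        # prioritizing by severity/preventability/occurrence instead of raw
        # counts promotes patient misidentification (TKHa) from 15 to 7
        assert cmp.table.loc["TKHa", "rank_a"] == 15
        assert cmp.table.loc["TKHa", "rank_b"] == 7
        assert "TKHa" in cmp.movers
        assert 0 < cmp.spearman < 1
        assert 0 < cmp.kendall < 1

    def test_identical_rankings(self):
        r = {"a": 1, "b": 2, "c": 3}
        cmp = compare_rankings(r, dict(r))
        assert cmp.spearman == pytest.approx(1.0)
        assert cmp.kendall == pytest.approx(1.0)
        assert cmp.movers == ()

    def test_reversed_ranking(self):
        cmp = compare_rankings({"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1})
        assert cmp.spearman == pytest.approx(-1.0)

    def test_mismatched_sets(self):
        with pytest.raises(KeyError, match="different errors"):
            compare_rankings({"a": 1}, {"b": 1})
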