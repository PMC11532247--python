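"""Index formulas against hand arithmetic and a brute-force enumeration oracle."""

import math

import pytest
from hypothesis import given

from conftest import make_survey, oracle_index_table, small_survey_triples
from ethnosurvey.exceptions import DomainError
from ethnosurvey.indices import (
    RoundingPolicy,
    cii,
    compute_index_table,
    cvi,
    index_table_to_frame,
    relative_importance,
    rfc,
    round_decimal,
    truncate_decimal,
    use_value,
)
from ethnosurvey.use_reports import fc_counts


class TestScalarOperations:
    def test_use_value_hand_sum(self):
        # informants report 2, 1 and 0 uses -> (2+1+0)/3
        survey = make_survey(
            [("A", "sp", "c1"), ("A", "sp", "c2"), ("B", "sp", "c1")],
            informants=["A", "B", "C"],
        )
        assert use_value(survey, "sp") == pytest.approx(1.0)

    def test_use_value_uncited_is_zero(self, toy_survey):
        assert use_value(toy_survey, "Neem") == 0.0

    def test_rfc_exact_rational(self):
        assert rfc(68, 145) == 68 / 145
        assert truncate_decimal(rfc(68, 145), 3) == 0.468

    @pytest.mark.parametrize(("fc", "n"), [(5, 4), (-1, 10), (1, 0)])
    def test_rfc_domain_errors(self, fc, n):
        with pytest.raises(DomainError):
            rfc(fc, n)

    def test_rfc_edges(self):
        assert rfc(0, 7) == 0.0
        assert rfc(7, 7) == 1.0

    def test_relative_importance_conventions(self):
        # top species under the normalized convention scores exactly 1
        assert relative_importance(0.5, 4, 0.5, 4, "normalized") == 1.0
        assert relative_importance(0.5, 2, 0.5, 4, "raw_rfc") == pytest.approx(0.5)
        assert relative_importance(0.25, 4, 0.5, 4, "normalized") == pytest.approx(0.75)

    def test_relative_importance_errors(self):
        with pytest.raises(DomainError):
            relative_importance(0.1, 1, 0.0, 4)
        with pytest.raises(DomainError):
            relative_importance(0.1, 5, 0.5, 4)

    def test_cii_hand_sum(self):
        # informant1 in 2 categories, informant2 in 1 -> 3/2
        survey = make_survey(
            [("A", "sp", "c1"), ("A", "sp", "c2"), ("B", "sp", "c1")],
            informants=["A", "B"],
        )
        assert cii(survey, "sp") == pytest.approx(1.5)

    def test_cii_full_saturation_equals_nc(self):
        survey = make_survey(
            [(i, "sp", c) for i in ("A", "B") for c in ("c1", "c2", "c3")]
        )
        assert cii(survey, "sp") == survey.n_categories == 3

    def test_cvi_hand_arithmetic(self):
        assert cvi(2, 4, 1, 2, 1.5) == pytest.approx(0.375)
        assert cvi(0, 4, 1, 2, 1.5) == 0.0
        assert cvi(4, 4, 2, 2, 1.5) == pytest.approx(1.5)  # both factors 1 -> CVI = CII

    def test_cvi_domain_errors(self):
        with pytest.raises(DomainError):
            cvi(1, 0, 1, 2, 1.0)
        with pytest.raises(DomainError):
            cvi(5, 4, 1, 2, 1.0)


class TestFormatting:
    @pytest.mark.parametrize(
        ("x", "places", "expected"),
        [
            (0.46896, 3, 0.468),
            (0.4206, 2, 0.42),
            (0.42, 3, 0.42),  # already short: unchanged
            (0.9999, 3, 0.999),
            (-0.4567, 2, -0.45),  # toward zero
        ],
    )
    def test_truncate(self, x, places, expected):
        assert truncate_decimal(x, places) == expected

    def test_round_half_up(self):
        assert round_decimal(1.1636, 3) == 1.164
        assert round_decimal(2.0332, 3) == 2.033

    def test_negative_places_rejected(self):
        with pytest.raises(DomainError):
            truncate_decimal(0.5, -1)

    def test_policy_binding(self):
        assert RoundingPolicy("truncate", 3).apply(0.46896) == 0.468
        assert RoundingPolicy("round", 3).apply(0.46896) == 0.469


class TestIndexTable:
    def test_two_species_toy_matches_hand_values(self, toy_survey):
        # Aloe vera: fc=2, nu=2, 3 reports; Centella: fc=1, nu=1, 1 report; N=2, NC=2
        rows = {row.species_id: row for row in compute_index_table(toy_survey)}
        aloe, centella = rows["Aloe vera"], rows["Centella asiatica"]
        assert (aloe.fc, aloe.nu) == (2, 2)
        assert aloe.uv == aloe.cii == pytest.approx(1.5)
        assert aloe.rfc == 1.0
        assert aloe.ri == pytest.approx((1.0 + 1.0) / 2)
        assert aloe.cvi == pytest.approx((2 / 2) * (2 / 2) * 1.5)
        assert centella.rfc == 0.5
        assert centella.ri == pytest.approx((0.5 + 0.5) / 2)
        assert centella.cvi == pytest.approx((1 / 2) * (1 / 2) * 0.5)
        assert (aloe.rank_rfc, centella.rank_rfc) == (1, 2)

    def test_single_species_cited_by_all_ranks_first(self):
        survey = make_survey([(f"i{k}", "sp", "c1") for k in range(5)])
        (row,) = compute_index_table(survey)
        assert row.rank_rfc == row.rank_ri == row.rank_cii == row.rank_cvi == 1

    def test_empty_survey_yields_empty_table(self):
        from ethnosurvey.use_reports import Survey

        assert compute_index_table(Survey(("A",), ("c1",), ())) == []

    def test_ties_share_minimum_rank(self):
        survey = make_survey(
            [("A", "sp_a", "c1"), ("A", "sp_b", "c1"), ("A", "sp_c", "c1"), ("B", "sp_c", "c1")]
        )
        rows = {row.species_id: row for row in compute_index_table(survey)}
        assert rows["sp_c"].rank_rfc == 1
        assert rows["sp_a"].rank_rfc == rows["sp_b"].rank_rfc == 2

    @given(small_survey_triples)
    def test_matches_bruteforce_oracle(self, triples):
        survey = make_survey(triples)
        expected = oracle_index_table(
            [(r.informant_id, r.species_id, r.use_category) for r in survey.reports],
            survey.n_informants,
            survey.n_categories,
        )
        rows = compute_index_table(survey)
        assert {r.species_id for r in rows} == set(expected)
        for row in rows:
            want = expected[row.species_id]
            for key in ("fc", "nu", "rank_rfc", "rank_ri", "rank_cii", "rank_cvi"):
                assert getattr(row, key) == want[key], (row.species_id, key)
            for key in ("uv", "rfc", "rnu", "ri", "cii", "cvi"):
                assert getattr(row, key) == pytest.approx(want[key], abs=1e-12)

    @given(small_survey_triples)
    def test_invariants(self, triples):
        survey = make_survey(triples)
        rows = compute_index_table(survey)
        fcs = fc_counts(survey)
        by_fc = sorted(rows, key=lambda r: -r.fc)
        for row in rows:
            assert row.uv == pytest.approx(row.cii)  # UV and CII coincide
            assert row.rfc <= row.uv + 1e-12
            assert row.cvi <= row.cii + 1e-12
            assert row.cii <= survey.n_categories + 1e-12
            assert 0 < row.ri <= 1.0 + 1e-12
        # RFC ranking is the FC ranking (monotone transform)
        for row in rows:
            fc_rank = 1 + sum(1 for other in rows if other.fc > row.fc)
            assert row.rank_rfc == fc_rank

    def test_formatted_frame_columns(self, toy_survey):
        frame = index_table_to_frame(
            compute_index_table(toy_survey), RoundingPolicy("truncate", 3)
        )
        assert {"rfc_fmt", "ri_fmt", "cii_fmt", "cvi_fmt"} <= set(frame.columns)
        assert (frame["rfc_fmt"] <= frame["rfc"] + 1e-12).all()
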