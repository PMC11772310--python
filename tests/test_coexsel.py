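"""Selection-cascade tests: each stage against its stated rule, the composed
cascades against a hand-worked fixture, and the algebraic properties of the
correlation measure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import pearson_brute
from conftest import make_hit_table
from lupin_miner.coexsel import (
    CandidateReport,
    ExpressionMatrix,
    SelectionConfig,
    coexpression_candidates,
    cultivar_ratio_filter,
    filter_min_expression,
    keyword_filter,
    pcc,
    select_dehydrogenase_candidates,
    select_oxidase_candidates,
    specificity_classify,
)
from lupin_miner.errors import ConfigError, ZeroVarianceError


class TestMinExpressionFilter:
    @pytest.fixture
    def tiny(self):
        values = pd.DataFrame({"s1": [9.99, 10.0, 500.0]}, index=["g1", "g2", "g3"])
        meta = pd.DataFrame(
            {"sample": ["s1"], "cultivar": ["Oskar"], "organ": ["young_leaf"]}
        ).set_index("sample")
        return ExpressionMatrix(values=values, meta=meta).validate()

    def test_boundary_retained(self, tiny):
        assert filter_min_expression(tiny, "s1", 10.0) == {"g2", "g3"}

    def test_floor_zero_keeps_all(self, tiny):
        assert filter_min_expression(tiny, "s1", 0.0) == {"g1", "g2", "g3"}

    def test_floor_above_max_empties(self, tiny):
        assert filter_min_expression(tiny, "s1", 1000.0) == set()

    def test_unknown_sample(self, tiny):
        with pytest.raises(KeyError):
            filter_min_expression(tiny, "nope", 10.0)


class TestPcc:
    def test_self_correlation(self):
        assert pcc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        x, y = [1, 2, 3, 5], [2, 2, 4, 5]
        assert abs(pcc(x, y) - pearson_brute(x, y)) < 1e-12

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pcc([1, 1, 1], [1, 2, 3])

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_positive_affine_invariance(self, data):
        n = data.draw(st.integers(3, 12))
        floats = st.floats(-100, 100, allow_nan=False)
        x = data.draw(st.lists(floats, min_size=n, max_size=n))
        y = data.draw(st.lists(floats, min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        a = data.draw(st.floats(0.1, 10))
        b = data.draw(st.floats(-50, 50))
        r = pcc(x, y)
        assert -1.0 <= r <= 1.0
        assert pcc(y, x) == pytest.approx(r, abs=1e-12)
        assert pcc([a * v + b for v in x], y) == pytest.approx(r, abs=1e-9)


class TestCoexpressionCandidates:
    @pytest.fixture
    def matrix(self):
        samples = ["s1", "s2", "s3", "s4"]
        values = pd.DataFrame(
            {
                "bait": [10.0, 20.0, 30.0, 40.0],
                "dup": [20.0, 40.0, 60.0, 80.0],
                "anti": [40.0, 30.0, 20.0, 10.0],
                "flatline": [5.0, 5.0, 5.0, 5.0],
            }
        ).T
        values.columns = samples
        meta = pd.DataFrame(
            {
                "sample": samples,
                "cultivar": ["Oskar"] * 4,
                "organ": ["a", "b", "c", "d"],
            }
        ).set_index("sample")
        return ExpressionMatrix(values=values, meta=meta).validate()

    def test_duplicate_profile_scores_one(self, matrix):
        out = coexpression_candidates(matrix, "bait", matrix.samples, 0.9)
        assert [tid for tid, _ in out] == ["dup"]
        assert out[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_strict_threshold_at_one_empties(self, matrix):
        # pcc_min = 1.0 is strict: even an exact duplicate (r = 1.0) fails "> 1.0"
        assert coexpression_candidates(matrix, "bait", matrix.samples, 1.0) == []

    def test_bait_excluded_and_zero_variance_dropped(self, matrix):
        out = coexpression_candidates(matrix, "bait", matrix.samples, -2.0)
        ids = [tid for tid, _ in out]
        assert "bait" not in ids and "flatline" not in ids
        assert ids == ["dup", "anti"]  # sorted by descending PCC

    def test_missing_bait(self, matrix):
        with pytest.raises(KeyError):
            coexpression_candidates(matrix, "nope", matrix.samples, 0.9)


class TestSpecificityClassify:
    def test_boundary_ten_or_more(self):
        table = make_hit_table("q", [65.0] * 10 + [85.0] * 20)
        assert specificity_classify(table, 30, 70.0, 10) == ("specific", 10)

    def test_conserved_gene(self):
        table = make_hit_table("q", [95.0] * 30)
        assert specificity_classify(table, 30, 70.0, 10) == ("general", 0)

    def test_window_ignores_hits_past_thirty(self):
        # 9 qualifying hits inside the first-30 window; 10 more past it
        pidents = [50.0] * 9 + [90.0] * 21 + [50.0] * 10
        table = make_hit_table("q", pidents)
        assert specificity_classify(table, 30, 70.0, 10) == ("general", 9)

    def test_no_hits_is_specific(self):
        assert specificity_classify(None, 30, 70.0, 10) == ("specific", 0)
        assert specificity_classify(make_hit_table("q", []), 30, 70.0, 10) == (
            "specific",
            0,
        )


class TestKeywordFilter:
    def test_substring_match(self):
        out = keyword_filter(
            {"t1": "cytochrome P450 71D"}, ["t1"], ["cytochrome P450", "oxidase"]
        )
        assert out == {"t1": "cytochrome P450"}

    @pytest.mark.parametrize(
        "desc",
        [
            "(−)-isopiperitenol/(−)-carveol dehydrogenase",
            "NAD(P)H dehydrogenase complex subunit CRR3",
        ],
    )
    def test_dehydrogenase_annotations_match(self, desc):
        assert keyword_filter({"t": desc}, ["t"], ["dehydrogenase"]) == {
            "t": "dehydrogenase"
        }

    def test_missing_annotation_is_nonmatch(self):
        assert keyword_filter({}, ["t"], ["oxidase"]) == {}

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ConfigError):
            keyword_filter({"t": "x"}, ["t"], [])


class TestCultivarRatioFilter:
    def _matrix(self, oskar_leaf, tanjil_leaf):
        samples = ["O_leaf", "T_leaf"]
        values = pd.DataFrame({"O_leaf": [oskar_leaf], "T_leaf": [tanjil_leaf]}, index=["g"])
        meta = pd.DataFrame(
            {
                "sample": samples,
                "cultivar": ["Oskar", "Tanjil"],
                "organ": ["young_leaf", "young_leaf"],
            }
        ).set_index("sample")
        return ExpressionMatrix(values=values, meta=meta).validate()

    @pytest.mark.parametrize(
        "oskar, tanjil, survives",
        [
            (50.0, 5.0, True),  # bitter-enriched: ratio 0.1
            (5.0, 50.0, False),  # sweet-enriched: ratio 10
            (20.0, 20.0, True),  # ratio exactly 1: rule removes only > 1
            (0.0, 0.0, True),  # 0/0 treated as ratio 0
            (0.0, 3.0, False),  # positive over zero: removed
        ],
    )
    def test_rule(self, oskar, tanjil, survives):
        m = self._matrix(oskar, tanjil)
        out = cultivar_ratio_filter(m, ["g"], "young_leaf", "Oskar", "Tanjil")
        assert ("g" in out) is survives

    def test_missing_organ_rejected(self):
        m = self._matrix(1.0, 1.0)
        with pytest.raises(ConfigError):
            cultivar_ratio_filter(m, ["g"], "pod", "Oskar", "Tanjil")


class TestCascades:
    def test_oxidase_cascade_on_hand_fixture(self, small_fixture):
        matrix, tables, annotations, cfg = small_fixture
        report = select_oxidase_candidates(matrix, tables, annotations, cfg)
        assert report.candidate_ids == ["OX1"]
        counts = [n for _, n in report.stage_counts]
        assert counts == sorted(counts, reverse=True)

    def test_dehydrogenase_cascade_on_hand_fixture(self, small_fixture):
        matrix, tables, annotations, cfg = small_fixture
        report = select_dehydrogenase_candidates(matrix, tables, annotations, cfg)
        assert report.candidate_ids == ["SDR"]
        counts = [n for _, n in report.stage_counts]
        assert counts == sorted(counts, reverse=True)

    def test_empty_matrix_gives_zero_report(self):
        values = pd.DataFrame(columns=["s1"], dtype=float)
        meta = pd.DataFrame(
            {"sample": ["s1"], "cultivar": ["Oskar"], "organ": ["young_leaf"]}
        ).set_index("sample")
        matrix = ExpressionMatrix(values=values, meta=meta).validate()
        cfg = SelectionConfig(reference_sample="s1")
        for fn in (select_oxidase_candidates, select_dehydrogenase_candidates):
            report = fn(matrix, {}, {}, cfg)
            assert report.candidates == []
            assert all(n == 0 for _, n in report.stage_counts)

    def test_stricter_pcc_yields_subset(self, small_fixture):
        matrix, tables, annotations, cfg = small_fixture
        base = set(
            select_oxidase_candidates(matrix, tables, annotations, cfg).candidate_ids
        )
        strict_cfg = SelectionConfig(pcc_min=0.99)
        strict = set(
            select_oxidase_candidates(matrix, tables, annotations, strict_cfg).candidate_ids
        )
        assert strict <= base

    def test_report_round_trip_dict(self, small_fixture):
        matrix, tables, annotations, cfg = small_fixture
        report = select_oxidase_candidates(matrix, tables, annotations, cfg)
        doc = report.to_dict()
        assert doc["strategy"] == "oxidase"
        assert doc["candidates"][0]["transcript_id"] == "OX1"
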