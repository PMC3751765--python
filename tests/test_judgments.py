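"""Bipolar scale encoding, survey parsing and matrix construction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahpgroup import datasets
from ahpgroup.errors import DesignError, SurveyError
from ahpgroup.judgments import (
    BASELINE,
    ComparisonJudgment,
    PairwiseMatrix,
    build_matrix,
    decode_ratio,
    encode_bipolar,
    parse_survey,
    star_matrix,
    star_ratios,
)
from ahpgroup.priority_engine import consistency, principal_eigenvector


def J(left, right, favored, score, context="criteria:goal", rid="r1"):
    return ComparisonJudgment(respondent_id=rid, context=context, left=left,
                              right=right, favored=favored, score=score)


class TestEncodeBipolar:
    @pytest.mark.parametrize(
        "favored, score, expected",
        [("left", 9, 9.0), ("neither", 1, 1.0), ("right", 3, 1 / 3),
         ("left", 1, 1.0), ("right", 9, 1 / 9)],
    )
    def test_scale_endpoints_and_reciprocals(self, favored, score, expected):
        assert encode_bipolar(favored, score) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "favored, score", [("neither", 2), ("left", 0), ("left", 10), ("up", 3)]
    )
    def test_invalid_judgments_rejected(self, favored, score):
        with pytest.raises(SurveyError):
            encode_bipolar(favored, score)

    @given(st.integers(min_value=1, max_value=9))
    def test_left_right_symmetry(self, score):
        assert encode_bipolar("left", score) * encode_bipolar("right", score) == pytest.approx(1.0)

    @given(st.floats(min_value=1 / 9, max_value=9.0))
    def test_decode_roundtrip(self, ratio):
        favored, score = decode_ratio(ratio)
        assert encode_bipolar(favored, score) == pytest.approx(ratio)


class TestParseSurvey:
    HEADER = "respondent_id,group,context,left,right,favored,score\n"

    def test_full_design_roundtrip(self, small_study, tmp_path):
        path = tmp_path / "survey.csv"
        small_study.write_survey_csv(path)
        respondents, judgments = parse_survey(path, groups=datasets.GROUPS)
        assert len(respondents) == len(small_study.respondents)
        per_resp = len(judgments) / len(respondents)
        assert per_resp == 72  # 6 main pairs + 3 sub pairs + 63 star judgments

    def test_empty_file_with_header(self):
        respondents, judgments = parse_survey(io.StringIO(self.HEADER))
        assert respondents == [] and judgments == []

    def test_bad_rows_reported_with_index(self):
        rows = (
            self.HEADER
            + "r1,patients,criteria:goal,a,b,left,10\n"
            + "r1,patients,criteria:goal,a,c,sideways,3\n"
            + "r1,aliens,criteria:goal,b,c,left,2\n"
        )
        with pytest.raises(SurveyError) as exc:
            parse_survey(io.StringIO(rows), groups=datasets.GROUPS)
        msg = str(exc.value)
        assert "row 0" in msg and "row 1" in msg and "row 2" in msg

    def test_duplicate_judgment_is_an_error_not_an_overwrite(self):
        rows = (
            self.HEADER
            + "r1,patients,criteria:goal,a,b,left,3\n"
            + "r1,patients,criteria:goal,b,a,right,5\n"
        )
        with pytest.raises(SurveyError, match="duplicate"):
            parse_survey(io.StringIO(rows))


class TestBuildMatrix:
    def test_two_items(self):
        m = build_matrix([J("A", "B", "left", 2)], ("A", "B"))
        assert np.allclose(m.values, [[1, 2], [0.5, 1]])

    def test_three_items_transitive(self):
        m = build_matrix(
            [J("A", "B", "left", 2), J("A", "C", "left", 4), J("B", "C", "left", 2)],
            ("A", "B", "C"),
        )
        assert np.allclose(m.values, [[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])

    def test_missing_pair_named(self):
        judgments = [
            J("a", "b", "left", 2), J("a", "c", "left", 2), J("a", "d", "left", 2),
            J("b", "c", "left", 2), J("b", "d", "left", 2),
        ]
        with pytest.raises(DesignError, match=r"\('c', 'd'\)"):
            build_matrix(judgments, ("a", "b", "c", "d"))

    @given(st.lists(st.integers(min_value=-8, max_value=8), min_size=6, max_size=6))
    @settings(max_examples=50)
    def test_reciprocity_and_unit_diagonal(self, codes):
        items = ("a", "b", "c", "d")
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        judgments = []
        for (i, j), code in zip(pairs, codes):
            favored = "left" if code > 0 else ("right" if code < 0 else "neither")
            judgments.append(J(items[i], items[j], favored, abs(code) + 1 if code else 1))
        m = build_matrix(judgments, items)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values * m.values.T, 1.0, atol=1e-12)


class TestStarMatrix:
    INNOVATIONS = ("i1", "i2", "i3")

    def star(self, scores):
        return [
            J(i, BASELINE, f, s, context="innovation:health_gain")
            for i, (f, s) in zip(self.INNOVATIONS, scores)
        ]

    def test_all_equal_to_baseline_gives_all_ones(self):
        innovations = tuple(f"i{k}" for k in range(9))
        judgments = [J(i, BASELINE, "neither", 1, "innovation:x") for i in innovations]
        m = star_matrix(judgments, innovations)
        assert m.n == 10
        assert np.allclose(m.values, 1.0)

    def test_transitive_completion_through_hub(self):
        m = star_matrix(self.star([("left", 4), ("left", 2), ("neither", 1)]),
                        self.INNOVATIONS)
        # a_12 = a_10 / a_20 = 4/2
        assert m.values[m.items.index("i1"), m.items.index("i2")] == pytest.approx(2.0)

    def test_accepts_either_orientation(self):
        judgments = [
            J("i1", BASELINE, "left", 4, "innovation:x"),
            J(BASELINE, "i2", "right", 2, "innovation:x"),  # i2 favored, flipped row
            J("i3", BASELINE, "right", 3, "innovation:x"),
        ]
        r = star_ratios(judgments, self.INNOVATIONS)
        assert r == pytest.approx([4.0, 2.0, 1 / 3])

    def test_missing_innovation_rejected(self):
        with pytest.raises(DesignError, match="i3"):
            star_matrix(self.star([("left", 4), ("left", 2)])[:2], self.INNOVATIONS)

    @given(st.lists(st.integers(min_value=-8, max_value=8), min_size=5, max_size=5))
    @settings(max_examples=50)
    def test_completed_star_is_rank_one_consistent(self, codes):
        innovations = tuple(f"i{k}" for k in range(5))
        judgments = []
        for i, code in zip(innovations, codes):
            favored = "left" if code > 0 else ("right" if code < 0 else "neither")
            judgments.append(J(i, BASELINE, favored, abs(code) + 1 if code else 1,
                               "innovation:x"))
        m = star_matrix(judgments, innovations)
        a = m.values
        for i in range(m.n):
            for j in range(m.n):
                for k in range(m.n):
                    assert a[i, j] * a[j, k] == pytest.approx(a[i, k], abs=1e-9)
        # and its CR is identically zero (eigen oracle)
        report = consistency(principal_eigenvector(m))
        assert report.cr == pytest.approx(0.0, abs=1e-9)


class TestPairwiseMatrixInvariants:
    def test_rejects_non_reciprocal(self):
        with pytest.raises(DesignError, match="reciprocity"):
            PairwiseMatrix(items=("a", "b"), values=np.array([[1.0, 2.0], [1.0, 1.0]]))

    def test_rejects_nonpositive(self):
        with pytest.raises(DesignError):
            PairwiseMatrix(items=("a", "b"), values=np.array([[1.0, -2.0], [-0.5, 1.0]]))
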