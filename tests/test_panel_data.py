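"""I/O round-trips, sentinel handling and validation of panel files."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from delphikit.errors import DomainError, ParseError, SchemaError
from delphikit.panel_data import (
    NOT_EVALUABLE,
    Item,
    Part,
    Question,
    QuestionnaireVersion,
    RankingSet,
    Rating,
    RatingMatrix,
    read_questionnaire,
    read_rankings,
    read_ratings,
    read_results,
    write_questionnaire,
    write_rankings,
    write_ratings,
    write_results,
)
from delphikit.scoring import ItemScore
from delphikit.selection import Thresholds, verdict_for


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


HEADER = "panelist_id,item_id,score,comment\n"


class TestReadRatings:
    def test_parses_numeric_ne_and_comment(self, tmp_path):
        p = _write(
            tmp_path,
            "r.csv",
            HEADER + "p01,q12.1,8,\np03,q27.2,NE,could not judge\n",
        )
        m = read_ratings(p, ["p01", "p03"])
        assert m.value("p01", "q12.1") == 8
        assert m.value("p03", "q27.2") is NOT_EVALUABLE
        assert m.comment("p03", "q27.2") == "could not judge"

    def test_missing_pair_is_distinct_from_ne(self, tmp_path):
        p = _write(tmp_path, "r.csv", HEADER + "p01,i1,NE,\n")
        m = read_ratings(p, ["p01", "p02"])
        assert m.value("p01", "i1") is NOT_EVALUABLE
        assert m.value("p02", "i1") is None  # missing
        assert m.n_not_evaluable == 1
        assert m.n_missing(["i1"]) == 1

    @pytest.mark.parametrize(
        "row,exc",
        [
            ("p01,q12.1,11,", SchemaError),  # out of range
            ("p01,q12.1,0,", SchemaError),
            ("p01,q12.1,maybe,", ParseError),  # non-numeric
            ("p01,q12.1,,", ParseError),  # explicit empty score cell
            ("p01,q12.1,8", ParseError),  # wrong field count
        ],
    )
    def test_malformed_rows_raise_typed_errors(self, tmp_path, row, exc):
        p = _write(tmp_path, "r.csv", HEADER + row + "\n")
        with pytest.raises(exc):
            read_ratings(p, ["p01"])

    def test_duplicate_pair_rejected(self, tmp_path):
        p = _write(tmp_path, "r.csv", HEADER + "p01,i1,5,\np01,i1,6,\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_ratings(p, ["p01"])

    def test_unknown_panelist_rejected(self, tmp_path):
        p = _write(tmp_path, "r.csv", HEADER + "p99,i1,5,\n")
        with pytest.raises(SchemaError, match="roster"):
            read_ratings(p, ["p01"])

    def test_bad_header_rejected(self, tmp_path):
        p = _write(tmp_path, "r.csv", "a,b,c\np01,i1,5\n")
        with pytest.raises(ParseError, match="header"):
            read_ratings(p, ["p01"])


class TestReadRankings:
    def test_rank_is_position(self, tmp_path, tiny_questionnaire):
        p = _write(
            tmp_path,
            "k.csv",
            "panelist_id,part_id,ranked_questions\np01,partA,q2;q1;q3\n",
        )
        rs = read_rankings(p, tiny_questionnaire)
        assert rs.ranking("p01", "partA") == ("q2", "q1", "q3")

    def test_duplicate_question_rejected(self, tmp_path, tiny_questionnaire):
        p = _write(
            tmp_path,
            "k.csv",
            "panelist_id,part_id,ranked_questions\np01,partA,q1;q1;q2\n",
        )
        with pytest.raises(SchemaError, match="duplicate"):
            read_rankings(p, tiny_questionnaire)

    def test_list_longer_than_depth_rejected(self, tiny_questionnaire):
        with pytest.raises(SchemaError, match="depth"):
            RankingSet(
                "r", {("p01", "partA"): ("q1", "q2", "q3", "q1b")}, tiny_questionnaire
            )

    def test_foreign_question_rejected(self, tiny_questionnaire):
        with pytest.raises(SchemaError, match="belong"):
            RankingSet("r", {("p01", "partA"): ("q9",)}, tiny_questionnaire)


class TestQuestionnaireModel:
    def test_duplicate_item_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate item ids"):
            QuestionnaireVersion(
                version_label="v",
                parts=(
                    Part(
                        part_id="a",
                        ranking_depth=3,
                        questions=(
                            Question(
                                question_id="q1",
                                items=(Item(item_id="q1.1"), Item(item_id="q1.2")),
                            ),
                        ),
                    ),
                    Part(
                        part_id="b",
                        ranking_depth=3,
                        questions=(
                            Question(question_id="q1.1", items=(Item(item_id="q1.1"),)),
                        ),
                    ),
                ),
            )

    def test_subitem_ids_must_be_prefixed(self):
        with pytest.raises(ValueError, match="prefixed"):
            Question(question_id="q7", items=(Item(item_id="x1"), Item(item_id="q7.2")))

    def test_ranking_depth_restricted(self):
        with pytest.raises(ValueError, match="3 or 5"):
            Part(
                part_id="a",
                ranking_depth=4,
                questions=(Question(question_id="q1", items=(Item(item_id="q1"),)),),
            )

    def test_find_item_unknown_raises(self, tiny_questionnaire):
        with pytest.raises(DomainError):
            tiny_questionnaire.find_item("nope")


# --- round trips -----------------------------------------------------------

scores_or_ne = st.one_of(st.integers(1, 9), st.just(NOT_EVALUABLE))


@st.composite
def rating_matrices(draw):
    panel = draw(
        st.lists(
            st.text(alphabet="abcdefgh", min_size=1, max_size=4).map(lambda s: "p_" + s),
            min_size=1,
            max_size=5,
            unique=True,
        )
    )
    items = draw(
        st.lists(
            st.text(alphabet="0123456789", min_size=1, max_size=3).map(lambda s: "i" + s),
            min_size=1,
            max_size=6,
            unique=True,
        )
    )
    ratings = []
    for p in panel:
        for i in items:
            if draw(st.booleans()):  # missing pairs stay missing
                continue
            value = draw(scores_or_ne)
            comment = draw(st.one_of(st.none(), st.text(alphabet="abc xyz", max_size=10)))
            comment = comment.strip() or None if comment else None
            ratings.append(Rating(p, i, value, comment))
    return RatingMatrix("round1", panel, ratings), items


@given(rating_matrices())
def test_ratings_roundtrip_preserves_everything(tmp_path_factory, mx):
    matrix, items = mx
    path = tmp_path_factory.mktemp("rt") / "r.csv"
    write_ratings(matrix, path)
    back = read_ratings(path, matrix.panel)
    assert back == matrix
    assert back.n_not_evaluable == matrix.n_not_evaluable
    assert back.n_missing(items) == matrix.n_missing(items)


def test_rankings_roundtrip(tmp_path, tiny_questionnaire, tiny_rankings):
    path = tmp_path / "k.csv"
    write_rankings(tiny_rankings, path)
    assert read_rankings(path, tiny_questionnaire) == tiny_rankings


def test_questionnaire_roundtrip_yaml_and_json(tmp_path, tiny_questionnaire):
    for name in ("q.yaml", "q.json"):
        path = tmp_path / name
        write_questionnaire(tiny_questionnaire, path)
        assert read_questionnaire(path) == tiny_questionnaire


def test_results_roundtrip_to_six_decimals(tmp_path):
    score = ItemScore("q1", 13, 7.5, 1 / 13, 3 / 13, 9 / 13, 71.428571)
    verdict = verdict_for(score, Thresholds())
    path = tmp_path / "results.csv"
    write_results([(score, verdict)], path)
    (rec,) = read_results(path)
    assert rec.item_id == "q1" and rec.n_evaluable == 13
    for got, want in [
        (rec.median, 7.5),
        (rec.frac_low, 1 / 13),
        (rec.frac_high, 9 / 13),
        (rec.top_pct, 71.428571),
    ]:
        assert got == pytest.approx(want, abs=5e-7)
    assert rec.status == verdict.status.value


def test_results_empty_collection_writes_header_only(tmp_path):
    path = tmp_path / "results.csv"
    write_results([], path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("item_id,")
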