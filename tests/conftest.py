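from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from delphikit.panel_data import (
    NOT_EVALUABLE,
    Item,
    Part,
    Question,
    QuestionnaireVersion,
    RankingSet,
    Rating,
    RatingMatrix,
)
from delphikit.synthetic_panel import PanelConfig, generate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_questionnaire() -> QuestionnaireVersion:
    """Two single-item questions and one two-sub-item question, one part."""
    return QuestionnaireVersion(
        version_label="v0",
        provenance="test",
        parts=(
            Part(
                part_id="partA",
                title="Section A",
                ranking_depth=3,
                questions=(
                    Question(question_id="q1", text="Q1", items=(Item(item_id="q1"),)),
                    Question(question_id="q2", text="Q2", items=(Item(item_id="q2"),)),
                    Question(
                        question_id="q3",
                        text="Q3",
                        items=(Item(item_id="q3.1"), Item(item_id="q3.2")),
                    ),
                ),
            ),
        ),
    )


@pytest.fixture
def tiny_ratings() -> RatingMatrix:
    panel = ("p1", "p2", "p3")
    rows = [
        Rating("p1", "q1", 9, "Essential item"),
        Rating("p2", "q1", 7),
        Rating("p3", "q1", NOT_EVALUABLE),
        Rating("p1", "q2", 2),
        Rating("p2", "q2", 3, "Too vague"),
        Rating("p3", "q2", 5),
        Rating("p1", "q3.1", 8),
        Rating("p2", "q3.1", 8),
        Rating("p3", "q3.1", 9),
        Rating("p1", "q3.2", 7),
        Rating("p2", "q3.2", 4),
        # (p3, q3.2) intentionally missing
    ]
    return RatingMatrix("round1", panel, rows)


@pytest.fixture
def tiny_rankings(tiny_questionnaire) -> RankingSet:
    entries = {
        ("p1", "partA"): ("q1", "q3", "q2"),
        ("p2", "partA"): ("q1", "q2", "q3"),
        ("p3", "partA"): ("q3", "q1"),
    }
    return RankingSet("round1", entries, tiny_questionnaire)


@pytest.fixture(scope="session")
def synthetic_round():
    """One full 14-panelist, 57-item synthetic round (fixed seed)."""
    return generate_panel(PanelConfig(seed=123))
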