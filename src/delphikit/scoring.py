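"""Per-item descriptive statistics feeding the Delphi selection rules.

Three statistics drive the triage of each questionnaire item:

* the **median** of the panel's 1-9 relevance scores;
* the **tertile fractions** — the share of scores falling in the lowest
  (1-3), middle (4-6) and highest (7-9) third of the scale;
* the **prioritization (top) percentage** — panelists rank each part's
  questions in a top-k (k = 3 or 5); rank r earns k−r+1 points, an
  unranked question earns 0, and the percentage is the achieved points
  over the maximum possible, ``panel_size × k``.

Sub-items inherit the top percentage of their parent question, since
rankings are collected at question level while Likert ratings are
per item.

"Not evaluable" and missing ratings are excluded from every denominator
except the prioritization one, where the full active panel counts — a
panelist who omits a question from their top-k contributes 0 points but
still enlarges the maximum.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DomainError, EmptyScoreError
from .panel_data import (
    Item,
    Part,
    Question,
    QuestionnaireVersion,
    RankingSet,
    RatingMatrix,
)

__all__ = [
    "ItemScore",
    "median_score",
    "tertile_fractions",
    "prioritization_pct",
    "score_item",
    "score_round",
]

LOW_TERTILE = range(1, 4)
MID_TERTILE = range(4, 7)
HIGH_TERTILE = range(7, 10)


@dataclass(frozen=True)
class ItemScore:
    """Descriptive statistics for one item in one round."""

    item_id: str
    n_evaluable: int
    median: float
    frac_low: float
    frac_mid: float
    frac_high: float
    top_pct: float

    def __post_init__(self) -> None:
        if self.n_evaluable > 0:
            total = self.frac_low + self.frac_mid + self.frac_high
            if abs(total - 1.0) > 1e-9:
                raise DomainError(
                    f"tertile fractions for {self.item_id} sum to {total}, not 1"
                )
        if not 0.0 <= self.top_pct <= 100.0:
            raise DomainError(f"top_pct {self.top_pct} outside [0, 100]")


def _check_scores(scores: Sequence[int]) -> None:
    if len(scores) == 0:
        raise EmptyScoreError("no evaluable scores")
    for s in scores:
        if not isinstance(s, int) or not 1 <= s <= 9:
            raise DomainError(f"score {s!r} outside 1..9")


def median_score(scores: Sequence[int]) -> float:
    """Sample median of evaluable scores; half-integer for even counts."""
    _check_scores(scores)
    return float(statistics.median(scores))


def tertile_fractions(scores: Sequence[int]) -> tuple[float, float, float]:
    """Shares of scores in the 1-3, 4-6 and 7-9 bands of the scale."""
    _check_scores(scores)
    n = len(scores)
    low = sum(1 for s in scores if s in LOW_TERTILE)
    mid = sum(1 for s in scores if s in MID_TERTILE)
    high = sum(1 for s in scores if s in HIGH_TERTILE)
    return low / n, mid / n, high / n


def prioritization_pct(
    rankings: RankingSet, question_id: str, part: Part, panel_size: int
) -> float:
    """Top percentage of a question: achieved ranking points over maximum.

    With list depth k, rank 1 earns k points down to rank k earning 1;
    a panelist who leaves the question out contributes 0 points but the
    maximum stays ``panel_size × k``.
    """
    if panel_size < 1:
        raise DomainError("panel_size must be >= 1")
    if question_id not in part.question_ids():
        raise DomainError(
            f"question {question_id!r} does not belong to part {part.part_id!r}"
        )
    k = part.ranking_depth
    points = 0
    for _, ranked in rankings.rankings_for_part(part.part_id):
        if question_id in ranked:
            rank = ranked.index(question_id) + 1
            points += k - rank + 1
    return 100.0 * points / (panel_size * k)


def score_item(
    ratings: RatingMatrix,
    rankings: RankingSet,
    item: Item,
    parent_question: Question,
    part: Part,
    panel_size: int,
) -> ItemScore:
    """Combine median, tertile fractions and inherited top percentage.

    Raises :class:`EmptyScoreError` when the item has no evaluable rating;
    callers flag such items as unscorable rather than classifying them.
    """
    scores = ratings.numeric_scores(item.item_id)
    if not scores:
        raise EmptyScoreError(f"item {item.item_id} has no evaluable rating")
    low, mid, high = tertile_fractions(scores)
    return ItemScore(
        item_id=item.item_id,
        n_evaluable=len(scores),
        median=median_score(scores),
        frac_low=low,
        frac_mid=mid,
        frac_high=high,
        top_pct=prioritization_pct(
            rankings, parent_question.question_id, part, panel_size
        ),
    )


def score_round(
    questionnaire: QuestionnaireVersion,
    ratings: RatingMatrix,
    rankings: RankingSet,
    panel_size: int,
) -> tuple[dict[str, ItemScore], list[str]]:
    """Score every item of a round.

    Returns ``(scores, unscorable)``: scores keyed by item id in
    questionnaire order, plus the ids of items with zero evaluable ratings
    (reported with a warning, excluded from classification).
    """
    scores: dict[str, ItemScore] = {}
    unscorable: list[str] = []
    for part, question, item in questionnaire.iter_items():
        try:
            scores[item.item_id] = score_item(
                ratings, rankings, item, question, part, panel_size
            )
        except EmptyScoreError:
            unscorable.append(item.item_id)
    if unscorable:
        warnings.warn(
            f"{len(unscorable)} item(s) had no evaluable rating and were "
            f"flagged UNSCORABLE: {', '.join(unscorable)}",
            stacklevel=2,
        )
    return scores, unscorable
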