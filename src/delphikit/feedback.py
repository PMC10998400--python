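"""Personalized feedback reports for panelists between rounds.

After the rating round each expert receives a report that puts their own
answers next to the anonymous panel result: the full score distribution
per item, the median and top percentage, the item's provisional triage
colour, their own score and comment, and the other panelists' comments
(anonymized, in a seeded shuffled order so no positional pattern leaks
identities while the rendering stays deterministic).
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .errors import DomainError
from .panel_data import (
    NOT_EVALUABLE,
    QuestionnaireVersion,
    RatingMatrix,
    RatingValue,
)
from .scoring import ItemScore
from .selection import ItemVerdict

__all__ = ["ItemBlock", "FeedbackReport", "build_report", "render_markdown"]


@dataclass(frozen=True)
class ItemBlock:
    """One item's panel result as shown to a single recipient."""

    item_id: str
    item_text: str
    question_id: str
    distribution: tuple[int, ...]  # counts for scores 1..9
    ne_count: int
    median: float
    top_pct: float
    own_score: Optional[RatingValue]  # None when the recipient skipped it
    own_comment: Optional[str]
    peer_comments: tuple[str, ...]
    status: str
    color: str


@dataclass(frozen=True)
class FeedbackReport:
    panelist_id: str
    round_label: str
    blocks: tuple[ItemBlock, ...]


def _comment_rng(seed: int, item_id: str) -> random.Random:
    # stable across processes: crc32 of the (seed, item) pair
    return random.Random(zlib.crc32(f"{seed}:{item_id}".encode()))


def build_report(
    panelist_id: str,
    questionnaire: QuestionnaireVersion,
    ratings: RatingMatrix,
    scores: Mapping[str, ItemScore],
    verdicts: Mapping[str, ItemVerdict],
    seed: int = 0,
) -> FeedbackReport:
    """Assemble one expert's report over every classifiable item.

    Items appear in questionnaire order; items without a score (no
    evaluable rating panel-wide) are omitted, mirroring their exclusion
    from classification.
    """
    if panelist_id not in ratings.panel:
        raise DomainError(f"panelist {panelist_id!r} is not on the round's panel")
    blocks: list[ItemBlock] = []
    for _, question, item in questionnaire.iter_items():
        score = scores.get(item.item_id)
        if score is None:
            continue
        verdict = verdicts[item.item_id]
        numeric = ratings.numeric_scores(item.item_id)
        dist = tuple(sum(1 for s in numeric if s == v) for v in range(1, 10))
        peer = [
            c
            for p, c in ratings.comments_for_item(item.item_id)
            if p != panelist_id
        ]
        _comment_rng(seed, item.item_id).shuffle(peer)
        blocks.append(
            ItemBlock(
                item_id=item.item_id,
                item_text=item.text,
                question_id=question.question_id,
                distribution=dist,
                ne_count=ratings.not_evaluable_count(item.item_id),
                median=score.median,
                top_pct=score.top_pct,
                own_score=ratings.value(panelist_id, item.item_id),
                own_comment=ratings.comment(panelist_id, item.item_id),
                peer_comments=tuple(peer),
                status=verdict.status.value,
                color=verdict.color,
            )
        )
    return FeedbackReport(panelist_id, ratings.round_label, tuple(blocks))


def _format_own_score(value: Optional[RatingValue]) -> str:
    if value is None:
        return "no answer"
    if value is NOT_EVALUABLE:
        return "not evaluable"
    return str(value)


def render_markdown(report: FeedbackReport, path=None) -> str:
    """Render a report to deterministic markdown; optionally write it."""
    lines: list[str] = [
        f"# Feedback report — panelist {report.panelist_id}",
        "",
        f"Round: {report.round_label}",
        f"Items: {len(report.blocks)}",
        "",
    ]
    for block in report.blocks:
        lines.append(f"## Item {block.item_id} ({block.color})")
        if block.item_text:
            lines.append(f"> {block.item_text}")
        lines.append("")
        hist = "  ".join(
            f"{v}:{c}" for v, c in zip(range(1, 10), block.distribution)
        )
        lines.append(f"- Panel scores: {hist}  NE:{block.ne_count}")
        lines.append(f"- Median: {block.median:g}")
        lines.append(f"- Top percentage: {block.top_pct:.1f}%")
        lines.append(f"- Status: {block.status.replace('_', ' ')} ({block.color})")
        lines.append(f"- Your score: {_format_own_score(block.own_score)}")
        if block.own_comment:
            lines.append(f"- Your comment: {block.own_comment}")
        if block.peer_comments:
            lines.append("- Panel comments (anonymized):")
            for comment in block.peer_comments:
                lines.append(f"  - {comment}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
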