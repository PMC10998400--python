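"""Preselection, consensus and triage rules for panel-rated items.

The selection stage applies two independent rules to each item's
statistics and combines them into a triage status:

**Preselection** (median × top percentage):

====================================  ============
median ≥ 7 and top ≥ 20%              Selection
median ≥ 7 and 0% < top < 20%         Discussion
median < 7 and top ≥ 20%              Discussion
other                                 No selection
====================================  ============

**Consensus** (tertile fractions of the panel's scores):

==========================================  ============
≥ 70% of scores in the highest tertile      Consensus
≥ 30% in highest and ≥ 30% in lowest        Discussion
other                                       No consensus
==========================================  ============

The combination rule is the strictest one consistent with a three-colour
triage: an item is *selected* (green) only when both rules return their
top category, *not selected* (red) only when both return their bottom
category, and *up for discussion* (orange) otherwise. All cut-points are
configurable through :class:`Thresholds` for sensitivity analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, field_validator

from .errors import DomainError, SchemaError
from .scoring import ItemScore

__all__ = [
    "Preselection",
    "Consensus",
    "Status",
    "STATUS_COLOR",
    "Thresholds",
    "ItemVerdict",
    "preselect",
    "consensus",
    "classify",
    "verdict_for",
    "triage_round",
]


class Preselection(str, Enum):
    SELECTION = "selection"
    DISCUSSION = "discussion"
    NO_SELECTION = "no_selection"


class Consensus(str, Enum):
    CONSENSUS = "consensus"
    DISCUSSION = "discussion"
    NO_CONSENSUS = "no_consensus"


class Status(str, Enum):
    SELECTED = "selected"
    UP_FOR_DISCUSSION = "up_for_discussion"
    NOT_SELECTED = "not_selected"


STATUS_COLOR: dict[Status, str] = {
    Status.SELECTED: "green",
    Status.UP_FOR_DISCUSSION: "orange",
    Status.NOT_SELECTED: "red",
}


class Thresholds(BaseModel):
    """Cut-points of the preselection and consensus rules.

    Defaults are the study rules: median ≥ 7 with top percentage ≥ 20%
    preselects an item; ≥ 70% of scores in the highest tertile is
    consensus; ≥ 30% in both extreme tertiles flags a split panel.
    """

    median_cut: float = 7.0
    top_cut: float = 20.0
    consensus_high: float = 0.70
    discussion_high: float = 0.30
    discussion_low: float = 0.30

    model_config = {"frozen": True}

    @field_validator("median_cut")
    @classmethod
    def _median_in_scale(cls, v: float) -> float:
        if not 1.0 <= v <= 9.0:
            raise ValueError("median_cut must lie in [1, 9]")
        return v

    @field_validator("top_cut")
    @classmethod
    def _top_cut_pct(cls, v: float) -> float:
        if not 0.0 < v <= 100.0:
            raise ValueError("top_cut must lie in (0, 100]")
        return v

    @field_validator("consensus_high", "discussion_high", "discussion_low")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("tertile thresholds must lie in [0, 1]")
        return v

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with Path(path).open(encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        if not isinstance(obj, dict):
            raise SchemaError(f"thresholds file {path} does not hold a mapping")
        return cls.model_validate(obj)


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class ItemVerdict:
    """Preselection × consensus outcome and the resulting triage status."""

    item_id: str
    preselection: Preselection
    consensus: Consensus
    status: Status

    @property
    def color(self) -> str:
        return STATUS_COLOR[self.status]


def preselect(
    median: float, top_pct: float, t: Thresholds = DEFAULT_THRESHOLDS
) -> Preselection:
    """Apply the median × top-percentage rule.

    The four rows partition the plane: "top percentage between 1-20%" is
    read as the open interval (0, top_cut), so a never-ranked question
    (top 0%) with a high median falls through to *no selection*.
    """
    if not 1.0 <= median <= 9.0:
        raise DomainError(f"median {median} outside [1, 9]")
    if not 0.0 <= top_pct <= 100.0:
        raise DomainError(f"top_pct {top_pct} outside [0, 100]")
    if median >= t.median_cut and top_pct >= t.top_cut:
        return Preselection.SELECTION
    if median >= t.median_cut and 0.0 < top_pct < t.top_cut:
        return Preselection.DISCUSSION
    if median < t.median_cut and top_pct >= t.top_cut:
        return Preselection.DISCUSSION
    return Preselection.NO_SELECTION


def consensus(
    frac_high: float, frac_low: float, t: Thresholds = DEFAULT_THRESHOLDS
) -> Consensus:
    """Apply the tertile-agreement rule."""
    for name, v in (("frac_high", frac_high), ("frac_low", frac_low)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} {v} outside [0, 1]")
    if frac_high + frac_low > 1.0 + 1e-9:
        raise DomainError("frac_high + frac_low exceeds 1")
    if frac_high >= t.consensus_high:
        return Consensus.CONSENSUS
    if frac_high >= t.discussion_high and frac_low >= t.discussion_low:
        return Consensus.DISCUSSION
    return Consensus.NO_CONSENSUS


def classify(pre: Preselection, cons: Consensus) -> Status:
    """Combine the two rule outcomes into the triage status.

    Selected only when both rules return their top category; not selected
    only when both return their bottom category; discussion otherwise.
    """
    if pre is Preselection.SELECTION and cons is Consensus.CONSENSUS:
        return Status.SELECTED
    if pre is Preselection.NO_SELECTION and cons is Consensus.NO_CONSENSUS:
        return Status.NOT_SELECTED
    return Status.UP_FOR_DISCUSSION


def verdict_for(score: ItemScore, t: Thresholds = DEFAULT_THRESHOLDS) -> ItemVerdict:
    pre = preselect(score.median, score.top_pct, t)
    cons = consensus(score.frac_high, score.frac_low, t)
    return ItemVerdict(score.item_id, pre, cons, classify(pre, cons))


def triage_round(
    scores: Iterable[ItemScore], t: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[list[ItemVerdict], Counter]:
    """Classify every scored item; returns verdicts plus status counts."""
    verdicts = [verdict_for(s, t) for s in scores]
    summary = Counter({status: 0 for status in Status})
    summary.update(v.status for v in verdicts)
    return verdicts, summary
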