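"""Seeded synthetic Delphi panels for testing every pipeline stage.

No raw panel ratings from real Delphi exercises of this kind are
publicly deposited, so the package ships a generator that emulates the
statistical structure the selection rules assume:

* each question carries an :class:`ItemProfile` — a probability vector
  over the nine Likert scores (plus a "not evaluable" probability) and a
  latent relevance in [0, 1];
* ratings are drawn independently per (panelist, item) from the
  question's profile;
* each panelist's top-k ranking per part follows a Plackett-Luce model
  with weights proportional to latent relevance (sampled via the
  Gumbel-max trick), so more relevant questions earn stochastically
  higher top percentages;
* one configurable panelist drops out after the first round, mirroring
  a 14-member panel losing one member before the final evaluation.

Four stock profiles cover the outcome classes the triage rules
distinguish: ``consensus_high`` (panel agrees the item is relevant),
``polarized`` (panel split between extremes), ``middling`` (lukewarm)
and ``irrelevant``.

Identical seeds give identical output, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import SchemaError
from .panel_data import (
    NOT_EVALUABLE,
    Item,
    Origin,
    Part,
    Question,
    QuestionnaireVersion,
    RankingSet,
    Rating,
    RatingMatrix,
    write_questionnaire,
    write_rankings,
    write_ratings,
)
from .scoring import score_round
from .selection import Status, Thresholds, triage_round

__all__ = [
    "ItemProfile",
    "PROFILES",
    "PartSpec",
    "PanelConfig",
    "SyntheticPanel",
    "default_profile_assignment",
    "generate_panel",
    "write_panel",
    "recovery_experiment",
]

ProfileLabel = Literal["consensus_high", "polarized", "middling", "irrelevant"]


class ItemProfile(BaseModel):
    """Rating behaviour of the panel towards one question's items."""

    label: ProfileLabel
    score_probs: tuple[float, ...] = Field(min_length=9, max_length=9)
    ne_prob: Optional[float] = None  # None → use the panel-wide ne_rate
    latent_relevance: float

    model_config = {"frozen": True}

    @field_validator("score_probs")
    @classmethod
    def _probs_sum_to_one(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(p < 0 for p in v):
            raise ValueError("score probabilities must be non-negative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"score probabilities sum to {sum(v)}, not 1")
        return v

    @field_validator("latent_relevance")
    @classmethod
    def _relevance_in_unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("latent_relevance must lie in [0, 1]")
        return v


PROFILES: dict[str, ItemProfile] = {
    "consensus_high": ItemProfile(
        label="consensus_high",
        score_probs=(0.005, 0.005, 0.01, 0.01, 0.02, 0.03, 0.22, 0.35, 0.35),
        latent_relevance=1.0,
    ),
    "polarized": ItemProfile(
        label="polarized",
        score_probs=(0.12, 0.14, 0.14, 0.06, 0.07, 0.07, 0.13, 0.14, 0.13),
        latent_relevance=0.45,
    ),
    "middling": ItemProfile(
        label="middling",
        score_probs=(0.03, 0.06, 0.11, 0.20, 0.20, 0.20, 0.11, 0.06, 0.03),
        latent_relevance=0.30,
    ),
    "irrelevant": ItemProfile(
        label="irrelevant",
        score_probs=(0.22, 0.20, 0.18, 0.14, 0.10, 0.06, 0.05, 0.03, 0.02),
        latent_relevance=0.05,
    ),
}


class PartSpec(BaseModel):
    part_id: str
    n_questions: int = Field(ge=1)
    ranking_depth: int

    model_config = {"frozen": True}

    @field_validator("ranking_depth")
    @classmethod
    def _depth(cls, v: int) -> int:
        if v not in (3, 5):
            raise ValueError("ranking_depth must be 3 or 5")
        return v


# part layout mirroring a five-section questionnaire of 34 questions
DEFAULT_PARTS = (
    PartSpec(part_id="part1", n_questions=12, ranking_depth=5),
    PartSpec(part_id="part2_1", n_questions=4, ranking_depth=3),
    PartSpec(part_id="part2_2", n_questions=6, ranking_depth=3),
    PartSpec(part_id="part2_3", n_questions=7, ranking_depth=5),
    PartSpec(part_id="part2_4", n_questions=5, ranking_depth=3),
)

# question number → sub-item count; everything else is a single item.
# With the default parts this yields 57 items over 34 questions.
DEFAULT_MULTI_ITEM = {12: 3, 14: 5, 21: 2, 23: 8, 24: 2, 27: 9}


class PanelConfig(BaseModel):
    """Dimensions and noise levels of a synthetic panel round."""

    n_panelists: int = Field(default=14, ge=2)
    parts: tuple[PartSpec, ...] = DEFAULT_PARTS
    multi_item_questions: Mapping[int, int] = Field(
        default_factory=lambda: dict(DEFAULT_MULTI_ITEM)
    )
    dropout_after_round1: int = Field(default=1, ge=0)
    ne_rate: float = Field(default=0.02, ge=0.0, le=0.5)
    ranking_noise: float = Field(default=0.10, gt=0.0)
    seed: int  # mandatory: every draw must be reproducible

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _dropout_leaves_panel(self) -> "PanelConfig":
        if self.dropout_after_round1 >= self.n_panelists:
            raise ValueError("dropout would empty the panel")
        return self

    @property
    def n_questions(self) -> int:
        return sum(p.n_questions for p in self.parts)


@dataclass(frozen=True)
class SyntheticPanel:
    """One generated round plus its ground truth."""

    questionnaire: QuestionnaireVersion
    ratings: RatingMatrix
    rankings: RankingSet
    truth: dict[str, str]  # item_id → profile label
    panel_after_dropout: tuple[str, ...]


def _build_questionnaire(config: PanelConfig) -> QuestionnaireVersion:
    parts = []
    qnum = 0
    for spec in config.parts:
        questions = []
        for _ in range(spec.n_questions):
            qnum += 1
            qid = str(qnum)
            n_sub = int(config.multi_item_questions.get(qnum, 1))
            if n_sub <= 1:
                items = (Item(item_id=qid, text=f"Statement {qid}", origin=Origin.CP_FIT),)
            else:
                items = tuple(
                    Item(
                        item_id=f"{qid}.{j}",
                        text=f"Statement {qid}.{j}",
                        origin=Origin.REFLECT52,
                    )
                    for j in range(1, n_sub + 1)
                )
            questions.append(
                Question(question_id=qid, text=f"Question {qid}", items=items)
            )
        parts.append(
            Part(
                part_id=spec.part_id,
                title=f"Section {spec.part_id}",
                ranking_depth=spec.ranking_depth,
                questions=tuple(questions),
            )
        )
    return QuestionnaireVersion(
        version_label="synthetic-round1", provenance="synthetic", parts=tuple(parts)
    )


# deterministic cycle: half the questions agreeable, the rest split
# between lukewarm, polarized and irrelevant
_DEFAULT_CYCLE = (
    "consensus_high",
    "consensus_high",
    "middling",
    "consensus_high",
    "polarized",
    "irrelevant",
)


def default_profile_assignment(
    questionnaire: QuestionnaireVersion,
) -> dict[str, ItemProfile]:
    """Assign stock profiles to questions in a fixed repeating pattern."""
    return {
        q.question_id: PROFILES[_DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)]]
        for i, (_, q) in enumerate(questionnaire.iter_questions())
    }


def generate_panel(
    config: PanelConfig,
    profile_assignment: Optional[Mapping[str, ItemProfile]] = None,
) -> SyntheticPanel:
    """Draw one full rating round: ratings, rankings and the truth key."""
    rng = np.random.default_rng(config.seed)
    questionnaire = _build_questionnaire(config)
    if profile_assignment is None:
        profile_assignment = default_profile_assignment(questionnaire)
    missing = set(questionnaire.question_ids()) - set(profile_assignment)
    if missing:
        raise SchemaError(
            f"no profile assigned to question(s): {', '.join(sorted(missing))}"
        )

    width = max(2, len(str(config.n_panelists)))
    panel = tuple(f"p{i + 1:0{width}d}" for i in range(config.n_panelists))

    scores = np.arange(1, 10)
    ratings: list[Rating] = []
    truth: dict[str, str] = {}
    for _, question, item in questionnaire.iter_items():
        profile = profile_assignment[question.question_id]
        truth[item.item_id] = profile.label
        ne_prob = profile.ne_prob if profile.ne_prob is not None else config.ne_rate
        probs = np.asarray(profile.score_probs)
        for panelist in panel:
            if rng.random() < ne_prob:
                ratings.append(Rating(panelist, item.item_id, NOT_EVALUABLE))
            else:
                value = int(rng.choice(scores, p=probs))
                ratings.append(Rating(panelist, item.item_id, value))
    matrix = RatingMatrix("round1", panel, ratings)

    entries: dict[tuple[str, str], tuple[str, ...]] = {}
    for panelist in panel:
        for part in questionnaire.parts:
            qids = part.question_ids()
            relevance = np.array(
                [profile_assignment[q].latent_relevance for q in qids]
            )
            # Gumbel-max sampling of a Plackett-Luce ranking with weights
            # relevance + noise floor (keeps zero-relevance questions rankable)
            weights = relevance + config.ranking_noise
            keys = np.log(weights) + rng.gumbel(size=len(qids))
            k = min(part.ranking_depth, len(qids))
            top = np.argsort(-keys, kind="stable")[:k]
            entries[(panelist, part.part_id)] = tuple(qids[i] for i in top)
    rankings = RankingSet("round1", entries, questionnaire)

    remaining = panel[: len(panel) - config.dropout_after_round1]
    return SyntheticPanel(questionnaire, matrix, rankings, truth, remaining)


def write_panel(panel: SyntheticPanel, outdir) -> dict[str, Path]:
    """Write the standard file set (plus the truth key) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "questionnaire": outdir / "questionnaire.yaml",
        "ratings": outdir / "ratings.csv",
        "rankings": outdir / "rankings.csv",
        "truth": outdir / "truth.csv",
    }
    write_questionnaire(panel.questionnaire, paths["questionnaire"])
    write_ratings(panel.ratings, paths["ratings"])
    write_rankings(panel.rankings, paths["rankings"])
    with paths["truth"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("item_id,profile\n")
        for item_id in panel.questionnaire.item_ids():
            fh.write(f"{item_id},{panel.truth[item_id]}\n")
    return paths


def recovery_experiment(
    config: PanelConfig,
    n_reps: int,
    profile_assignment_factory=default_profile_assignment,
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """How often does each true profile land in each triage status?

    Runs generate → score → triage ``n_reps`` times (replicate ``i`` uses
    seed ``config.seed + i``) and tabulates row-normalized frequencies:
    rows are profile labels, columns triage statuses. With the stock
    profiles, agreeable questions should land in *selected*, irrelevant
    ones in *not selected* and polarized ones in *up for discussion*.
    """
    if n_reps < 1:
        raise SchemaError("n_reps must be >= 1")
    thresholds = thresholds or Thresholds()
    labels = sorted({p.label for p in PROFILES.values()})
    statuses = [s.value for s in Status]
    counts = pd.DataFrame(0, index=labels, columns=statuses, dtype=float)
    for rep in range(n_reps):
        rep_config = config.model_copy(update={"seed": config.seed + rep})
        panel = generate_panel(
            rep_config, profile_assignment_factory(_build_questionnaire(rep_config))
        )
        scores, _ = score_round(
            panel.questionnaire, panel.ratings, panel.rankings, config.n_panelists
        )
        verdicts, _ = triage_round(scores.values(), thresholds)
        for v in verdicts:
            counts.loc[panel.truth[v.item_id], v.status.value] += 1
    totals = counts.sum(axis=1)
    return counts.div(totals.where(totals > 0, 1.0), axis=0)
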