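"""Data model and file I/O for Delphi panel artifacts.

The package analyses expert-panel data for a RAND-modified Delphi study:
a structured questionnaire (parts → questions → items), one rating per
(panelist, item) on a 9-point relevance Likert scale with an explicit
"not evaluable" option, and per-part top-k rankings of questions.

Two kinds of non-numeric rating are kept strictly apart:

* ``NOT_EVALUABLE`` — the panelist actively chose the "not evaluable"
  option (serialized as the sentinel ``"NE"``);
* *missing* — no rating was recorded for that (panelist, item) pair at
  all (serialized as an empty cell, represented in memory by absence).

All files are UTF-8 CSV (long/tidy format) or YAML/JSON for the nested
questionnaire structure.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import DomainError, ParseError, SchemaError

__all__ = [
    "NOT_EVALUABLE",
    "NE_TOKEN",
    "Origin",
    "ResponseFormat",
    "Item",
    "Question",
    "Part",
    "QuestionnaireVersion",
    "Rating",
    "RatingMatrix",
    "RankingSet",
    "ResultRecord",
    "read_ratings",
    "write_ratings",
    "read_rankings",
    "write_rankings",
    "read_questionnaire",
    "write_questionnaire",
    "write_results",
    "read_results",
]

NE_TOKEN = "NE"

LIKERT_MIN, LIKERT_MAX = 1, 9


class _NotEvaluable:
    """Singleton sentinel for the explicit 'not evaluable' choice."""

    __slots__ = ()
    _singleton: Optional["_NotEvaluable"] = None

    def __new__(cls) -> "_NotEvaluable":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_EVALUABLE"

    def __reduce__(self):
        return (_NotEvaluable, ())


NOT_EVALUABLE = _NotEvaluable()

RatingValue = Union[int, _NotEvaluable]


class Origin(str, Enum):
    """Where a candidate item was drafted from."""

    CP_FIT = "cp_fit"
    REFLECT52 = "reflect52"
    BOTH = "both"
    PANEL_ADDED = "panel_added"


class ResponseFormat(str, Enum):
    LIKERT_AGREEMENT = "likert_agreement"
    SATISFACTION = "satisfaction"
    CATEGORICAL = "categorical"
    NUMERIC_BAND = "numeric_band"
    OPEN = "open"


class Item(BaseModel):
    """A single ratable item (a question or one of its sub-statements)."""

    item_id: str
    text: str = ""
    origin: Origin = Origin.PANEL_ADDED

    model_config = {"frozen": True}


class Question(BaseModel):
    question_id: str
    text: str = ""
    response_format: ResponseFormat = ResponseFormat.LIKERT_AGREEMENT
    items: tuple[Item, ...] = Field(min_length=1)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _item_ids_match_question(self) -> "Question":
        for it in self.items:
            ok = it.item_id == self.question_id or it.item_id.startswith(
                self.question_id + "."
            )
            if not ok:
                raise ValueError(
                    f"item id {it.item_id!r} is not prefixed by its question id "
                    f"{self.question_id!r}"
                )
        if len(self.items) > 1 and any(
            it.item_id == self.question_id for it in self.items
        ):
            raise ValueError(
                f"question {self.question_id!r} with sub-items may not also "
                "carry a bare item"
            )
        return self


class Part(BaseModel):
    """A questionnaire section; panelists rank its questions in a top-k."""

    part_id: str
    title: str = ""
    ranking_depth: int
    questions: tuple[Question, ...] = Field(min_length=1)

    model_config = {"frozen": True}

    @field_validator("ranking_depth")
    @classmethod
    def _depth_3_or_5(cls, v: int) -> int:
        if v not in (3, 5):
            raise ValueError("ranking_depth must be 3 or 5")
        return v

    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for q in self.questions)


class QuestionnaireVersion(BaseModel):
    """One versioned questionnaire: ordered parts → questions → items."""

    version_label: str
    provenance: str = ""
    parts: tuple[Part, ...] = Field(min_length=1)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _unique_ids(self) -> "QuestionnaireVersion":
        part_ids = [p.part_id for p in self.parts]
        if len(set(part_ids)) != len(part_ids):
            raise ValueError("duplicate part ids")
        qids = [q.question_id for p in self.parts for q in p.questions]
        if len(set(qids)) != len(qids):
            raise ValueError("duplicate question ids")
        iids = [it.item_id for p in self.parts for q in p.questions for it in q.items]
        if len(set(iids)) != len(iids):
            raise ValueError("duplicate item ids")
        return self

    # -- traversal helpers -------------------------------------------------

    def iter_questions(self) -> Iterator[tuple[Part, Question]]:
        for part in self.parts:
            for q in part.questions:
                yield part, q

    def iter_items(self) -> Iterator[tuple[Part, Question, Item]]:
        for part, q in self.iter_questions():
            for it in q.items:
                yield part, q, it

    @property
    def n_questions(self) -> int:
        return sum(len(p.questions) for p in self.parts)

    @property
    def n_items(self) -> int:
        return sum(len(q.items) for _, q in self.iter_questions())

    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for _, _, it in self.iter_items())

    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for _, q in self.iter_questions())

    def find_item(self, item_id: str) -> tuple[Part, Question, Item]:
        for part, q, it in self.iter_items():
            if it.item_id == item_id:
                return part, q, it
        raise DomainError(f"unknown item id {item_id!r}")

    def find_question(self, question_id: str) -> tuple[Part, Question]:
        for part, q in self.iter_questions():
            if q.question_id == question_id:
                return part, q
        raise DomainError(f"unknown question id {question_id!r}")

    def part(self, part_id: str) -> Part:
        for p in self.parts:
            if p.part_id == part_id:
                return p
        raise DomainError(f"unknown part id {part_id!r}")


@dataclass(frozen=True)
class Rating:
    """One panelist's rating of one item."""

    panelist_id: str
    item_id: str
    value: RatingValue
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        v = self.value
        if isinstance(v, bool) or (
            isinstance(v, int) and not (LIKERT_MIN <= v <= LIKERT_MAX)
        ):
            raise SchemaError(
                f"rating {v!r} for ({self.panelist_id}, {self.item_id}) "
                f"outside {LIKERT_MIN}..{LIKERT_MAX}"
            )
        if not isinstance(v, (int, _NotEvaluable)):
            raise SchemaError(f"rating value must be int or NOT_EVALUABLE, got {v!r}")

    @property
    def is_not_evaluable(self) -> bool:
        return isinstance(self.value, _NotEvaluable)


class RatingMatrix:
    """All ratings of one round: panel × item, sparse over missing pairs.

    Absent (panelist, item) pairs are *missing*, distinct from an explicit
    ``NOT_EVALUABLE`` rating.
    """

    def __init__(
        self, round_label: str, panel: Iterable[str], ratings: Iterable[Rating]
    ) -> None:
        self.round_label = round_label
        self.panel = frozenset(panel)
        by_key: dict[tuple[str, str], Rating] = {}
        for r in ratings:
            if r.panelist_id not in self.panel:
                raise SchemaError(
                    f"rating by {r.panelist_id!r} who is not on the panel roster"
                )
            key = (r.panelist_id, r.item_id)
            if key in by_key:
                raise SchemaError(f"duplicate rating for {key}")
            by_key[key] = r
        self._by_key = by_key

    # -- access ------------------------------------------------------------

    @property
    def ratings(self) -> tuple[Rating, ...]:
        return tuple(self._by_key[k] for k in sorted(self._by_key))

    def value(self, panelist_id: str, item_id: str) -> Optional[RatingValue]:
        """The stored value, or ``None`` when the pair is missing."""
        r = self._by_key.get((panelist_id, item_id))
        return None if r is None else r.value

    def comment(self, panelist_id: str, item_id: str) -> Optional[str]:
        r = self._by_key.get((panelist_id, item_id))
        return None if r is None else r.comment

    def item_ids(self) -> tuple[str, ...]:
        return tuple(sorted({item for _, item in self._by_key}))

    def numeric_scores(self, item_id: str) -> list[int]:
        """Evaluable (1-9) scores for one item, in sorted panelist order."""
        return [
            r.value
            for (p, i), r in sorted(self._by_key.items())
            if i == item_id and isinstance(r.value, int)
        ]

    def not_evaluable_count(self, item_id: str) -> int:
        return sum(
            1
            for (_, i), r in self._by_key.items()
            if i == item_id and r.is_not_evaluable
        )

    def comments_for_item(self, item_id: str) -> list[tuple[str, str]]:
        """(panelist_id, comment) pairs, sorted by panelist."""
        return [
            (p, r.comment)
            for (p, i), r in sorted(self._by_key.items())
            if i == item_id and r.comment
        ]

    @property
    def n_not_evaluable(self) -> int:
        return sum(1 for r in self._by_key.values() if r.is_not_evaluable)

    def n_missing(self, item_ids: Sequence[str]) -> int:
        """Missing pairs over the full panel × given item grid."""
        return sum(
            1
            for p in self.panel
            for i in item_ids
            if (p, i) not in self._by_key
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingMatrix):
            return NotImplemented
        return (
            self.round_label == other.round_label
            and self.panel == other.panel
            and self._by_key == other._by_key
        )

    def __len__(self) -> int:
        return len(self._by_key)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"RatingMatrix({self.round_label!r}, panel={len(self.panel)}, "
            f"ratings={len(self._by_key)})"
        )


class RankingSet:
    """Per-panelist ordered top-k question lists, keyed by (panelist, part)."""

    def __init__(
        self,
        round_label: str,
        entries: Mapping[tuple[str, str], Sequence[str]],
        questionnaire: Optional[QuestionnaireVersion] = None,
    ) -> None:
        self.round_label = round_label
        validated: dict[tuple[str, str], tuple[str, ...]] = {}
        for (panelist, part_id), qs in entries.items():
            qs = tuple(qs)
            if len(set(qs)) != len(qs):
                raise SchemaError(
                    f"duplicate question in ranking of {panelist!r} for part {part_id!r}"
                )
            if questionnaire is not None:
                part = questionnaire.part(part_id)
                if len(qs) > part.ranking_depth:
                    raise SchemaError(
                        f"ranking of {panelist!r} for part {part_id!r} has "
                        f"{len(qs)} entries, depth is {part.ranking_depth}"
                    )
                members = set(part.question_ids())
                for q in qs:
                    if q not in members:
                        raise SchemaError(
                            f"question {q!r} ranked by {panelist!r} does not "
                            f"belong to part {part_id!r}"
                        )
            validated[(panelist, part_id)] = qs
        self._entries = validated

    @property
    def entries(self) -> dict[tuple[str, str], tuple[str, ...]]:
        return dict(self._entries)

    def ranking(self, panelist_id: str, part_id: str) -> tuple[str, ...]:
        return self._entries.get((panelist_id, part_id), ())

    def rankings_for_part(self, part_id: str) -> list[tuple[str, tuple[str, ...]]]:
        return [
            (p, qs) for (p, pid), qs in sorted(self._entries.items()) if pid == part_id
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankingSet):
            return NotImplemented
        return (
            self.round_label == other.round_label and self._entries == other._entries
        )

    def __len__(self) -> int:
        return len(self._entries)


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

RATINGS_HEADER = ["panelist_id", "item_id", "score", "comment"]
RANKINGS_HEADER = ["panelist_id", "part_id", "ranked_questions"]
RESULTS_HEADER = [
    "item_id",
    "n_evaluable",
    "median",
    "frac_low",
    "frac_mid",
    "frac_high",
    "top_pct",
    "preselection",
    "consensus",
    "status",
]


def _check_header(actual: Optional[Sequence[str]], expected: Sequence[str], path) -> None:
    if actual is None or list(actual) != list(expected):
        raise ParseError(
            f"expected header {','.join(expected)!r}, got "
            f"{','.join(actual) if actual else '<empty file>'!r}",
            path=path,
            line=1,
        )


def read_ratings(
    path, panel_roster: Iterable[str], round_label: str = "round1"
) -> RatingMatrix:
    """Read a long-format ratings CSV into a validated :class:`RatingMatrix`.

    The ``score`` column holds an integer 1-9, the sentinel ``NE``
    (not evaluable), or is empty — an empty score cell with a comment still
    records the comment-less pair as missing and is rejected to avoid silent
    data loss.
    """
    path = Path(path)
    ratings: list[Rating] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, RATINGS_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RATINGS_HEADER):
                raise ParseError(
                    f"expected {len(RATINGS_HEADER)} fields, got {len(row)}",
                    path=path,
                    line=lineno,
                )
            panelist, item, score, comment = (cell.strip() for cell in row)
            if not panelist or not item:
                raise ParseError("empty panelist_id or item_id", path=path, line=lineno)
            if score == "":
                # a fully absent pair is simply not written; an explicit empty
                # score row is a recording error
                raise ParseError(
                    "empty score cell; omit the row for a missing rating",
                    path=path,
                    line=lineno,
                )
            if score == NE_TOKEN:
                value: RatingValue = NOT_EVALUABLE
            else:
                try:
                    value = int(score)
                except ValueError:
                    raise ParseError(
                        f"score {score!r} is neither an integer nor {NE_TOKEN!r}",
                        path=path,
                        line=lineno,
                    ) from None
            try:
                ratings.append(Rating(panelist, item, value, comment or None))
            except SchemaError as exc:
                raise SchemaError(f"{exc} (line {lineno} of {path})") from None
    return RatingMatrix(round_label, panel_roster, ratings)


def write_ratings(matrix: RatingMatrix, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RATINGS_HEADER)
        for r in matrix.ratings:
            score = NE_TOKEN if r.is_not_evaluable else str(r.value)
            writer.writerow([r.panelist_id, r.item_id, score, r.comment or ""])


def read_rankings(
    path, questionnaire: QuestionnaireVersion, round_label: str = "round1"
) -> RankingSet:
    """Read a rankings CSV; position in the semicolon list is the rank."""
    path = Path(path)
    entries: dict[tuple[str, str], tuple[str, ...]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, RANKINGS_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RANKINGS_HEADER):
                raise ParseError(
                    f"expected {len(RANKINGS_HEADER)} fields, got {len(row)}",
                    path=path,
                    line=lineno,
                )
            panelist, part_id, ranked = (cell.strip() for cell in row)
            key = (panelist, part_id)
            if key in entries:
                raise SchemaError(
                    f"duplicate ranking entry for {key} (line {lineno} of {path})"
                )
            qs = tuple(q.strip() for q in ranked.split(";") if q.strip())
            entries[key] = qs
    return RankingSet(round_label, entries, questionnaire)


def write_rankings(rankings: RankingSet, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RANKINGS_HEADER)
        for (panelist, part_id), qs in sorted(rankings.entries.items()):
            writer.writerow([panelist, part_id, ";".join(qs)])


def _questionnaire_to_obj(q: QuestionnaireVersion) -> dict:
    return json.loads(q.model_dump_json())


def read_questionnaire(path) -> QuestionnaireVersion:
    """Load a questionnaire version from YAML or JSON (by extension)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            obj = json.load(fh)
        else:
            obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ParseError("questionnaire file does not hold a mapping", path=path)
    try:
        return QuestionnaireVersion.model_validate(obj)
    except ValidationError as exc:
        raise SchemaError(f"invalid questionnaire in {path}: {exc}") from None


def write_questionnaire(q: QuestionnaireVersion, path) -> None:
    path = Path(path)
    obj = _questionnaire_to_obj(q)
    with path.open("w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(obj, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(obj, fh, sort_keys=False, allow_unicode=True)


@dataclass(frozen=True)
class ResultRecord:
    """One row of a results table (scores + verdict), as re-read from CSV."""

    item_id: str
    n_evaluable: int
    median: float
    frac_low: float
    frac_mid: float
    frac_high: float
    top_pct: float
    preselection: str
    consensus: str
    status: str


def write_results(rows: Iterable, path) -> None:
    """Write scored+classified items to ``results.csv``.

    ``rows`` yields ``(ItemScore, ItemVerdict)`` pairs (duck-typed to avoid
    an import cycle with the scoring/selection modules). Fractions and
    percentages are written to 6 decimal places so the file round-trips.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for score, verdict in rows:
            writer.writerow(
                [
                    score.item_id,
                    score.n_evaluable,
                    f"{score.median:.6f}",
                    f"{score.frac_low:.6f}",
                    f"{score.frac_mid:.6f}",
                    f"{score.frac_high:.6f}",
                    f"{score.top_pct:.6f}",
                    verdict.preselection.value,
                    verdict.consensus.value,
                    verdict.status.value,
                ]
            )


def read_results(path) -> list[ResultRecord]:
    path = Path(path)
    out: list[ResultRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, RESULTS_HEADER, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RESULTS_HEADER):
                raise ParseError(
                    f"expected {len(RESULTS_HEADER)} fields, got {len(row)}",
                    path=path,
                    line=lineno,
                )
            try:
                out.append(
                    ResultRecord(
                        item_id=row[0],
                        n_evaluable=int(row[1]),
                        median=float(row[2]),
                        frac_low=float(row[3]),
                        frac_mid=float(row[4]),
                        frac_high=float(row[5]),
                        top_pct=float(row[6]),
                        preselection=row[7],
                        consensus=row[8],
                        status=row[9],
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return out
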