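# Methods

## Scope and model

`delphikit` implements the quantitative core of a RAND-modified Delphi
exercise for questionnaire content validation. The workflow has five
stages — drafting, an individual rating round, a consensus meeting, a
final evaluation and the final questionnaire — of which the package
covers everything downstream of drafting: the drafted questionnaire
enters as a structured input file, and every later stage is either a
computation (scoring, triage, feedback) or an explicit, auditable human
decision (ledgers).

A questionnaire version is a tree: ordered *parts* (sections), each
with ordered *questions*, each with one or more ratable *items*.
A question without sub-statements has a single item whose id equals the
question id; sub-items use dotted ids (`23.7` is the 7th statement of
question 23). Ratings are per item; rankings are per question and per
part.

## Statistics

**Median.** Standard sample median of the evaluable scores; an even
count yields the mean of the two middle order statistics, so medians
may be half-integers.

**Tertile fractions.** The 9-point scale is split into equal thirds —
1–3 (lowest), 4–6 (middle), 7–9 (highest). This is the conventional
tertile split for 9-point appropriateness scales; the source rules
phrase the consensus criterion as a percentage of "median Likert
scores" in a tertile, which is only computable per item if it refers to
the individual panelists' scores (an item has exactly one median), and
that is how it is implemented.

**Prioritization (top) percentage.** Rank *r* in a top-*k* list earns
*k − r + 1* points (5/4/3/2/1 for top-5; the top-3 generalization
3/2/1 follows the same formula). The denominator is
`panel_size × k`, counting panelists who omitted the question — this is
forced by the published worked example, where 4 omitters still
contribute to the maximum of 70. `panel_size` is always an explicit
argument, never inferred from the ratings file, because a panel may
shrink between rounds (the emulated study lost one of fourteen members
after round 1) and the intended denominator is a design choice of the
analyst.

**Not evaluable vs missing.** An explicit "not evaluable" answer
(`NE` in files) and an absent rating are distinct states. Both are
excluded from median and tertile denominators — they never count as
low scores — but their counts are preserved separately through all I/O.

## Selection rules

Preselection (median × top %) and consensus (tertile fractions) are
applied independently; see README for the rule tables. Two reading
choices make the preselection rows a partition of the plane:
"top percentage ≥ 20 %" is inclusive, and "between 1–20 %" is the open
interval (0 %, 20 %), so a question never ranked by anyone (top = 0 %)
cannot be preselected regardless of median. Monotonicity in both
arguments and the no-gap/no-overlap property are enforced by tests over
a dense grid.

The combination of the two outcomes into a triage status is not fully
dictated by the source rules; the implemented policy is the strictest
one consistent with a three-colour triage — *selected* requires both
top categories, *not selected* requires both bottom categories,
everything else is *up for discussion*. All five cut-points live in a
`Thresholds` object (defaults: median 7, top 20 %, consensus 0.70,
discussion 0.30/0.30) so sensitivity analyses need no code change.

## Decision ledgers

The consensus meeting routinely overrides the automatic triage —
promoting orange or red items after rewording, dropping green ones —
so stage decisions are first-class input data, not something inferred
from verdicts. Ledger semantics:

- items without an explicit decision are **kept** (an empty ledger is
  the identity transform);
- `PROMOTE` is valid only for items whose incoming verdict is *up for
  discussion* or *not selected*, and requires verdicts to be supplied;
- `MODIFY` rewords an item or question and counts as kept — rewording
  never affects counts;
- `ADD` carries its payload (a whole question into a part, or an item
  into a question);
- a question whose items are all dropped is removed, as is an emptied
  part;
- conservation — `items_out = kept + promoted + added` and
  `dropped = items_in − kept − promoted` — is asserted on every
  application and property-tested over random ledgers.

### Shipped development-chain fixtures

The emulated study's chain is shipped under `delphikit/data/` and
replayed by `delphikit.datasets.development_chain()`:
57 items / 34 questions triaged 34 / 16 / 7 → consensus meeting (keep
31 of the 34 selected, drop 3 of them, promote 10 discussion + 2
not-selected items, add 1 question) → 44 items / 31 questions → final
evaluation (drop question 11) → 43 items / 30 questions.

Caveats, deliberately documented rather than silently resolved:

- The published report's abstract states 42 final items where its
  results section states 43 (and 43 vs 44 after the consensus round).
  The fixtures follow the results-section chain (44 → 43).
- The round-1 questionnaire and verdicts are **synthetic** stand-ins
  (filenames say so): the real item texts and raw ratings were never
  published. The structure, the ids of promoted/rescued/dropped items
  and the 34/16/7 totals follow the published account; unnamed items'
  statuses and the third selected-then-dropped item (only two of three
  are named) are invented — the fixture assigns it to `24.2`, which
  also makes exactly four questions lose all items, matching the
  published question counts.
- The final questionnaire fixture transcribes the published final
  instrument (30 questions / 43 items, five sections). Item origins in
  that fixture are coded `both` (the published mapping is not
  item-resolved) except the panel-added payment question.

## Feedback reports

One markdown report per panelist: per item, the full panel score
distribution as a 1–9 histogram plus NE count, the median and top
percentage, the triage colour, the recipient's own score (rendered
"not evaluable" or "no answer" where applicable) and comment, and the
other panelists' comments anonymized. Peer comments are shuffled with a
per-item RNG keyed on `crc32(seed:item_id)` so output is deterministic
across processes while the order carries no identity information.
Identical inputs render byte-identical files; a golden-file test pins
the format.

## Synthetic panel generator

The generator emulates the structure the rules assume, not any real
panel's behaviour:

- **Dimensions** default to the emulated study: 14 panelists, 34
  questions / 57 items in five parts (12/4/6/7/5 questions), one
  dropout after round 1. Sub-item placement mirrors the study's
  published numbering (questions 12, 14, 21, 23, 24, 27 carry 3, 5, 2,
  8, 2 and 9 items). Ranking depths are top-5 for the two largest parts
  and top-3 for the rest; the source only states that both depths were
  used, not which section used which.
- **Ratings** are drawn i.i.d. per (panelist, item) from the question's
  profile distribution over 1–9, with a global "not evaluable"
  probability (`ne_rate`, default 0.02 — a realistic few NE answers per
  round without dominating any item). There are no rater-severity or
  item-correlation effects, because the selection rules consume only
  marginal per-item distributions; rater effects are an extension
  point, and passing tests therefore say nothing about robustness to
  correlated raters.
- **Profiles.** Four stock profiles span the triage outcomes:
  `consensus_high` (≥ 0.9 mass on 7–9, latent relevance 1.0),
  `polarized` (0.40/0.20/0.40 across tertiles, relevance 0.45),
  `middling` (mass centred on 4–6, relevance 0.30) and `irrelevant`
  (0.9 mass on 1–6, relevance 0.05). The default assignment cycles a
  fixed pattern giving half the questions the agreeable profile.
- **Rankings** follow a Plackett–Luce model: each panelist's top-k per
  part is sampled by the Gumbel-max trick with weights
  `latent_relevance + 0.10` (the floor keeps zero-relevance questions
  rankable and injects per-panelist noise). More relevant questions
  thus earn stochastically higher top percentages (rank correlation
  > 0.5 in tests).
- **Determinism.** The seed is a mandatory config field; all draws go
  through one `numpy` generator in a fixed traversal order, so equal
  seeds give byte-identical files on any platform.

The **recovery experiment** runs generate → score → triage over
replicates (replicate *i* uses `seed + i`) and tabulates row-normalized
profile × status frequencies. A 5-replicate calibration of the default
configuration observed consensus_high → selected 0.98, irrelevant →
not_selected 0.95 (never selected), polarized → up_for_discussion 0.98;
the unit tests assert the looser bands 0.90 / 0.80 / 0.80, and the
20-replicate acceptance check asserts selected ≥ 0.90 for agreeable
questions and zero selections for irrelevant ones.

## Numerical and interface choices

- Tertile fractions are exact rational counts; the sum-to-one invariant
  is checked to 1e-9.
- Results CSV writes fractions and percentages to 6 decimal places;
  round-trip tests compare at 5e-7.
- Files are UTF-8 CSV (long format, mandatory header) and YAML/JSON for
  nested structures; ranked lists are semicolon-joined in one cell with
  position = rank.
- CLI exit codes: 2 for validation errors, 3 for I/O errors; data
  products go to files, logs to stderr.
- Problem sizes in tests (14 × 57 panels, 5–20 replicates, ~12,000
  draws for the distributional chi-square) were chosen as the smallest
  that exercise the study-scale code paths with stable statistics.

## Known limitations

- No inter-rater reliability statistics (kappa, ICC) and no alternative
  consensus definitions (IQR-based, percent agreement).
- The generator does not model panelists' comments, opinion shift
  between rounds, or panelist-specific severity.
- The exact combination rule used by any particular study team to
  colour items may differ from the strict policy implemented here; the
  policy is configurable only via code (subclassing/wrapping
  `classify`), not via the thresholds file.
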