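"""Survey judgments: the bipolar 9-1-9 scale and reciprocal pairwise matrices.

Respondents express each comparison on a bipolar scale running from 9
(extreme dominance of the left item) through 1 (equality) to 9 (extreme
dominance of the right item). A judgment decodes to a ratio ``a_lr``: the
score itself when the left item is favored, its reciprocal when the right one
is. Complete sibling comparisons become full reciprocal matrices; the
innovation block of the hospital IT study is a *star design* — every
innovation is compared only against the "current care" baseline — whose
matrix is completed by transitivity through the hub and is therefore
perfectly consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SurveyError

#: Default label of the comparison hub in the innovation block.
BASELINE = "current_care"

#: Required survey CSV columns.
SURVEY_COLUMNS = ("respondent_id", "group", "context", "left", "right", "favored", "score")

_FAVORED = frozenset({"left", "right", "neither"})


@dataclass(frozen=True)
class Respondent:
    """A survey respondent belonging to one stakeholder group."""

    id: str
    group: str


@dataclass(frozen=True)
class ComparisonJudgment:
    """One pairwise judgment.

    ``context`` is ``"criteria:<parent id>"`` for sibling-criteria
    comparisons (``criteria:goal`` for the main criteria) or
    ``"innovation:<leaf id>"`` for an innovation-vs-baseline comparison under
    that leaf criterion. ``score`` is an integer 1-9 on the survey instrument;
    simulated non-discretized judgments may carry a float in [1, 9].
    """

    respondent_id: str
    context: str
    left: str
    right: str
    favored: str
    score: float

    def __post_init__(self) -> None:
        if self.favored not in _FAVORED:
            raise SurveyError(f"favored must be left/right/neither, got {self.favored!r}")
        if not (1.0 <= self.score <= 9.0):
            raise SurveyError(f"score must lie in [1, 9], got {self.score!r}")
        if self.favored == "neither" and self.score != 1:
            raise SurveyError("favored='neither' requires score 1")

    @property
    def ratio(self) -> float:
        """The encoded ratio a_left,right."""
        return encode_bipolar(self.favored, self.score)


def encode_bipolar(favored: str, score: float) -> float:
    """Decode a bipolar-scale judgment into the ratio a_left,right.

    ``favored='left'`` gives the score itself, ``'right'`` its reciprocal and
    ``'neither'`` (only legal with score 1) gives 1.
    """
    if favored not in _FAVORED:
        raise SurveyError(f"favored must be left/right/neither, got {favored!r}")
    if not (1.0 <= score <= 9.0):
        raise SurveyError(f"score must lie in [1, 9], got {score!r}")
    if favored == "neither":
        if score != 1:
            raise SurveyError("favored='neither' requires score 1")
        return 1.0
    return float(score) if favored == "left" else 1.0 / float(score)


def decode_ratio(ratio: float) -> tuple[str, float]:
    """Inverse of :func:`encode_bipolar`: ratio -> (favored, score >= 1)."""
    if ratio <= 0:
        raise SurveyError(f"ratio must be positive, got {ratio!r}")
    if ratio == 1:
        return "neither", 1.0
    return ("left", float(ratio)) if ratio > 1 else ("right", 1.0 / ratio)


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal judgment matrix over an ordered item set."""

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        n = len(self.items)
        if n < 2:
            raise DesignError("a pairwise matrix needs at least 2 items")
        if a.shape != (n, n):
            raise DesignError(f"matrix shape {a.shape} does not match {n} items")
        if not np.all(a > 0):
            raise DesignError("pairwise matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise DesignError("pairwise matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-12):
            raise DesignError("pairwise matrix violates reciprocity a_ij*a_ji=1")

    @property
    def n(self) -> int:
        return len(self.items)

    def permuted(self, order: Sequence[int]) -> "PairwiseMatrix":
        idx = np.asarray(order)
        return PairwiseMatrix(
            items=tuple(self.items[i] for i in idx), values=self.values[np.ix_(idx, idx)]
        )


def parse_survey(
    source, *, groups: Iterable[str] | None = None
) -> tuple[list[Respondent], list[ComparisonJudgment]]:
    """Read a long-format survey CSV into typed records.

    One judgment per row; header columns ``respondent_id, group, context,
    left, right, favored, score``. Scores must be integers 1-9. All row-level
    problems (bad score, unknown group when ``groups`` is given, duplicate
    judgment for the same respondent/context/pair) are collected and raised
    together as a :class:`SurveyError` naming the offending rows; nothing is
    silently dropped or overwritten.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyError(f"survey file misses required columns: {missing}")

    group_set = set(groups) if groups is not None else None
    errors: list[str] = []
    respondents: dict[str, Respondent] = {}
    judgments: list[ComparisonJudgment] = []
    seen: set[tuple[str, str, frozenset]] = set()

    for row_idx, row in enumerate(df.itertuples(index=False)):
        problems = []
        try:
            score = int(row.score)
            if not 1 <= score <= 9:
                raise ValueError
        except ValueError:
            problems.append(f"score {row.score!r} not an integer in 1-9")
            score = 1
        if group_set is not None and row.group not in group_set:
            problems.append(f"unknown group {row.group!r}")
        if row.favored not in _FAVORED:
            problems.append(f"favored {row.favored!r} not left/right/neither")
        elif row.favored == "neither" and score != 1:
            problems.append("favored='neither' with score > 1")
        key = (row.respondent_id, row.context, frozenset((row.left, row.right)))
        if not problems and key in seen:
            problems.append(
                f"duplicate judgment for respondent {row.respondent_id!r}, "
                f"context {row.context!r}, pair ({row.left!r}, {row.right!r})"
            )
        if problems:
            errors.extend(f"row {row_idx}: {p}" for p in problems)
            continue
        seen.add(key)
        prev = respondents.get(row.respondent_id)
        if prev is not None and prev.group != row.group:
            errors.append(
                f"row {row_idx}: respondent {row.respondent_id!r} listed in two "
                f"groups ({prev.group!r} and {row.group!r})"
            )
            continue
        if prev is None:
            respondents[row.respondent_id] = Respondent(id=row.respondent_id, group=row.group)
        judgments.append(
            ComparisonJudgment(
                respondent_id=row.respondent_id, context=row.context,
                left=row.left, right=row.right, favored=row.favored, score=score,
            )
        )

    if errors:
        raise SurveyError("rejected survey rows:\n  " + "\n  ".join(errors))
    return list(respondents.values()), judgments


def build_matrix(
    judgments: Iterable[ComparisonJudgment], items: Sequence[str]
) -> PairwiseMatrix:
    """Assemble a complete reciprocal matrix from one judgment per item pair.

    Incomplete designs are rejected (no imputation): a :class:`DesignError`
    lists every missing pair. Judgments whose pair is not in ``items`` are
    likewise an error.
    """
    items = tuple(items)
    index = {item: i for i, item in enumerate(items)}
    a = np.eye(len(items))
    seen: set[frozenset] = set()
    for j in judgments:
        if j.left not in index or j.right not in index:
            raise DesignError(f"judgment pair ({j.left!r}, {j.right!r}) not in items {items}")
        key = frozenset((j.left, j.right))
        if key in seen:
            raise DesignError(f"duplicate judgment for pair ({j.left!r}, {j.right!r})")
        seen.add(key)
        r = j.ratio
        li, ri = index[j.left], index[j.right]
        a[li, ri] = r
        a[ri, li] = 1.0 / r
    missing = [
        (x, y) for x, y in combinations(items, 2) if frozenset((x, y)) not in seen
    ]
    if missing:
        raise DesignError(f"incomplete design; missing pairs: {missing}")
    return PairwiseMatrix(items=items, values=a)


def star_ratios(
    judgments: Iterable[ComparisonJudgment],
    innovations: Sequence[str],
    baseline: str = BASELINE,
) -> np.ndarray:
    """Extract the ratio vector a_i0 (innovation i vs baseline hub).

    Accepts judgments in either orientation; exactly one per innovation.
    """
    ratios: dict[str, float] = {}
    for j in judgments:
        pair = {j.left, j.right}
        if baseline not in pair:
            raise DesignError(f"star judgment ({j.left!r}, {j.right!r}) lacks the baseline")
        (other,) = pair - {baseline} if len(pair) == 2 else (baseline,)
        if other not in innovations:
            raise DesignError(f"unknown innovation {other!r} in star judgment")
        if other in ratios:
            raise DesignError(f"duplicate star judgment for {other!r}")
        r = j.ratio
        ratios[other] = r if j.left == other else 1.0 / r
    missing = [i for i in innovations if i not in ratios]
    if missing:
        raise DesignError(f"missing star judgments for innovations: {missing}")
    return np.array([ratios[i] for i in innovations])


def star_matrix(
    judgments: Iterable[ComparisonJudgment],
    innovations: Sequence[str],
    baseline: str = BASELINE,
) -> PairwiseMatrix:
    """Complete the star design into a full (m+1) x (m+1) reciprocal matrix.

    Items are ordered ``(baseline, *innovations)``. Off-hub entries follow by
    transitivity through the hub, ``a_ij = a_i0 / a_j0``, so the completed
    matrix is rank-one consistent by construction and its consistency ratio
    is identically 0.
    """
    r = star_ratios(judgments, innovations, baseline)
    col = np.concatenate(([1.0], r))  # ratios vs baseline, hub first
    a = np.outer(col, 1.0 / col)
    np.fill_diagonal(a, 1.0)
    return PairwiseMatrix(items=(baseline, *tuple(innovations)), values=a)


def judgments_per_respondent(
    judgments: Iterable[ComparisonJudgment],
) -> dict[str, list[ComparisonJudgment]]:
    """Group judgments by respondent id, preserving order."""
    out: dict[str, list[ComparisonJudgment]] = {}
    for j in judgments:
        out.setdefault(j.respondent_id, []).append(j)
    return out
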