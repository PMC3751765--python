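"""Group aggregation and hierarchical synthesis.

One group judgment matrix per sibling set is formed by aggregating the
individual judgment matrices (AIJ — aggregation of individual judgments;
entrywise geometric mean by default, which preserves reciprocity exactly).
Group criterion weights come from the principal eigenvector of each
aggregated criteria matrix; per-leaf innovation priorities come from the
aggregated star ratios; the overall priority of an innovation is the
weighted sum of its per-leaf priorities with the global leaf weights.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .hierarchy import Hierarchy, global_leaf_weights
from .judgments import (
    BASELINE,
    ComparisonJudgment,
    PairwiseMatrix,
    Respondent,
    build_matrix,
    judgments_per_respondent,
    star_ratios,
)
from .priority_engine import (
    DEFAULT_CR_THRESHOLD,
    ConsistencyReport,
    PriorityVector,
    consistency,
    principal_eigenvector,
    star_priorities,
)

logger = logging.getLogger("ahpgroup")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table formatting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_judgments(
    matrices: Sequence[PairwiseMatrix], method: str = "geometric"
) -> PairwiseMatrix:
    """Aggregate individual judgment matrices into one group matrix.

    ``geometric`` (default) takes the entrywise geometric mean, which keeps
    the result exactly reciprocal. ``arithmetic`` averages the upper-triangle
    entries and restores reciprocity by setting ``a_ji = 1/a_ij``; it is
    offered for sensitivity analysis only.
    """
    if not matrices:
        raise DesignError("need at least one matrix to aggregate")
    items = matrices[0].items
    for m in matrices[1:]:
        if m.items != items:
            raise DesignError(f"mismatched item sets: {m.items} vs {items}")
    stack = np.stack([m.values for m in matrices])
    if method == "geometric":
        agg = np.exp(np.mean(np.log(stack), axis=0))
    elif method == "arithmetic":
        mean = np.mean(stack, axis=0)
        agg = np.triu(mean, k=1)
        agg = agg + np.divide(1.0, agg.T, out=np.zeros_like(agg), where=agg.T > 0)
    else:
        raise DesignError(f"unknown aggregation method {method!r}")
    np.fill_diagonal(agg, 1.0)
    # symmetrize away float noise so the reciprocity invariant holds exactly
    iu = np.triu_indices(len(items), k=1)
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    return PairwiseMatrix(items=items, values=agg)


def synthesize(
    leaf_weights: Mapping[str, float],
    leaf_priorities: Mapping[str, PriorityVector],
) -> PriorityVector:
    """Weighted-sum synthesis of per-criterion priorities into overall ones.

    ``overall_i = sum_leaf w_leaf * p_i|leaf``; requires the leaf weights to
    sum to 1 and every leaf's priority vector to share one item set.
    """
    if set(leaf_weights) != set(leaf_priorities):
        raise DesignError("leaf weight map and leaf priorities cover different leaves")
    total = math.fsum(leaf_weights.values())
    if abs(total - 1.0) > 1e-8:
        raise DesignError(f"global leaf weights sum to {total}, expected 1")
    leaves = list(leaf_weights)
    items = leaf_priorities[leaves[0]].items
    overall = np.zeros(len(items))
    for leaf in leaves:
        pv = leaf_priorities[leaf]
        if pv.items != items:
            raise DesignError(f"item set mismatch under leaf {leaf!r}")
        overall += leaf_weights[leaf] * pv.weights
    return PriorityVector(items=items, weights=overall, lambda_max=math.nan)


@dataclass(frozen=True)
class GroupResult:
    """Derived quantities for one stakeholder group."""

    group: str
    n_respondents: int
    local_weights: dict[str, float]
    global_weights: dict[str, float]
    main_weights: PriorityVector
    leaf_priorities: dict[str, PriorityVector]
    overall: PriorityVector
    consistency: dict[str, ConsistencyReport]


@dataclass(frozen=True)
class StudyResult:
    """Full study output: per-group weights, priorities and diagnostics."""

    hierarchy: Hierarchy
    innovations: tuple[str, ...]
    baseline: str
    groups: dict[str, GroupResult]
    excluded: tuple[tuple[str, str], ...]
    aggregation: str
    cr_threshold: float

    def criteria_table(self, rounded: bool = False) -> pd.DataFrame:
        """Local criterion weights, criteria as rows (depth-first), groups as columns."""
        rows = [n.id for n in self.hierarchy]
        data = {}
        for g, res in self.groups.items():
            col = [res.local_weights[r] for r in rows]
            data[g] = [round_half_up(v) for v in col] if rounded else col
        return pd.DataFrame(data, index=rows)

    def priority_table(
        self, rounded: bool = False, drop_baseline: bool = False
    ) -> pd.DataFrame:
        """Overall innovation priorities (baseline row first), groups as columns.

        ``drop_baseline`` removes the baseline row and renormalizes each
        column over the innovations alone.
        """
        data = {}
        for g, res in self.groups.items():
            w = res.overall.weights
            if drop_baseline:
                w = w[1:] / w[1:].sum()
            col = w.tolist()
            data[g] = [round_half_up(v) for v in col] if rounded else col
        index = list(self.innovations) if drop_baseline else [self.baseline, *self.innovations]
        return pd.DataFrame(data, index=index)

    def to_dict(self) -> dict:
        out: dict = {
            "goal": self.hierarchy.goal,
            "aggregation": self.aggregation,
            "cr_threshold": self.cr_threshold,
            "baseline": self.baseline,
            "innovations": list(self.innovations),
            "excluded_respondents": [list(e) for e in self.excluded],
            "groups": {},
        }
        for g, res in self.groups.items():
            out["groups"][g] = {
                "n_respondents": res.n_respondents,
                "local_weights": res.local_weights,
                "global_leaf_weights": res.global_weights,
                "leaf_priorities": {
                    leaf: pv.as_dict() for leaf, pv in res.leaf_priorities.items()
                },
                "overall_priorities": res.overall.as_dict(),
                "consistency": {
                    key: {
                        "n": rep.n, "CI": rep.ci, "RI": rep.ri, "CR": rep.cr,
                        "acceptable": rep.acceptable, "threshold": rep.threshold,
                    }
                    for key, rep in res.consistency.items()
                },
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        """Deterministic JSON serialization (sorted keys, full precision)."""
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


class CompiledStudy:
    """Per-respondent log-scale judgment arrays, ready for (re)aggregation.

    Compiling once and aggregating over index subsets is what makes the
    bootstrap affordable: a replicate is a mean of log matrices over resampled
    respondents, not a re-parse of the survey.
    """

    def __init__(
        self,
        respondents: Sequence[Respondent],
        judgments: Iterable[ComparisonJudgment],
        hierarchy: Hierarchy,
        innovations: Sequence[str] | None = None,
        baseline: str = BASELINE,
        on_incomplete: str = "warn",
    ) -> None:
        if on_incomplete not in ("warn", "error"):
            raise DesignError("on_incomplete must be 'warn' or 'error'")
        self.hierarchy = hierarchy
        self.baseline = baseline
        self.sibling_sets = hierarchy.sibling_sets()
        by_respondent = judgments_per_respondent(judgments)

        if innovations is None:
            innovations = _infer_innovations(judgments=by_respondent, baseline=baseline)
        self.innovations = tuple(innovations)

        crit_logs: dict[str, list[np.ndarray]] = {p: [] for p in self.sibling_sets}
        star_logs: dict[str, list[np.ndarray]] = {l: [] for l in hierarchy.leaf_ids}
        ids: list[str] = []
        groups: dict[str, list[int]] = {}
        excluded: list[tuple[str, str]] = []

        for resp in respondents:
            rows = by_respondent.get(resp.id, [])
            try:
                crit, star = self._compile_one(rows)
            except DesignError as err:
                if on_incomplete == "error":
                    raise DesignError(f"respondent {resp.id!r}: {err}") from err
                logger.warning("excluding respondent %s: %s", resp.id, err)
                excluded.append((resp.id, str(err)))
                continue
            idx = len(ids)
            ids.append(resp.id)
            groups.setdefault(resp.group, []).append(idx)
            for p, m in crit.items():
                crit_logs[p].append(m)
            for leaf, r in star.items():
                star_logs[leaf].append(r)

        self.respondent_ids = tuple(ids)
        self.group_indices = {g: np.array(ix) for g, ix in groups.items()}
        self.excluded = tuple(excluded)
        self.crit_logs = {p: np.stack(v) if v else np.empty((0, 0, 0)) for p, v in crit_logs.items()}
        self.star_logs = {l: np.stack(v) if v else np.empty((0, 0)) for l, v in star_logs.items()}

    def _compile_one(
        self, rows: Sequence[ComparisonJudgment]
    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        by_context: dict[str, list[ComparisonJudgment]] = {}
        for j in rows:
            by_context.setdefault(j.context, []).append(j)
        crit: dict[str, np.ndarray] = {}
        for parent, children in self.sibling_sets.items():
            ctx = f"criteria:{parent}"
            if ctx not in by_context:
                raise DesignError(f"no judgments for context {ctx!r}")
            crit[parent] = np.log(build_matrix(by_context[ctx], children).values)
        star: dict[str, np.ndarray] = {}
        for leaf in self.hierarchy.leaf_ids:
            ctx = f"innovation:{leaf}"
            if ctx not in by_context:
                raise DesignError(f"no judgments for context {ctx!r}")
            star[leaf] = np.log(
                star_ratios(by_context[ctx], self.innovations, self.baseline)
            )
        return crit, star

    def derive(
        self,
        idx: np.ndarray,
        group: str = "",
        aggregation: str = "geometric",
        cr_threshold: float = DEFAULT_CR_THRESHOLD,
    ) -> GroupResult:
        """Aggregate the respondents at positions ``idx`` and derive results."""
        idx = np.asarray(idx)
        if idx.size == 0:
            raise DesignError("cannot derive results from zero respondents")
        reports: dict[str, ConsistencyReport] = {}
        local: dict[str, float] = {}
        main_pv: PriorityVector | None = None
        for parent, children in self.sibling_sets.items():
            m = self._aggregate_matrix(self.crit_logs[parent][idx], children, aggregation)
            pv = principal_eigenvector(m)
            reports[f"criteria:{parent}"] = consistency(pv, cr_threshold)
            for item, w in pv.as_dict().items():
                local[item] = w
            if parent == next(iter(self.sibling_sets)):
                main_pv = pv
        gw = global_leaf_weights(self.hierarchy, local)

        leaf_pvs: dict[str, PriorityVector] = {}
        items = (self.baseline, *self.innovations)
        for leaf in self.hierarchy.leaf_ids:
            logs = self.star_logs[leaf][idx]
            if aggregation == "geometric":
                pv = star_priorities(np.exp(np.mean(logs, axis=0)), items=items,
                                     baseline=self.baseline)
            else:
                mats = [
                    PairwiseMatrix(items=items, values=_star_values(np.exp(v)))
                    for v in logs
                ]
                pv = principal_eigenvector(aggregate_judgments(mats, aggregation))
            leaf_pvs[leaf] = pv
            reports[f"innovation:{leaf}"] = consistency(pv, cr_threshold)
        overall = synthesize(gw, leaf_pvs)
        return GroupResult(
            group=group, n_respondents=int(idx.size), local_weights=local,
            global_weights=gw, main_weights=main_pv, leaf_priorities=leaf_pvs,
            overall=overall, consistency=reports,
        )

    @staticmethod
    def _aggregate_matrix(
        logs: np.ndarray, items: tuple[str, ...], aggregation: str
    ) -> PairwiseMatrix:
        if aggregation == "geometric":
            agg = np.exp(np.mean(logs, axis=0))
            np.fill_diagonal(agg, 1.0)
            iu = np.triu_indices(len(items), k=1)
            agg[(iu[1], iu[0])] = 1.0 / agg[iu]
            return PairwiseMatrix(items=items, values=agg)
        mats = [PairwiseMatrix(items=items, values=np.exp(v)) for v in logs]
        return aggregate_judgments(mats, aggregation)


def _star_values(ratios: np.ndarray) -> np.ndarray:
    col = np.concatenate(([1.0], ratios))
    a = np.outer(col, 1.0 / col)
    np.fill_diagonal(a, 1.0)
    return a


def _infer_innovations(judgments: Mapping[str, list], baseline: str) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for rows in judgments.values():
        for j in rows:
            if j.context.startswith("innovation:"):
                for item in (j.left, j.right):
                    if item != baseline and item not in seen:
                        seen[item] = None
    if not seen:
        raise DesignError("survey contains no innovation comparisons")
    return tuple(seen)


def run_study(
    respondents: Sequence[Respondent],
    judgments: Iterable[ComparisonJudgment],
    hierarchy: Hierarchy,
    innovations: Sequence[str] | None = None,
    baseline: str = BASELINE,
    aggregation: str = "geometric",
    cr_threshold: float = DEFAULT_CR_THRESHOLD,
    on_incomplete: str = "warn",
) -> StudyResult:
    """Run the full group pipeline on a parsed survey.

    Per stakeholder group: aggregate the criteria matrices and derive weights,
    aggregate the star ratios per leaf criterion and derive innovation
    priorities, then synthesize overall priorities. Respondents with an
    incomplete design are excluded with a logged warning (``on_incomplete=
    'error'`` raises instead). High consistency ratios produce warnings in the
    attached reports, never a failure. Deterministic given its input.
    """
    compiled = CompiledStudy(
        respondents, judgments, hierarchy,
        innovations=innovations, baseline=baseline, on_incomplete=on_incomplete,
    )
    groups: dict[str, GroupResult] = {}
    for g, idx in compiled.group_indices.items():
        res = compiled.derive(idx, group=g, aggregation=aggregation,
                              cr_threshold=cr_threshold)
        for key, rep in res.consistency.items():
            if not rep.acceptable:
                logger.warning(
                    "group %s, %s: CR %.3f exceeds threshold %.2f",
                    g, key, rep.cr, cr_threshold,
                )
        logger.info("group %s: %d respondents", g, res.n_respondents)
        groups[g] = res
    return StudyResult(
        hierarchy=hierarchy, innovations=compiled.innovations, baseline=baseline,
        groups=groups, excluded=compiled.excluded, aggregation=aggregation,
        cr_threshold=cr_threshold,
    )
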