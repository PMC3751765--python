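"""Within-group dispersion and bootstrap confidence intervals.

The group pipeline yields one point estimate per group; the spread of
opinion behind it is described two ways. Per-respondent overall priorities
(the full derivation chain run on each individual alone) summarize as
box-plot statistics. Nonparametric percentile bootstrap over respondents —
resample the group's respondents with replacement, rerun the whole AIJ
pipeline per replicate — yields confidence intervals for group priorities
and for differences between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .hierarchy import Hierarchy
from .judgments import BASELINE, ComparisonJudgment, Respondent
from .priority_engine import DEFAULT_CR_THRESHOLD, PriorityVector
from .group_synthesis import CompiledStudy

logger = logging.getLogger("ahpgroup")

#: Default bootstrap replicate count.
DEFAULT_B = 10_000


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap interval for one scalar quantity.

    ``draws`` keeps the replicate values so results can be compared (paired
    differences reuse the same resample schedule). ``significant`` is set only
    on difference results and flags an interval excluding zero.
    """

    item: str
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    b: int
    seed: int | None
    draws: np.ndarray
    significant: bool | None = None


def individual_overall_priorities(
    respondents: Sequence[Respondent],
    judgments: Iterable[ComparisonJudgment],
    hierarchy: Hierarchy,
    innovations: Sequence[str] | None = None,
    baseline: str = BASELINE,
) -> dict[str, PriorityVector]:
    """Overall priorities derived per respondent (no group aggregation).

    Runs weight derivation and synthesis on each individual's own judgment
    matrices; incomplete respondents are excluded with a warning. In general
    the mean of these vectors differs from the AIJ group vector — both views
    are informative.
    """
    compiled = CompiledStudy(
        respondents, judgments, hierarchy, innovations=innovations, baseline=baseline
    )
    out: dict[str, PriorityVector] = {}
    for i, rid in enumerate(compiled.respondent_ids):
        out[rid] = compiled.derive(np.array([i])).overall
    return out


def dispersion_summary(
    respondents: Sequence[Respondent],
    judgments: Iterable[ComparisonJudgment],
    hierarchy: Hierarchy,
    innovations: Sequence[str] | None = None,
    baseline: str = BASELINE,
) -> pd.DataFrame:
    """Box-plot statistics of individual overall priorities per group and item.

    Quartiles use linear interpolation; whiskers follow the 1.5 x IQR rule
    (most extreme observation within the fences); values beyond the whiskers
    are listed as outliers.
    """
    compiled = CompiledStudy(
        respondents, judgments, hierarchy, innovations=innovations, baseline=baseline
    )
    indiv = {
        rid: compiled.derive(np.array([i])).overall
        for i, rid in enumerate(compiled.respondent_ids)
    }
    group_of = {r.id: r.group for r in respondents}
    items = (compiled.baseline, *compiled.innovations)
    rows = []
    by_group: dict[str, list[np.ndarray]] = {}
    for rid, pv in indiv.items():
        by_group.setdefault(group_of[rid], []).append(pv.weights)
    for g, vecs in by_group.items():
        arr = np.stack(vecs)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], axis=0)
        iqr = q3 - q1
        for k, item in enumerate(items):
            col = arr[:, k]
            lo_fence, hi_fence = q1[k] - 1.5 * iqr[k], q3[k] + 1.5 * iqr[k]
            inside = col[(col >= lo_fence) & (col <= hi_fence)]
            rows.append({
                "group": g, "item": item, "n": len(col),
                "median": med[k], "q1": q1[k], "q3": q3[k],
                "whisker_low": inside.min(), "whisker_high": inside.max(),
                "outliers": sorted(col[(col < lo_fence) | (col > hi_fence)].tolist()),
            })
    return pd.DataFrame(rows)


def bootstrap_group(
    respondents: Sequence[Respondent],
    judgments: Iterable[ComparisonJudgment],
    hierarchy: Hierarchy,
    group: str,
    b: int = DEFAULT_B,
    level: float = 0.95,
    seed: int | None = None,
    innovations: Sequence[str] | None = None,
    baseline: str = BASELINE,
    aggregation: str = "geometric",
) -> dict[str, BootstrapResult]:
    """Percentile bootstrap of one group's overall innovation priorities.

    Resamples the group's complete respondents with replacement ``b`` times,
    recomputes the full AIJ pipeline per replicate and returns one
    :class:`BootstrapResult` per item (baseline included). All items of one
    call share the same resample schedule, so within-group comparisons via
    :func:`compare` are paired. Fully reproducible from ``seed``.
    """
    if b < 1:
        raise DesignError("bootstrap needs at least 1 replicate")
    if not 0 < level < 1:
        raise DesignError(f"confidence level must be in (0, 1), got {level}")
    compiled = CompiledStudy(
        respondents, judgments, hierarchy, innovations=innovations, baseline=baseline
    )
    if group not in compiled.group_indices:
        raise DesignError(f"no complete respondents in group {group!r}")
    idx = compiled.group_indices[group]
    n = idx.size
    if n < 2:
        raise DesignError(f"group {group!r} has {n} respondent(s); bootstrap needs >= 2")

    estimate = compiled.derive(idx, group=group, aggregation=aggregation).overall
    rng = np.random.default_rng(seed)
    draws = np.empty((b, estimate.n))
    for rep in range(b):
        resample = idx[rng.integers(0, n, size=n)]
        draws[rep] = compiled.derive(resample, group=group, aggregation=aggregation).overall.weights

    alpha = 1.0 - level
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return {
        item: BootstrapResult(
            item=item, estimate=float(estimate.weights[k]),
            ci_low=float(lo[k]), ci_high=float(hi[k]),
            level=level, b=b, seed=seed, draws=draws[:, k],
        )
        for k, item in enumerate(estimate.items)
    }


def compare(a: BootstrapResult, b: BootstrapResult, paired: bool = True) -> BootstrapResult:
    """Bootstrap interval for the difference ``a - b``.

    ``paired=True`` is for two quantities bootstrapped on the *same* resample
    schedule (e.g. two innovations within one group); ``paired=False`` for
    independently resampled groups. Either way the replicate differences are
    taken elementwise, so the two results must have equal ``b`` and level.
    The ``significant`` flag is set when the interval excludes 0.
    """
    if a.b != b.b:
        raise DesignError(f"replicate counts differ: {a.b} vs {b.b}")
    if a.level != b.level:
        raise DesignError(f"confidence levels differ: {a.level} vs {b.level}")
    if paired and a.seed != b.seed:
        raise DesignError("paired comparison requires a shared resample schedule (same seed)")
    diff = a.draws - b.draws
    alpha = 1.0 - a.level
    lo, hi = np.percentile(diff, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        item=f"{a.item} - {b.item}", estimate=a.estimate - b.estimate,
        ci_low=float(lo), ci_high=float(hi), level=a.level, b=a.b, seed=a.seed,
        draws=diff, significant=not (lo <= 0.0 <= hi),
    )
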