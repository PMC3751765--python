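"""Simulated preference studies with known ground truth.

The generator emulates the elicitation design the pipeline expects: each
respondent judges every criteria pair of every sibling set plus one
innovation-vs-baseline comparison per innovation per leaf criterion (9
criteria judgments and 63 innovation judgments in the default scenario).
Judgments are the group's true ratios perturbed by multiplicative log-normal
noise on the elicited magnitude and, optionally, snapped to the discrete
1-9 instrument scale; the ground truth each study was sampled from is
recorded so recovery can be measured exactly.

The default scenario mirrors the reference hospital IT study shipped in
:mod:`ahpgroup.datasets`: six stakeholder groups of sizes 15/22/9/9/5/6,
seven leaf criteria, nine innovations vs a current-care baseline, with the
groups' published weights and priorities (renormalized exactly) as truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets
from .errors import ConfigurationError, DesignError
from .hierarchy import Hierarchy, global_leaf_weights, validate_weights
from .judgments import BASELINE, ComparisonJudgment, Respondent, SURVEY_COLUMNS
from .priority_engine import PriorityVector, star_priorities
from .group_synthesis import synthesize

#: Default log-scale noise level; gives individual 4x4 consistency ratios in
#: the low-tenths range typical of real criteria panels.
DEFAULT_SIGMA = 0.3

_LOG_SCORES = np.log(np.arange(1, 10))


def perturb_ratio(
    true_ratio: float, sigma: float, rng: np.random.Generator, discretize: bool = True
) -> tuple[str, float]:
    """Perturb a true ratio and express it as a survey judgment.

    Noise is applied to the judgment magnitude ``max(r, 1/r)`` on the log
    scale — ``exp(log m + eps)`` with ``eps ~ Normal(0, sigma^2)`` — and the
    favored side is reattached afterwards, so perturbing ``x`` and ``1/x``
    with the same random stream yields exactly reciprocal judgments. With
    ``discretize=True`` the result snaps to the nearest instrument value
    (1-9 or a reciprocal, nearest in log space) and returns an integer score;
    otherwise the float ratio is clipped to the instrument range [1/9, 9] and
    returned as a (favored, score) pair with a float score.
    """
    if true_ratio <= 0:
        raise ConfigurationError(f"true ratio must be positive, got {true_ratio!r}")
    if sigma < 0:
        raise ConfigurationError(f"sigma must be >= 0, got {sigma}")
    sign = 1.0 if true_ratio >= 1.0 else -1.0
    mag = true_ratio if sign > 0 else 1.0 / true_ratio  # elicited magnitude >= 1
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    log_ratio = sign * (np.log(mag) + eps)
    if discretize:
        score = int(1 + np.argmin(np.abs(np.abs(log_ratio) - _LOG_SCORES)))
        if score == 1:
            return "neither", 1
        return ("left", score) if log_ratio > 0 else ("right", score)
    # continuous path: keep the magnitude exact when eps == 0 (no log round
    # trip) and truncate at the instrument extreme
    out_mag = mag if eps == 0.0 else float(np.exp(abs(log_ratio)))
    out_mag = min(out_mag, 9.0)
    if out_mag == 1.0 or log_ratio == 0.0:
        return "neither", 1.0
    return ("left", out_mag) if log_ratio > 0 else ("right", out_mag)


@dataclass(frozen=True)
class GroupTruth:
    """Ground truth for one simulated group."""

    local_weights: dict[str, float]
    global_weights: dict[str, float]
    leaf_priorities: dict[str, PriorityVector]
    overall: PriorityVector


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one study.

    ``true_local_weights`` maps group -> node id -> local weight (each sibling
    set summing to 1); ``true_ratios`` maps group -> leaf id -> vector of
    innovation-vs-baseline ratios. ``noise_sigma`` is the standard deviation
    of the log-magnitude perturbation; ``discretize`` snaps judgments to the
    integer 1-9 scale (required for CSV round-trips).
    """

    groups: tuple[tuple[str, int], ...]
    hierarchy: Hierarchy
    true_local_weights: Mapping[str, Mapping[str, float]]
    true_ratios: Mapping[str, Mapping[str, np.ndarray]]
    innovations: tuple[str, ...]
    baseline: str = BASELINE
    noise_sigma: float = DEFAULT_SIGMA
    discretize: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        for g, n in self.groups:
            if n < 1:
                raise ConfigurationError(f"group {g!r} must have >= 1 respondents")
            if g not in self.true_local_weights:
                raise ConfigurationError(f"no true local weights for group {g!r}")
            rep = validate_weights(self.hierarchy, self.true_local_weights[g], tol=1e-6)
            if not rep.ok:
                raise ConfigurationError(
                    f"true local weights for group {g!r} are not normalized: {rep.violations}"
                )
            for leaf in self.hierarchy.leaf_ids:
                r = np.asarray(self.true_ratios[g][leaf], dtype=float)
                if r.shape != (len(self.innovations),) or np.any(r <= 0):
                    raise ConfigurationError(
                        f"true ratios for group {g!r}, leaf {leaf!r} must be "
                        f"{len(self.innovations)} positive values"
                    )


@dataclass(frozen=True)
class SimulatedStudy:
    """Generated survey records plus the truth they were sampled from."""

    config: SimulationConfig
    respondents: tuple[Respondent, ...]
    judgments: tuple[ComparisonJudgment, ...]
    truth: dict[str, GroupTruth]

    def survey_frame(self) -> pd.DataFrame:
        """The judgments as a long-format survey table (CSV schema)."""
        group_of = {r.id: r.group for r in self.respondents}
        return pd.DataFrame(
            [
                (j.respondent_id, group_of[j.respondent_id], j.context,
                 j.left, j.right, j.favored, j.score)
                for j in self.judgments
            ],
            columns=list(SURVEY_COLUMNS),
        )

    def write_survey_csv(self, path) -> None:
        """Write the survey CSV (requires a discretized study: integer scores)."""
        if not self.config.discretize:
            raise DesignError(
                "only discretized studies round-trip through the CSV format "
                "(integer 1-9 scores); non-discretized studies are in-memory only"
            )
        df = self.survey_frame()
        df["score"] = df["score"].astype(int)
        df.to_csv(path, index=False)

    def write_truth_json(self, path) -> None:
        payload = {
            g: {
                "local_weights": t.local_weights,
                "global_leaf_weights": t.global_weights,
                "leaf_priorities": {l: pv.as_dict() for l, pv in t.leaf_priorities.items()},
                "overall_priorities": t.overall.as_dict(),
            }
            for g, t in self.truth.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _group_truth(config: SimulationConfig, group: str) -> GroupTruth:
    local = dict(config.true_local_weights[group])
    gw = global_leaf_weights(config.hierarchy, local)
    total = sum(gw.values())
    gw = {k: v / total for k, v in gw.items()}  # absorb 1e-7-level config rounding
    items = (config.baseline, *config.innovations)
    leaf_pvs = {
        leaf: star_priorities(
            np.asarray(config.true_ratios[group][leaf], dtype=float),
            items=items, baseline=config.baseline,
        )
        for leaf in config.hierarchy.leaf_ids
    }
    return GroupTruth(
        local_weights=local, global_weights=gw, leaf_priorities=leaf_pvs,
        overall=synthesize(gw, leaf_pvs),
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete study: every respondent judges the full design.

    Each judgment's true ratio (sibling weight ratio ``w_a/w_b`` for criteria
    pairs, innovation-vs-baseline ratio for the star block) is perturbed
    independently via :func:`perturb_ratio`. Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sibling_sets = config.hierarchy.sibling_sets()
    respondents: list[Respondent] = []
    judgments: list[ComparisonJudgment] = []
    truth = {g: _group_truth(config, g) for g, _ in config.groups}

    for group, n in config.groups:
        local = config.true_local_weights[group]
        slug = group.replace(" ", "_")
        for i in range(n):
            rid = f"{slug}_{i + 1:03d}"
            respondents.append(Respondent(id=rid, group=group))
            for parent, children in sibling_sets.items():
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        left, right = children[a], children[b]
                        favored, score = perturb_ratio(
                            local[left] / local[right], config.noise_sigma,
                            rng, config.discretize,
                        )
                        judgments.append(ComparisonJudgment(
                            respondent_id=rid, context=f"criteria:{parent}",
                            left=left, right=right, favored=favored, score=score,
                        ))
            for leaf in config.hierarchy.leaf_ids:
                ratios = np.asarray(config.true_ratios[group][leaf], dtype=float)
                for k, innovation in enumerate(config.innovations):
                    favored, score = perturb_ratio(
                        float(ratios[k]), config.noise_sigma, rng, config.discretize
                    )
                    judgments.append(ComparisonJudgment(
                        respondent_id=rid, context=f"innovation:{leaf}",
                        left=innovation, right=config.baseline,
                        favored=favored, score=score,
                    ))
    return SimulatedStudy(
        config=config, respondents=tuple(respondents),
        judgments=tuple(judgments), truth=truth,
    )


def default_config(
    seed: int | None = None,
    noise_sigma: float = DEFAULT_SIGMA,
    discretize: bool = True,
    group_sizes: Mapping[str, int] | None = None,
) -> SimulationConfig:
    """The reference-study scenario.

    Six stakeholder groups at their surveyed sizes (15/22/9/9/5/6 unless
    ``group_sizes`` overrides them), the shipped 7-leaf hierarchy, and truth
    taken from the reference summary tables (renormalized exactly). The
    reference tables only publish *overall* innovation priorities, so the
    same innovation-vs-baseline ratio vector — overall priority relative to
    the baseline's — is used under every leaf criterion; overall truth then
    equals the published column regardless of the criterion weights.
    """
    h = datasets.hospital_it_hierarchy()
    sizes = dict(datasets.GROUP_SIZES)
    if group_sizes is not None:
        sizes.update(group_sizes)
    true_local: dict[str, dict[str, float]] = {}
    true_ratios: dict[str, dict[str, np.ndarray]] = {}
    for g in sizes:
        local, overall = datasets.normalized_truth(g)
        true_local[g] = local
        ratios = overall[1:] / overall[0]
        true_ratios[g] = {leaf: ratios.copy() for leaf in h.leaf_ids}
    return SimulationConfig(
        groups=tuple((g, n) for g, n in sizes.items()),
        hierarchy=h,
        true_local_weights=true_local,
        true_ratios=true_ratios,
        innovations=datasets.INNOVATIONS,
        noise_sigma=noise_sigma,
        discretize=discretize,
        seed=seed,
    )


def recovery_metrics(
    truth: PriorityVector | Mapping[str, float],
    estimate: PriorityVector | Mapping[str, float],
) -> dict[str, float]:
    """How well an estimated priority vector recovers the truth.

    Returns mean absolute error, maximum absolute error, and a Kendall-type
    rank agreement: the fraction of item pairs ordered the same way, where a
    pair tied in exactly one of the two vectors counts 0.5 and a pair tied in
    both counts as agreement.
    """
    t = truth.as_dict() if isinstance(truth, PriorityVector) else dict(truth)
    e = estimate.as_dict() if isinstance(estimate, PriorityVector) else dict(estimate)
    if set(t) != set(e):
        raise DesignError("truth and estimate cover different item sets")
    items = list(t)
    tv = np.array([t[i] for i in items])
    ev = np.array([e[i] for i in items])
    abs_err = np.abs(tv - ev)
    agree = 0.0
    pairs = 0
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            pairs += 1
            dt, de = tv[a] - tv[b], ev[a] - ev[b]
            if dt == 0 and de == 0:
                agree += 1.0
            elif dt == 0 or de == 0:
                agree += 0.5
            elif (dt > 0) == (de > 0):
                agree += 1.0
    return {
        "mae": float(abs_err.mean()),
        "max_abs_error": float(abs_err.max()),
        "rank_agreement": agree / pairs if pairs else 1.0,
    }


__all__ = [
    "DEFAULT_SIGMA", "GroupTruth", "SimulationConfig", "SimulatedStudy",
    "perturb_ratio", "simulate_study", "default_config", "recovery_metrics",
]
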