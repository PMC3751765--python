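"""Reference study configuration and summary tables.

The package ships the configuration of a six-stakeholder-group survey on
nine hospital IT innovations (62 respondents total): its criteria hierarchy,
the published group-level criterion weights and innovation priorities
(transcribed at the two decimals they were printed with), and the reported
group consistency ratios. These serve two purposes: worked-example fixtures
for the table validators, and the ground truth of the default simulation
scenario (see :mod:`ahpgroup.synthetic_data`). The raw individual judgments
of that survey were never deposited, so the tables are summary-level inputs,
not re-derivable data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy, load_hierarchy

#: Stakeholder groups with their sample sizes.
GROUP_SIZES: dict[str, int] = {
    "patients": 15,
    "nurses": 22,
    "physicians": 9,
    "managers": 9,
    "health insurers": 5,
    "policy makers": 6,
}

GROUPS: tuple[str, ...] = tuple(GROUP_SIZES)

#: The nine IT innovations, in the reference table's row order, preceded by
#: the "current care" baseline hub they were each compared against.
INNOVATIONS: tuple[str, ...] = (
    "Virtual consultation",
    "Digital hospital portal",
    "Planning operations",
    "Telepathology",
    "Barcodes",
    "PDA",
    "Telesurgery",
    "Regional EPF",
    "Self-tests",
)

BASELINE_LABEL = "Baseline innovation"

#: Reported group-level consistency ratios for the criteria comparisons.
GROUP_CONSISTENCY_RATIOS: dict[str, float] = {
    "patients": 0.02,
    "nurses": 0.04,
    "physicians": 0.13,
    "managers": 0.10,
    "health insurers": 0.03,
    "policy makers": 0.02,
}

# Local criterion weights per group, two decimals as printed. Keys are the
# node ids of the shipped hierarchy; main criteria and each sub-criterion
# pair are separately normalized (up to print rounding).
CRITERIA_WEIGHTS: dict[str, dict[str, float]] = {
    "patients": {
        "efficiency": 0.22, "health_gain": 0.42, "satisfaction": 0.28, "investments": 0.09,
        "self_management": 0.45, "organization": 0.55,
        "professionals": 0.21, "patients": 0.79,
        "initial": 0.25, "restructuring": 0.76,
    },
    "nurses": {
        "efficiency": 0.21, "health_gain": 0.35, "satisfaction": 0.31, "investments": 0.14,
        "self_management": 0.35, "organization": 0.65,
        "professionals": 0.52, "patients": 0.48,
        "initial": 0.45, "restructuring": 0.55,
    },
    "physicians": {
        "efficiency": 0.20, "health_gain": 0.36, "satisfaction": 0.33, "investments": 0.11,
        "self_management": 0.28, "organization": 0.72,
        "professionals": 0.42, "patients": 0.58,
        "initial": 0.32, "restructuring": 0.68,
    },
    "managers": {
        "efficiency": 0.29, "health_gain": 0.28, "satisfaction": 0.33, "investments": 0.11,
        "self_management": 0.24, "organization": 0.76,
        "professionals": 0.26, "patients": 0.75,
        "initial": 0.43, "restructuring": 0.57,
    },
    "health insurers": {
        "efficiency": 0.29, "health_gain": 0.43, "satisfaction": 0.18, "investments": 0.10,
        "self_management": 0.45, "organization": 0.55,
        "professionals": 0.21, "patients": 0.79,
        "initial": 0.25, "restructuring": 0.76,
    },
    "policy makers": {
        "efficiency": 0.46, "health_gain": 0.28, "satisfaction": 0.15, "investments": 0.11,
        "self_management": 0.64, "organization": 0.36,
        "professionals": 0.26, "patients": 0.74,
        "initial": 0.24, "restructuring": 0.76,
    },
}

# Overall innovation priorities per group (baseline row first), two decimals
# as printed; each column sums to 1 up to print rounding.
INNOVATION_PRIORITIES: dict[str, dict[str, float]] = {
    "patients": {
        BASELINE_LABEL: 0.05, "Virtual consultation": 0.08, "Digital hospital portal": 0.10,
        "Planning operations": 0.12, "Telepathology": 0.08, "Barcodes": 0.16,
        "PDA": 0.09, "Telesurgery": 0.08, "Regional EPF": 0.15, "Self-tests": 0.09,
    },
    "nurses": {
        BASELINE_LABEL: 0.05, "Virtual consultation": 0.09, "Digital hospital portal": 0.12,
        "Planning operations": 0.13, "Telepathology": 0.07, "Barcodes": 0.13,
        "PDA": 0.10, "Telesurgery": 0.06, "Regional EPF": 0.15, "Self-tests": 0.10,
    },
    "physicians": {
        BASELINE_LABEL: 0.05, "Virtual consultation": 0.08, "Digital hospital portal": 0.11,
        "Planning operations": 0.11, "Telepathology": 0.09, "Barcodes": 0.09,
        "PDA": 0.16, "Telesurgery": 0.07, "Regional EPF": 0.19, "Self-tests": 0.06,
    },
    "managers": {
        BASELINE_LABEL: 0.05, "Virtual consultation": 0.09, "Digital hospital portal": 0.12,
        "Planning operations": 0.11, "Telepathology": 0.08, "Barcodes": 0.12,
        "PDA": 0.09, "Telesurgery": 0.06, "Regional EPF": 0.14, "Self-tests": 0.13,
    },
    "health insurers": {
        BASELINE_LABEL: 0.04, "Virtual consultation": 0.11, "Digital hospital portal": 0.12,
        "Planning operations": 0.09, "Telepathology": 0.10, "Barcodes": 0.10,
        "PDA": 0.11, "Telesurgery": 0.09, "Regional EPF": 0.11, "Self-tests": 0.13,
    },
    "policy makers": {
        BASELINE_LABEL: 0.05, "Virtual consultation": 0.09, "Digital hospital portal": 0.11,
        "Planning operations": 0.11, "Telepathology": 0.07, "Barcodes": 0.13,
        "PDA": 0.09, "Telesurgery": 0.06, "Regional EPF": 0.11, "Self-tests": 0.18,
    },
}


def hospital_it_hierarchy() -> Hierarchy:
    """The shipped criteria hierarchy: 4 main criteria, 7 leaves."""
    path = resources.files("ahpgroup").joinpath("data/hospital_it_hierarchy.yaml")
    with resources.as_file(path) as p:
        return load_hierarchy(p)


def reference_criteria_weights() -> pd.DataFrame:
    """Criterion-weight table, criteria as rows and groups as columns."""
    rows = list(next(iter(CRITERIA_WEIGHTS.values())))
    return pd.DataFrame(
        {g: [CRITERIA_WEIGHTS[g][r] for r in rows] for g in GROUPS}, index=rows
    )


def reference_innovation_priorities() -> pd.DataFrame:
    """Overall innovation-priority table (baseline row first), groups as columns."""
    rows = [BASELINE_LABEL, *INNOVATIONS]
    return pd.DataFrame(
        {g: [INNOVATION_PRIORITIES[g][r] for r in rows] for g in GROUPS}, index=rows
    )


def normalized_truth(group: str) -> tuple[dict[str, float], np.ndarray]:
    """Exactly renormalized reference values for one group.

    Returns ``(local_weights, overall_priorities)`` where each sibling set of
    the local weights sums to 1 exactly and the overall priority vector
    (baseline first) sums to 1 exactly — the rounded printed values divided by
    their sibling/column sums. This is the ground truth of the default
    simulation scenario.
    """
    h = hospital_it_hierarchy()
    raw = CRITERIA_WEIGHTS[group]
    local: dict[str, float] = {}
    for _, children in h.sibling_sets().items():
        total = sum(raw[c] for c in children)
        for c in children:
            local[c] = raw[c] / total
    pr = INNOVATION_PRIORITIES[group]
    vec = np.array([pr[BASELINE_LABEL]] + [pr[i] for i in INNOVATIONS], dtype=float)
    return local, vec / vec.sum()
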