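"""Decision hierarchies: criteria trees and weight propagation.

An AHP analysis starts from a tree of decision criteria under a single goal.
Interior nodes carry *local* weights relative to their siblings; the *global*
weight of a leaf criterion is the product of the local weights along its path
from the goal. The study configuration shipped with this package (see
:mod:`ahpgroup.datasets`) has four main criteria, three of which split into
two sub-criteria, giving seven leaves; the code supports arbitrary depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import yaml

from .errors import ConfigurationError

#: Synthetic node id used for the root when addressing the sibling set of the
#: main criteria (e.g. in judgment contexts ``criteria:goal``).
GOAL_ID = "goal"

#: Tolerance for sibling weight sums computed at full precision.
INTERNAL_TOL = 1e-9
#: Tolerance when weights are read back from tables rounded to 2 decimals.
PUBLISHED_TOL = 2e-2

# A node id -> local weight mapping; siblings must sum to 1.
WeightAssignment = Mapping[str, float]


@dataclass(frozen=True)
class CriterionNode:
    """A criterion in the decision hierarchy.

    Parameters
    ----------
    id
        Short unique identifier, used in judgment contexts and weight maps.
    label
        Human-readable display text.
    children
        Sub-criteria; either empty (a leaf) or at least two entries — a
        single child would make its pairwise comparison degenerate.
    """

    id: str
    label: str
    children: tuple["CriterionNode", ...] = ()

    def __post_init__(self) -> None:
        if len(self.children) == 1:
            raise ConfigurationError(
                f"criterion {self.id!r} has exactly one child; nodes must have "
                "0 or >=2 children"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Hierarchy:
    """A validated criteria tree under a single goal.

    ``leaves`` is the depth-first order of the leaf criteria, which fixes the
    ordering of every derived weight vector and output table.
    """

    goal: str
    main_criteria: tuple[CriterionNode, ...]
    _nodes: dict[str, CriterionNode] = field(repr=False, default_factory=dict)
    _parents: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def leaves(self) -> tuple[CriterionNode, ...]:
        return tuple(n for n in self._walk() if n.is_leaf)

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.leaves)

    def node(self, node_id: str) -> CriterionNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise ConfigurationError(f"unknown criterion id {node_id!r}") from None

    def parent_of(self, node_id: str) -> str:
        """Parent id of ``node_id`` (``GOAL_ID`` for main criteria)."""
        self.node(node_id)
        return self._parents[node_id]

    def sibling_sets(self) -> dict[str, tuple[str, ...]]:
        """Map each parent id (incl. ``GOAL_ID``) to its ordered children ids.

        These are exactly the sets compared pairwise by respondents.
        """
        sets = {GOAL_ID: tuple(n.id for n in self.main_criteria)}
        for node in self._walk():
            if node.children:
                sets[node.id] = tuple(c.id for c in node.children)
        return sets

    def root_path(self, leaf_id: str) -> tuple[str, ...]:
        """Node ids from the main criterion down to ``leaf_id`` (inclusive)."""
        path = [leaf_id]
        while self._parents[path[-1]] != GOAL_ID:
            path.append(self._parents[path[-1]])
        return tuple(reversed(path))

    def _walk(self) -> Iterator[CriterionNode]:
        stack = list(reversed(self.main_criteria))
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __iter__(self) -> Iterator[CriterionNode]:
        return self._walk()


def _parse_node(raw: Mapping) -> CriterionNode:
    if not isinstance(raw, Mapping) or "id" not in raw:
        raise ConfigurationError(f"criterion entry must be a mapping with an 'id': {raw!r}")
    children = tuple(_parse_node(c) for c in raw.get("children") or ())
    return CriterionNode(
        id=str(raw["id"]), label=str(raw.get("label", raw["id"])), children=children
    )


def build_hierarchy(spec: Mapping) -> Hierarchy:
    """Build and validate a :class:`Hierarchy` from a nested configuration.

    ``spec`` is a mapping with keys ``goal`` (string) and ``criteria`` (list of
    node mappings ``{id, label, children: [...]}``). Leaf order is the
    depth-first order of the configuration.

    Raises
    ------
    ConfigurationError
        On duplicate ids (which is also how a node listing itself — a cycle in
        this nested format — manifests), single-child nodes, a reserved id, or
        fewer than one main criterion.
    """
    if "criteria" not in spec:
        raise ConfigurationError("hierarchy config must have a 'criteria' list")
    main = tuple(_parse_node(c) for c in spec["criteria"])
    if not main:
        raise ConfigurationError("hierarchy must have at least one main criterion")

    nodes: dict[str, CriterionNode] = {}
    parents: dict[str, str] = {}

    def register(node: CriterionNode, parent: str) -> None:
        if node.id == GOAL_ID:
            raise ConfigurationError(f"criterion id {GOAL_ID!r} is reserved for the root")
        if node.id in nodes:
            raise ConfigurationError(
                f"duplicate criterion id {node.id!r} (a repeated id also indicates "
                "a cycle, e.g. a node listing itself as a child)"
            )
        nodes[node.id] = node
        parents[node.id] = parent
        for child in node.children:
            register(child, node.id)

    for node in main:
        register(node, GOAL_ID)

    return Hierarchy(
        goal=str(spec.get("goal", "goal")), main_criteria=main,
        _nodes=nodes, _parents=parents,
    )


def load_hierarchy(path) -> Hierarchy:
    """Read a hierarchy configuration from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        return build_hierarchy(yaml.safe_load(fh))


def global_leaf_weights(h: Hierarchy, w: WeightAssignment) -> dict[str, float]:
    """Propagate local weights to global leaf weights.

    The global weight of a leaf is the product of local weights along its root
    path; for exactly normalized sibling sets the result sums to 1.

    Raises
    ------
    ConfigurationError
        If ``w`` misses any non-root node of ``h`` (the error names the node).
    """
    out: dict[str, float] = {}
    for leaf in h.leaves:
        weight = 1.0
        for node_id in h.root_path(leaf.id):
            if node_id not in w:
                raise ConfigurationError(f"no local weight assigned to node {node_id!r}")
            weight *= w[node_id]
        out[leaf.id] = weight
    return out


@dataclass(frozen=True)
class WeightValidation:
    """Report of sibling-sum checks; ``ok`` iff no set deviates beyond tol."""

    violations: tuple[tuple[str, float], ...]  # (parent id, actual sum)
    tol: float

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_weights(
    h: Hierarchy, w: WeightAssignment, tol: float = INTERNAL_TOL
) -> WeightValidation:
    """Check that every sibling set's local weights sum to 1 within ``tol``.

    Use ``tol=PUBLISHED_TOL`` (0.02) for weights transcribed from tables
    rounded to two decimals; exact pipeline output should satisfy the default
    1e-9. Missing nodes count as weight 0, so they surface as violations.
    """
    violations = []
    for parent, children in h.sibling_sets().items():
        total = math.fsum(w.get(c, 0.0) for c in children)
        if abs(total - 1.0) > tol:
            violations.append((parent, total))
    return WeightValidation(violations=tuple(violations), tol=tol)
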