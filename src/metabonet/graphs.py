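"""Directed acyclic graphs over named discrete variables, with layering constraints."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "Dag",
    "ConstraintSet",
    "CycleError",
    "ConstraintError",
    "is_acyclic",
    "topological_order",
    "layering_constraints",
]

Arc = tuple[str, str]


class CycleError(ValueError):
    """The arc set admits no topological order."""


class ConstraintError(ValueError):
    """Blacklist/whitelist are mutually inconsistent."""


def _toposort(nodes, arcs) -> list[str] | None:
    """Kahn's algorithm; returns an order or None if cyclic."""
    indeg = {v: 0 for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for a, b in arcs:
        indeg[b] += 1
        children[a].append(b)
    frontier = [v for v in nodes if indeg[v] == 0]
    order: list[str] = []
    while frontier:
        v = frontier.pop()
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                frontier.append(c)
    return order if len(order) == len(nodes) else None


@dataclass(frozen=True)
class Dag:
    """A DAG: variable names plus a set of directed arcs.

    Node order is preserved (it fixes deterministic iteration everywhere);
    arcs are held as a frozenset of ``(parent, child)`` pairs.  Construction
    validates endpoints and rejects self-loops and cycles.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        known = set(self.nodes)
        if len(known) != len(self.nodes):
            raise ValueError("duplicate node names")
        for a, b in self.arcs:
            if a not in known or b not in known:
                raise ValueError(f"arc endpoint not a node: ({a!r}, {b!r})")
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
        if _toposort(self.nodes, self.arcs) is None:
            raise CycleError("arc set contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in node order."""
        ps = {a for a, b in self.arcs if b == node}
        return tuple(v for v in self.nodes if v in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {b for a, b in self.arcs if a == node}
        return tuple(v for v in self.nodes if v in cs)

    def topological_order(self) -> tuple[str, ...]:
        order = _toposort(self.nodes, self.arcs)
        assert order is not None  # guaranteed by construction
        # stable: prefer node order among ties
        remaining = set(self.nodes)
        placed: list[str] = []
        parent_map = {v: set(self.parents(v)) for v in self.nodes}
        while remaining:
            for v in self.nodes:
                if v in remaining and parent_map[v] <= set(placed):
                    placed.append(v)
                    remaining.discard(v)
                    break
        return tuple(placed)


def is_acyclic(nodes, arcs) -> bool:
    """True iff ``arcs`` over ``nodes`` admits a topological order.

    Accepts a raw (nodes, arcs) pair so candidate arc sets can be tested
    without constructing a :class:`Dag` (which would raise).
    """
    return _toposort(tuple(nodes), set(arcs)) is not None


@dataclass(frozen=True)
class ConstraintSet:
    """Hard structural constraints for structure learning.

    ``blacklist`` arcs may never appear; ``whitelist`` arcs must always be
    present (and are in the search's starting graph).  The two sets must be
    disjoint and the whitelist alone acyclic.
    """

    blacklist: frozenset[Arc] = field(default_factory=frozenset)
    whitelist: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "blacklist", frozenset(tuple(a) for a in self.blacklist))
        object.__setattr__(self, "whitelist", frozenset(tuple(a) for a in self.whitelist))
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise ConstraintError(f"arcs both required and forbidden: {sorted(overlap)}")
        wl_nodes = {v for arc in self.whitelist for v in arc}
        if not is_acyclic(sorted(wl_nodes), self.whitelist):
            raise ConstraintError("whitelist arcs form a cycle")


def layering_constraints(roles: dict[str, str]) -> ConstraintSet:
    """Build the layering blacklist from node roles.

    ``roles`` maps each node to one of ``outcome``, ``exposure``,
    ``demographic``, ``covariate``.  The layering forbids (i) arcs between
    exposure-layer nodes in either direction (metabolic syndrome and obesity
    are two readings of the same construct and must not explain each other)
    and (ii) every arc out of the outcome node, so that exposures, sex and
    covariates may point at the outcome but never the reverse.  The whitelist
    is empty: pointing at the outcome is permitted, not forced.
    """
    valid = {"outcome", "exposure", "demographic", "covariate"}
    bad = {r for r in roles.values() if r not in valid}
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}")
    outcomes = [v for v, r in roles.items() if r == "outcome"]
    if len(outcomes) != 1:
        raise ValueError("exactly one node must have the 'outcome' role")
    outcome = outcomes[0]
    exposures = [v for v, r in roles.items() if r == "exposure"]
    black: set[Arc] = set()
    for a, b in product(exposures, exposures):
        if a != b:
            black.add((a, b))
    for v in roles:
        if v != outcome:
            black.add((outcome, v))
    return ConstraintSet(blacklist=frozenset(black))
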