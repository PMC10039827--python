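"""Causal diagrams for confirmatory path analysis.

A path diagram is a directed acyclic graph in which every node is an observed
site-level variable (a land-cover covariate or a guild richness count) and
every link a hypothesised causal effect.  Richness nodes are Poisson-family
sinks; all other nodes are Gaussian.  The diagram is the unit that the
d-separation test validates and that the effect decomposition walks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "NodeSpec",
    "LinkSpec",
    "DagSpec",
    "IndependenceClaim",
    "DagValidationError",
    "validate_dag",
    "topological_order",
    "basis_set",
    "directed_paths",
]

FAMILIES = ("gaussian", "poisson")
FORMS = ("linear", "quadratic")
SIGNS = ("+", "-", "peaked", "none")
PROVENANCES = ("a_priori", "added")


class DagValidationError(ValueError):
    """Raised when a diagram violates a structural invariant."""


@dataclass(frozen=True)
class NodeSpec:
    """A variable in the diagram.

    ``family`` selects the local regression used whenever the node is a
    response: ``gaussian`` (identity link, least squares) or ``poisson``
    (log link, for richness counts only).
    """

    name: str
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DagValidationError(f"unknown family {self.family!r} for node {self.name!r}")


@dataclass(frozen=True)
class LinkSpec:
    """A directed causal link.

    ``form='quadratic'`` means the source enters the target's regression as
    the pair {x, x**2}; used where a peaked (∩) relation is hypothesised.
    ``predicted_sign`` records the a-priori direction; ``provenance``
    distinguishes hypothesised links from ones added after failed
    independence claims.
    """

    source: str
    target: str
    form: str = "linear"
    predicted_sign: str = "none"
    provenance: str = "a_priori"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise DagValidationError(f"self-link on {self.source!r}")
        if self.form not in FORMS:
            raise DagValidationError(f"unknown form {self.form!r}")
        if self.predicted_sign not in SIGNS:
            raise DagValidationError(f"unknown predicted_sign {self.predicted_sign!r}")
        if self.provenance not in PROVENANCES:
            raise DagValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class IndependenceClaim:
    """A conditional-independence statement implied by the diagram.

    The claim reads: ``later`` is independent of ``earlier`` given
    ``conditioning_set``.  The causally later member is always the response
    of the regression that tests the claim.
    """

    earlier: str
    later: str
    conditioning_set: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        cond = ", ".join(self.conditioning_set) or "∅"
        return f"{self.later} ⟂ {self.earlier} | {{{cond}}}"


@dataclass(frozen=True)
class DagSpec:
    """A full path diagram: nodes plus directed links."""

    nodes: tuple[NodeSpec, ...]
    links: tuple[LinkSpec, ...]
    name: str = ""

    def __init__(
        self,
        nodes: Iterable[NodeSpec | str],
        links: Iterable[LinkSpec | tuple],
        name: str = "",
    ) -> None:
        node_specs = tuple(
            n if isinstance(n, NodeSpec) else NodeSpec(str(n)) for n in nodes
        )
        link_specs = tuple(
            l if isinstance(l, LinkSpec) else LinkSpec(*l) for l in links
        )
        object.__setattr__(self, "nodes", node_specs)
        object.__setattr__(self, "links", link_specs)
        object.__setattr__(self, "name", name)

    # -- basic queries -------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def family(self, name: str) -> str:
        return self.node(name).family

    def link(self, source: str, target: str) -> LinkSpec | None:
        for l in self.links:
            if l.pair == (source, target):
                return l
        return None

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(l.source for l in self.links if l.target == name)

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(l.target for l in self.links if l.source == name)

    def exogenous(self) -> tuple[str, ...]:
        """Nodes with no incoming links."""
        targets = {l.target for l in self.links}
        return tuple(n.name for n in self.nodes if n.name not in targets)

    def adjacent(self, a: str, b: str) -> bool:
        return self.link(a, b) is not None or self.link(b, a) is not None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from(l.pair for l in self.links)
        return g

    def with_links(self, extra: Sequence[LinkSpec]) -> "DagSpec":
        return DagSpec(self.nodes, self.links + tuple(extra), name=self.name)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [{"name": n.name, "family": n.family} for n in self.nodes],
            "links": [
                {
                    "source": l.source,
                    "target": l.target,
                    "form": l.form,
                    "predicted_sign": l.predicted_sign,
                    "provenance": l.provenance,
                }
                for l in self.links
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DagSpec":
        nodes = [NodeSpec(n["name"], n.get("family", "gaussian")) for n in d["nodes"]]
        links = [
            LinkSpec(
                l["source"],
                l["target"],
                l.get("form", "linear"),
                l.get("predicted_sign", "none"),
                l.get("provenance", "a_priori"),
            )
            for l in d["links"]
        ]
        return cls(nodes, links, name=d.get("name", ""))

    @classmethod
    def from_json(cls, path: str | Path) -> "DagSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def validate_dag(spec: DagSpec) -> DagSpec:
    """Check structural invariants, returning the spec unchanged if sound.

    Raises :class:`DagValidationError` for duplicate node names, links with
    undeclared endpoints, duplicate ordered pairs, cycles (the offending
    cycle is named), or Poisson nodes with outgoing links (richness counts
    are sinks: nothing in the diagram is caused by a count).
    """
    names = [n.name for n in spec.nodes]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DagValidationError(f"duplicate node names: {sorted(dupes)}")
    declared = set(names)
    seen_pairs: set[tuple[str, str]] = set()
    for l in spec.links:
        if l.source not in declared or l.target not in declared:
            raise DagValidationError(f"link {l.source}->{l.target} names an undeclared node")
        if l.pair in seen_pairs:
            raise DagValidationError(f"duplicate link {l.source}->{l.target}")
        seen_pairs.add(l.pair)
        if (l.target, l.source) in seen_pairs:
            raise DagValidationError(
                f"links in both directions between {l.source} and {l.target}"
            )
    g = spec.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
        raise DagValidationError(f"cycle detected: {pretty}")
    for n in spec.nodes:
        if n.family == "poisson" and spec.children(n.name):
            raise DagValidationError(
                f"poisson node {n.name!r} has outgoing links; count responses must be sinks"
            )
    return spec


def topological_order(spec: DagSpec) -> list[str]:
    """Deterministic (lexicographic) topological order of the node names."""
    validate_dag(spec)
    return list(nx.lexicographical_topological_sort(spec.to_networkx()))


def _terms_for_parent(spec: DagSpec, parent: str, child: str) -> tuple[str, ...]:
    link = spec.link(parent, child)
    if link is not None and link.form == "quadratic":
        return (parent, f"{parent}^2")
    return (parent,)


def conditioning_terms(spec: DagSpec, member_a: str, member_b: str) -> tuple[str, ...]:
    """Union of the direct parents of both claim members, as regression terms.

    Quadratic links contribute the pair {x, x^2}.  The members themselves are
    excluded.  Order follows the topological order for determinism.
    """
    parents = set(spec.parents(member_a)) | set(spec.parents(member_b))
    parents -= {member_a, member_b}
    order = {n: i for i, n in enumerate(topological_order(spec))}
    terms: list[str] = []
    for p in sorted(parents, key=lambda n: (order[n], n)):
        for child in (member_a, member_b):
            if p in spec.parents(child):
                for t in _terms_for_parent(spec, p, child):
                    if t not in terms:
                        terms.append(t)
    return tuple(terms)


def basis_set(spec: DagSpec) -> list[IndependenceClaim]:
    """The union basis set of independence claims implied by the diagram.

    One claim per unordered non-adjacent pair of nodes.  The topologically
    later member is the claim's response; the conditioning set is the union
    of the direct parents of both members.  A pair of parentless nodes
    yields a marginal-independence claim (empty conditioning set).
    """
    validate_dag(spec)
    order = topological_order(spec)
    position = {n: i for i, n in enumerate(order)}
    claims: list[IndependenceClaim] = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if spec.adjacent(a, b):
                continue
            # a precedes b in topological order, so b cannot be an ancestor of a
            cond = conditioning_terms(spec, a, b)
            claims.append(IndependenceClaim(earlier=a, later=b, conditioning_set=cond))
    claims.sort(key=lambda c: (position[c.later], position[c.earlier]))
    return claims


def directed_paths(spec: DagSpec, source: str, sink: str) -> list[list[str]]:
    """All simple directed paths from ``source`` to ``sink``.

    The direct link, when present, appears as the length-2 path
    ``[source, sink]``.  Paths are returned sorted (shortest first, then
    lexicographic) for determinism.
    """
    declared = set(spec.node_names)
    for n in (source, sink):
        if n not in declared:
            raise KeyError(f"unknown node {n!r}")
    if source == sink:
        raise ValueError("source and sink must differ")
    g = spec.to_networkx()
    paths = [list(p) for p in nx.all_simple_paths(g, source, sink)]
    paths.sort(key=lambda p: (len(p), p))
    return paths
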