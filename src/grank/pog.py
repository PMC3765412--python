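"""Part-Of Graph (POG) construction.

The POG keeps every node of the source ontology but only part-of edges:
the explicit ones plus those inferable by composing relations — if A is-a B
and B part-of C then A part-of C, and if A part-of B and B is-a C then
A part-of C.  Applied to a fixed point (together with part-of transitivity,
which GO treats as valid), the inferred edge set is exactly the pairs (x, z)
joined by a directed path that uses at least one part-of edge.  With
transitivity disabled, it is the pairs joined by a path of shape
is-a* part-of is-a* (a single part-of hop framed by is-a chains).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

from .model import GoGraph, GrankError, QueryError, Relation, TermId


class Provenance(enum.Enum):
    EXPLICIT = "explicit"
    INFERRED = "inferred"


@dataclass
class Pog:
    """Derived graph of part-of relations, edges stored child -> parent."""

    nodes: frozenset[TermId]
    edges: dict[tuple[TermId, TermId], Provenance] = field(default_factory=dict)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, t: TermId) -> frozenset[TermId]:
        self._check(t)
        return frozenset(p for (c, p) in self.edges if c == t)

    def children(self, t: TermId) -> frozenset[TermId]:
        self._check(t)
        return frozenset(c for (c, p) in self.edges if p == t)

    def _check(self, t: TermId) -> None:
        if t not in self.nodes:
            raise QueryError(f"unknown term: {t}")

    def __contains__(self, t: TermId) -> bool:
        return t in self.nodes


def build_pog(graph: GoGraph, partof_transitivity: bool = True) -> Pog:
    """Convert a :class:`GoGraph` into its Part-Of Graph.

    Parameters
    ----------
    graph
        Source ontology (must be acyclic; validated at construction).
    partof_transitivity
        When True (default) part-of composes with itself, so multi-hop
        part-of chains collapse into inferred edges.  When False only the
        two is-a/part-of composition rules are applied to a fixed point.
    """
    explicit = {(c, p) for c, p, r in graph.edges if r is Relation.PART_OF}
    union = graph.union_digraph()

    inferred: set[tuple[TermId, TermId]] = set()
    if partof_transitivity:
        # Reachability with >= 1 part-of edge: BFS over (node, used_po) states.
        for src in graph.terms:
            seen: set[tuple[TermId, bool]] = {(src, False)}
            frontier = [(src, False)]
            while frontier:
                node, used = frontier.pop()
                for _, nxt, data in union.out_edges(node, data=True):
                    rels = data["relations"]
                    reachable_states: set[bool] = set()
                    if Relation.IS_A in rels:
                        reachable_states.add(used)
                    if Relation.PART_OF in rels:
                        reachable_states.add(True)
                    for used2 in reachable_states:
                        state = (nxt, used2)
                        if state not in seen:
                            seen.add(state)
                            frontier.append(state)
            inferred.update((src, z) for (z, used) in seen if used and z != src)
    else:
        # Single part-of hop framed by is-a chains: compose the is-a
        # reflexive closure around each explicit part-of edge.
        isa = graph.digraph(Relation.IS_A)
        up = {n: nx.descendants(isa, n) | {n} for n in isa}      # is-a ancestors
        down = {n: nx.ancestors(isa, n) | {n} for n in isa}      # is-a descendants
        for (u, v) in explicit:
            for x in down[u]:
                for z in up[v]:
                    if x != z:
                        inferred.add((x, z))

    edges: dict[tuple[TermId, TermId], Provenance] = {
        e: Provenance.INFERRED for e in inferred
    }
    edges.update({e: Provenance.EXPLICIT for e in explicit})

    pog = Pog(frozenset(graph.terms), edges)
    if not nx.is_directed_acyclic_graph(pog.digraph()):  # impossible on a DAG
        raise GrankError("internal error: POG closure introduced a cycle")
    return pog


def pog_ancestors(pog: Pog, t: TermId) -> frozenset[TermId]:
    """All terms reachable upward from ``t`` along part-of edges (t excluded)."""
    pog._check(t)
    return frozenset(nx.descendants(pog.digraph(), t))


def pog_descendants(pog: Pog, t: TermId) -> frozenset[TermId]:
    """All terms reaching ``t`` upward, i.e. its part-of descendants."""
    pog._check(t)
    return frozenset(nx.ancestors(pog.digraph(), t))


def write_pog_tsv(pog: Pog, out: IO[str]) -> None:
    out.write("child\tparent\tprovenance\n")
    for (c, p) in sorted(pog.edges):
        out.write(f"{c}\t{p}\t{pog.edges[(c, p)].value}\n")
    isolated = sorted(pog.nodes - {n for e in pog.edges for n in e})
    for n in isolated:
        out.write(f"{n}\t\tisolated\n")


def read_pog_tsv(lines: Iterable[str]) -> Pog:
    nodes: set[TermId] = set()
    edges: dict[tuple[TermId, TermId], Provenance] = {}
    for i, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if not line or (i == 0 and line.startswith("child\t")):
            continue
        c, p, prov = line.split("\t")
        nodes.add(c)
        if prov == "isolated":
            continue
        nodes.add(p)
        edges[(c, p)] = Provenance(prov)
    return Pog(frozenset(nodes), edges)
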