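"""Term depth assignment.

The depth of a term is the length of the *longest* chain of is-a edges from
its namespace root down to the term; part-of edges never contribute.  Under
multiple inheritance the longest distance governs.  Depths can be rendered
as alphabetical level labels (0 -> "A", 1 -> "B", ..., 26 -> "AA") for
display, but are stored as integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

import networkx as nx

from .model import GoGraph, GrankError, QueryError, Relation, TermId


@dataclass
class DepthMap:
    depths: dict[TermId, int] = field(default_factory=dict)
    unrooted: frozenset[TermId] = frozenset()

    def __getitem__(self, t: TermId) -> int:
        try:
            return self.depths[t]
        except KeyError:
            raise QueryError(f"unknown term: {t}") from None

    def __contains__(self, t: TermId) -> bool:
        return t in self.depths

    def label(self, t: TermId) -> str:
        return depth_label(self[t])


def assign_depths(graph: GoGraph) -> DepthMap:
    """Longest is-a distance from a root for every term.

    Depth is computed over the is-a subgraph alone, so it is invariant to
    part-of edges: terms without is-a parents are the depth-0 bases and every
    other term takes 1 + the maximum depth of its is-a parents.  A term with
    no is-a path to a true root (e.g. one attached only via part-of, and its
    is-a descendants) is flagged unrooted; its depth is then measured from
    its local is-a source.
    """
    isa = graph.digraph(Relation.IS_A)
    roots = graph.roots
    depths: dict[TermId, int] = {}
    rooted: set[TermId] = set()
    # child -> parent orientation: process parents before children
    order = list(nx.topological_sort(isa.reverse(copy=False)))
    for node in order:
        parents = list(isa.successors(node))
        depths[node] = max((depths[p] for p in parents), default=-1) + 1
        if node in roots or any(p in rooted for p in parents):
            rooted.add(node)
    unrooted = set(depths) - rooted
    if unrooted:
        import logging

        logging.getLogger("grank").warning(
            "%d term(s) have no is-a path to a root; assigned depth 0",
            len(unrooted),
        )
    return DepthMap(depths, frozenset(unrooted))


def depth_label(d: int) -> str:
    """Spreadsheet-style level label: 0->A ... 25->Z, 26->AA, 27->AB."""
    if d < 0:
        raise GrankError(f"depth must be non-negative, got {d}")
    n = d + 1  # bijective base-26
    out = ""
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def write_depths_tsv(depths: DepthMap, out: IO[str]) -> None:
    out.write("term\tdepth\tlabel\n")
    for t in sorted(depths.depths):
        flag = "*" if t in depths.unrooted else ""
        out.write(f"{t}\t{depths.depths[t]}{flag}\t{depth_label(depths.depths[t])}\n")


def read_depths_tsv(lines) -> DepthMap:
    depths: dict[TermId, int] = {}
    unrooted: set[TermId] = set()
    for i, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if not line or (i == 0 and line.startswith("term\t")):
            continue
        t, d, _label = line.split("\t")
        if d.endswith("*"):
            unrooted.add(t)
            d = d[:-1]
        depths[t] = int(d)
    return DepthMap(depths, frozenset(unrooted))
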