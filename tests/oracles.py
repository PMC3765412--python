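"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (naive loops, exhaustive
enumeration, exact rational arithmetic) and deliberately shares no code with
the package internals it validates.
"""

from fractions import Fraction
from math import comb

from grank.model import GoGraph, Relation


def closure_oracle(graph: GoGraph, transitivity: bool = True) -> set:
    """Repeat-until-stable application of the part-of inference rules."""
    isa = {(c, p) for c, p, r in graph.edges if r is Relation.IS_A}
    po = {(c, p) for c, p, r in graph.edges if r is Relation.PART_OF}
    changed = True
    while changed:
        changed = False
        new = set()
        for (a, b) in isa:
            for (b2, c) in po:
                if b == b2 and a != c:
                    new.add((a, c))  # A is-a B, B part-of C => A part-of C
        for (a, b) in po:
            for (b2, c) in isa:
                if b == b2 and a != c:
                    new.add((a, c))  # A part-of B, B is-a C => A part-of C
            if transitivity:
                for (b2, c) in po:
                    if b == b2 and a != c:
                        new.add((a, c))
        if new - po:
            po |= new
            changed = True
    return po


def reachable(edges: set, start: str) -> set:
    """Naive upward reachability over child->parent pairs (start excluded)."""
    out, frontier = set(), [start]
    while frontier:
        node = frontier.pop()
        for (c, p) in edges:
            if c == node and p not in out:
                out.add(p)
                frontier.append(p)
    return out


def longest_isa_depths(graph: GoGraph) -> dict:
    """Depth oracle: exhaustive enumeration of all upward is-a paths.

    Every maximal is-a path ends at a term without is-a parents (a depth-0
    base), so the depth of a term is the length of its longest upward path.
    """
    isa = {(c, p) for c, p, r in graph.edges if r is Relation.IS_A}

    def all_path_lengths(node):
        yield 0
        for (c, p) in isa:
            if c == node:
                for length in all_path_lengths(p):
                    yield length + 1

    return {
        t: max(all_path_lengths(t)) for t in graph.terms
    }


def all_simple_paths_oracle(edges: set, source: str, target: str):
    """Exhaustive DFS enumeration of simple directed paths (inclusive)."""
    if source == target:
        yield (source,)
        return
    stack = [(source, (source,))]
    while stack:
        node, path = stack.pop()
        for (c, p) in edges:
            if c == node and p not in path:
                if p == target:
                    yield path + (p,)
                else:
                    stack.append((p, path + (p,)))


def meaningful_oracle(pog_edges: set, depths: dict, kcs: set, candidate: str,
                      role_lca: bool) -> bool:
    """Exhaustive path-depth-multiset check of the meaningfulness rule."""
    if kcs == {candidate}:
        return True
    for kc in kcs:
        if depths[candidate] == depths[kc]:
            return False
        src, dst = (kc, candidate) if role_lca else (candidate, kc)
        for path in all_simple_paths_oracle(pog_edges, src, dst):
            ds = [depths[t] for t in path]
            if len(set(ds)) != len(ds):
                return False
    return True


def lca_oracle(pog_edges: set, nodes: set, kcs: set) -> set:
    """Intersect full ancestor sets; discard members with a descendant inside."""
    common = None
    for kc in kcs:
        anc = reachable(pog_edges, kc) | {kc}
        common = anc if common is None else common & anc
    rev = {(p, c) for (c, p) in pog_edges}
    return {a for a in common if not (reachable(rev, a) & common)}


def tcd_oracle(pog_edges: set, nodes: set, kcs: set) -> set:
    return lca_oracle({(p, c) for (c, p) in pog_edges}, nodes, kcs)


def hypergeom_oracle(a: int, b: int, c: int, k: int) -> Fraction:
    """Exact rational cumulative hypergeometric mass P(X <= k-1)."""
    return Fraction(
        sum(
            comb(b, i) * comb(a - b, c - i)
            for i in range(k)
            if i <= b and 0 <= c - i <= a - b
        ),
        comb(a, c),
    )
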