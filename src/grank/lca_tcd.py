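"""Meaningful lowest common ancestors and top common descendants.

Given the KCs of a query, candidates are the lowest common ancestors (LCAs)
and top common descendants (TCDs) of the KC set in the Part-Of Graph.  A
candidate is *meaningful* — the existence-dependency test — when

1. its depth differs from the depth of every KC, and
2. every directed POG path between the candidate and each KC (endpoints
   included) contains no two terms of equal depth.

Condition 2 defaults to universal quantification over paths
(``path_semantics="all"``); ``"exists"`` accepts a candidate when at least
one clean path per KC exists.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import networkx as nx

from .depth import DepthMap
from .model import GrankError, TermId
from .pog import Pog, pog_ancestors, pog_descendants


class Role(enum.Enum):
    LCA = "LCA"
    TCD = "TCD"


@dataclass(frozen=True)
class DepthEqualityWitness:
    """Candidate and KC sit at the same hierarchical level."""

    kc: TermId
    candidate: TermId


@dataclass(frozen=True)
class PathWitness:
    """A POG path between candidate and KC with two equal-depth terms."""

    kc: TermId
    path: tuple[TermId, ...]
    pair: tuple[TermId, TermId]


Witness = Union[DepthEqualityWitness, PathWitness]


@dataclass(frozen=True)
class CandidateVerdict:
    candidate: TermId
    role: Role
    meaningful: bool
    witness: Optional[Witness] = None

    def __post_init__(self) -> None:
        if self.meaningful == (self.witness is not None):
            raise GrankError("witness must be present exactly when meaningless")


def _common(pog: Pog, kcs: Iterable[TermId], up: bool) -> set[TermId]:
    reach = pog_ancestors if up else pog_descendants
    sets = [reach(pog, k) | {k} for k in sorted(set(kcs))]
    out = set.intersection(*map(set, sets))
    return out


def lowest_common_ancestors(pog: Pog, kcs: Iterable[TermId]) -> frozenset[TermId]:
    """Common POG ancestors of all KCs with no common-ancestor descendant.

    A KC that is an ancestor of the others counts as its own ancestor, so a
    singleton KC set returns the KC itself.
    """
    kcs = set(kcs)
    if not kcs:
        raise GrankError("empty KC set")
    common = _common(pog, kcs, up=True)
    return frozenset(
        a for a in common if not (pog_descendants(pog, a) & common)
    )


def top_common_descendants(pog: Pog, kcs: Iterable[TermId]) -> frozenset[TermId]:
    """Mirror of :func:`lowest_common_ancestors` with direction reversed."""
    kcs = set(kcs)
    if not kcs:
        raise GrankError("empty KC set")
    common = _common(pog, kcs, up=False)
    return frozenset(
        d for d in common if not (pog_ancestors(pog, d) & common)
    )


def _sorted_simple_paths(
    g: nx.DiGraph, source: TermId, target: TermId
) -> list[tuple[TermId, ...]]:
    if source == target:
        return [(source,)]
    paths = [tuple(p) for p in nx.all_simple_paths(g, source, target)]
    return sorted(paths)


def _first_equal_depth_pair(
    path: tuple[TermId, ...], depths: DepthMap
) -> Optional[tuple[TermId, TermId]]:
    for i, j in itertools.combinations(range(len(path)), 2):
        if depths[path[i]] == depths[path[j]]:
            return (path[i], path[j])
    return None


def is_meaningful(
    pog: Pog,
    depths: DepthMap,
    kcs: Iterable[TermId],
    candidate: TermId,
    role: Role,
    path_semantics: str = "all",
) -> CandidateVerdict:
    """Apply the depth-uniqueness test to one LCA/TCD candidate.

    ``candidate`` must be a common ancestor (LCA role) or common descendant
    (TCD role) of the KCs; a singleton KC set equal to the candidate is
    trivially meaningful.  Violations are reported deterministically: KCs in
    lexicographic order, paths in lexicographic order.
    """
    if path_semantics not in ("all", "exists"):
        raise GrankError(f"unknown path semantics: {path_semantics!r}")
    kcs = set(kcs)
    if not kcs:
        raise GrankError("empty KC set")
    if kcs == {candidate}:
        return CandidateVerdict(candidate, role, True)

    common = _common(pog, kcs, up=(role is Role.LCA))
    if candidate not in common:
        kind = "ancestor" if role is Role.LCA else "descendant"
        raise GrankError(f"{candidate} is not a common {kind} of the KCs")

    g = pog.digraph()
    for kc in sorted(kcs):
        if depths[candidate] == depths[kc]:
            return CandidateVerdict(
                candidate, role, False, DepthEqualityWitness(kc, candidate)
            )
        if role is Role.LCA:
            paths = _sorted_simple_paths(g, kc, candidate)
        else:
            paths = _sorted_simple_paths(g, candidate, kc)
        clean = False
        first_bad: Optional[PathWitness] = None
        for path in paths:
            pair = _first_equal_depth_pair(path, depths)
            if pair is None:
                clean = True
            elif first_bad is None:
                first_bad = PathWitness(kc, path, pair)
        if path_semantics == "all" and first_bad is not None:
            return CandidateVerdict(candidate, role, False, first_bad)
        if path_semantics == "exists" and not clean:
            return CandidateVerdict(candidate, role, False, first_bad)
    return CandidateVerdict(candidate, role, True)


def meaningful_candidates(
    pog: Pog,
    depths: DepthMap,
    kcs_per_gene: Mapping[str, Iterable[TermId]],
    path_semantics: str = "all",
) -> list[CandidateVerdict]:
    """Enumerate and judge LCA/TCD candidates over all KC combinations.

    One KC is selected per query gene; each resulting KC set contributes its
    LCAs and TCDs.  Candidates are deduplicated by (term, role); a candidate
    is meaningful if it is meaningful under at least one combination.
    Returned sorted by (term, role) for determinism.
    """
    genes = sorted(kcs_per_gene)
    if not genes:
        raise GrankError("no gene has any KC")
    choices = [sorted(set(kcs_per_gene[g])) for g in genes]
    verdicts: dict[tuple[TermId, Role], CandidateVerdict] = {}
    for combo in itertools.product(*choices):
        kc_set = frozenset(combo)
        for role, candidates in (
            (Role.LCA, lowest_common_ancestors(pog, kc_set)),
            (Role.TCD, top_common_descendants(pog, kc_set)),
        ):
            for cand in sorted(candidates):
                v = is_meaningful(pog, depths, kc_set, cand, role, path_semantics)
                key = (cand, role)
                prev = verdicts.get(key)
                if prev is None or (v.meaningful and not prev.meaningful):
                    verdicts[key] = v
    return [verdicts[k] for k in sorted(verdicts, key=lambda k: (k[0], k[1].value))]


def write_verdicts_tsv(verdicts: Iterable[CandidateVerdict], out) -> None:
    out.write("candidate\trole\tmeaningful\twitness\n")
    for v in verdicts:
        if v.witness is None:
            w = ""
        elif isinstance(v.witness, DepthEqualityWitness):
            w = f"depth({v.witness.candidate})==depth({v.witness.kc})"
        else:
            w = (
                f"path {'->'.join(v.witness.path)} has equal depths at "
                f"{v.witness.pair[0]},{v.witness.pair[1]}"
            )
        out.write(f"{v.candidate}\t{v.role.value}\t{int(v.meaningful)}\t{w}\n")
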