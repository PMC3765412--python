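"""Scoring and ranking of meaningful LCA/TCD candidates.

Three ingredients combine into the overall rank of a candidate term:

* a per-term *microarray score* S(v): the cumulative hypergeometric
  probability that fewer than k of the c significant genes fall among the
  b genes annotated to v, drawn from a universe of a genes;
* a PageRank-style *KC rank* R(KC) mixing S(KC) with the normalised scores
  of its POG parents (weight p1) and children (weight p2);
* *decay* attenuation per hierarchical level separating the candidate from
  a KC, aggregated per gene (max by default) and summed over query genes,
  then multiplied by a keyword-proximity factor in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom

from .depth import DepthMap
from .lca_tcd import CandidateVerdict, Role
from .model import (
    Aggregation,
    AnnotationSet,
    GrankError,
    MicroarrayReference,
    Query,
    RankParams,
    TermId,
)
from .pog import Pog


@dataclass(frozen=True)
class TermScore:
    term: TermId
    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise GrankError(f"term score out of [0,1]: {self.s}")


@dataclass(frozen=True)
class KcRank:
    kc: TermId
    r: float

    def __post_init__(self) -> None:
        if self.r < 0.0:
            raise GrankError(f"negative KC rank: {self.r}")


@dataclass(frozen=True)
class ProximityWindow:
    """Smallest window of the ontology drawing covering the annotated terms.

    height spans hierarchical levels, width spans horizontal positions in
    the canonical (lexicographic-within-layer) layout; prox = 1/(h*w).
    """

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise GrankError("window height and width must be >= 1")

    @property
    def prox(self) -> float:
        return 1.0 / (self.height * self.width)


@dataclass(frozen=True)
class AnswerRow:
    term: TermId
    role: Role
    score: float
    genes: tuple[str, ...]


@dataclass
class RankedAnswer:
    rows: list[AnswerRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def genes(self) -> tuple[str, ...]:
        """All answer genes, best-ranked first, deduplicated."""
        out: list[str] = []
        for row in self.rows:
            for g in row.genes:
                if g not in out:
                    out.append(g)
        return tuple(out)


# ---------------------------------------------------------------------------
# Term score (cumulative hypergeometric)
# ---------------------------------------------------------------------------

def hypergeom_score(a: int, b: int, c: int, k: int) -> float:
    """P(X <= k-1) for X ~ Hypergeom(universe a, annotated b, draws c).

    Computed through scipy's log-space hypergeometric CDF, stable at
    microarray scale (a in the tens of thousands).  k = 0 is the empty sum.
    """
    if not (0 <= b <= a):
        raise GrankError(f"need 0 <= b <= a, got b={b}, a={a}")
    if not (0 <= c <= a):
        raise GrankError(f"need 0 <= c <= a, got c={c}, a={a}")
    if k < 0:
        raise GrankError(f"need k >= 0, got k={k}")
    if k == 0:
        return 0.0
    # k - 1 >= min(b, c) saturates the CDF at exactly 1
    return float(hypergeom.cdf(k - 1, a, b, c))


def term_score(
    ref: MicroarrayReference, ann: AnnotationSet, term: TermId
) -> TermScore:
    """Microarray score of one term.

    b and k are computed on the intersection of the term's annotated genes
    with the microarray universe; a term absent from the universe scores 0.
    """
    annotated = ann.genes_for_term(term) & ref.universe
    b = len(annotated)
    if b == 0:
        return TermScore(term, 0.0)
    k = len(annotated & ref.significant)
    return TermScore(term, hypergeom_score(ref.a, b, ref.c, k))


def score_terms(
    ref: MicroarrayReference, ann: AnnotationSet, terms: Iterable[TermId]
) -> dict[TermId, TermScore]:
    return {t: term_score(ref, ann, t) for t in set(terms)}


# ---------------------------------------------------------------------------
# KC rank (PageRank-style neighbourhood mix)
# ---------------------------------------------------------------------------

def kc_rank(
    pog: Pog,
    kc: TermId,
    scores: Mapping[TermId, TermScore],
    params: RankParams,
) -> KcRank:
    """R(KC) = (1-p1-p2) S(KC) + p1 sum_parents S(v)/Ni(v) + p2 sum_children S(v)/Ni(v).

    Ni(v) counts POG edges entering v (its part-of children); terms without
    entering edges contribute S(v)/1.  At the defaults p1=0.4, p2=0.6 the
    S(KC) coefficient is exactly zero.
    """
    if kc not in pog:
        raise GrankError(f"unknown term: {kc}")
    g = pog.digraph()

    def n_in(v: TermId) -> int:
        return max(g.in_degree(v), 1)

    def s(v: TermId) -> float:
        return scores[v].s

    r = (1.0 - params.p1 - params.p2) * s(kc)
    r += params.p1 * sum(s(v) / n_in(v) for v in sorted(pog.parents(kc)))
    r += params.p2 * sum(s(v) / n_in(v) for v in sorted(pog.children(kc)))
    return KcRank(kc, r)


def rank_wrt_kc(r_kc: KcRank, j: int, params: RankParams) -> float:
    """Rank of a candidate w.r.t. one KC: R(KC) * decay^(j-1).

    j is the number of hierarchical levels between KC and candidate
    (adjacent = 1); non-increasing in j for decay <= 1.
    """
    if j < 1:
        raise GrankError(f"level separation j must be >= 1, got {j}")
    return r_kc.r * params.decay ** (j - 1)


def combined_rank(values: Sequence[float], params: RankParams) -> float:
    """Aggregate per-KC ranks of one gene (max by default, sum optional)."""
    if not values:
        raise GrankError("cannot combine an empty rank list")
    if params.aggregation is Aggregation.MAX:
        return max(values)
    return sum(values)


# ---------------------------------------------------------------------------
# Proximity window
# ---------------------------------------------------------------------------

def layer_positions(depths: DepthMap) -> dict[TermId, int]:
    """Canonical horizontal coordinate: lexicographic rank within each level."""
    by_depth: dict[int, list[TermId]] = {}
    for t, d in depths.depths.items():
        by_depth.setdefault(d, []).append(t)
    pos: dict[TermId, int] = {}
    for d, terms in by_depth.items():
        for i, t in enumerate(sorted(terms)):
            pos[t] = i
    return pos


def proximity(
    depths: DepthMap,
    annotated_terms: Iterable[TermId],
    positions: Optional[Mapping[TermId, int]] = None,
) -> ProximityWindow:
    """Smallest drawing window containing all the query genes' terms.

    height = depth span + 1; width = horizontal span + 1 under the canonical
    within-layer order (all graph terms, lexicographic).  All terms identical
    gives prox = 1.
    """
    terms = sorted(set(annotated_terms))
    if not terms:
        raise GrankError("empty term set")
    if positions is None:
        positions = layer_positions(depths)
    ds = [depths[t] for t in terms]
    xs = [positions[t] for t in terms]
    return ProximityWindow(max(ds) - min(ds) + 1, max(xs) - min(xs) + 1)


# ---------------------------------------------------------------------------
# Overall ranking
# ---------------------------------------------------------------------------

def _level_separation(depths: DepthMap, cand: TermId, kc: TermId) -> int:
    return max(abs(depths[cand] - depths[kc]), 1)


def rank_answers(
    verdicts: Iterable[CandidateVerdict],
    kcs_per_gene: Mapping[str, Iterable[TermId]],
    pog: Pog,
    depths: DepthMap,
    scores: Mapping[TermId, TermScore],
    params: RankParams,
    ann: AnnotationSet,
    query: Optional[Query] = None,
) -> RankedAnswer:
    """Score every meaningful candidate and order the answers.

    Per candidate: sum over query genes of the aggregated decayed KC ranks,
    multiplied by the keyword proximity of all KCs.  Answer genes are the
    candidate's direct annotations, minus the query genes when
    ``params.exclude_query_genes`` (the default).
    """
    meaningful = [v for v in verdicts if v.meaningful]
    all_kcs = sorted({t for ts in kcs_per_gene.values() for t in ts})
    if not all_kcs:
        raise GrankError("no gene has any KC")
    if not meaningful:
        import logging

        logging.getLogger("grank").warning("no meaningful candidate; empty answer")
        return RankedAnswer([])

    prox = proximity(depths, all_kcs).prox
    kc_ranks = {kc: kc_rank(pog, kc, scores, params) for kc in all_kcs}
    exclude = set(query.genes) if (query and params.exclude_query_genes) else set()

    rows: list[AnswerRow] = []
    for v in sorted(meaningful, key=lambda v: (v.candidate, v.role.value)):
        total = 0.0
        for gene in sorted(kcs_per_gene):
            per_kc = [
                rank_wrt_kc(
                    kc_ranks[kc],
                    _level_separation(depths, v.candidate, kc),
                    params,
                )
                for kc in sorted(kcs_per_gene[gene])
            ]
            total += combined_rank(per_kc, params)
        score = total * prox
        genes = tuple(sorted(ann.genes_for_term(v.candidate) - exclude))
        rows.append(AnswerRow(v.candidate, v.role, score, genes))
    rows.sort(key=lambda r: (-r.score, r.term, r.role.value))
    return RankedAnswer(rows)
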