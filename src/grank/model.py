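"""Core domain model: ontology graph, annotations, microarray reference, queries.

The ontology is a typed DAG over GO-style terms with two relations, ``is_a``
and ``part_of``.  Genes are attached to terms by direct annotation; the terms
directly annotating a query gene are its *keyword contexts* (KCs), the units
the search operates on.  A microarray reference supplies the gene universe and
the subset of differentially-expressed ("significant") genes used by the
hypergeometric term score.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import networkx as nx
import obonet

logger = logging.getLogger("grank")

TermId = str


class GrankError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GrankError):
    """Malformed input stream."""


class ValidationError(GrankError):
    """Structurally invalid object (e.g. a cyclic ontology)."""


class QueryError(GrankError):
    """A query that cannot be answered."""


class Relation(enum.Enum):
    IS_A = "is_a"
    PART_OF = "part_of"


@dataclass(frozen=True)
class Term:
    id: TermId
    name: str = ""
    namespace: str = ""


class GoGraph:
    """Typed DAG of ontology terms with ``is_a`` / ``part_of`` edges.

    Edges are stored child -> parent.  The union of both relations (and each
    relation alone) must be acyclic; every edge endpoint must be a known term
    and self-edges are rejected.
    """

    def __init__(
        self,
        terms: Iterable[Term],
        edges: Iterable[tuple[TermId, TermId, Relation]],
    ) -> None:
        self.terms: dict[TermId, Term] = {}
        for t in terms:
            if not t.id:
                raise ValidationError("empty term identifier")
            self.terms[t.id] = t
        self.edges: set[tuple[TermId, TermId, Relation]] = set()
        for child, parent, rel in edges:
            if child == parent:
                raise ValidationError(f"self-edge on {child}")
            for end in (child, parent):
                if end not in self.terms:
                    raise ValidationError(f"edge endpoint {end} is not a known term")
            self.edges.add((child, parent, Relation(rel)))
        self._validate_acyclic()

    # -- construction helpers -------------------------------------------------

    def _validate_acyclic(self) -> None:
        g = self.union_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(u for u, _ in cycle) + " -> " + cycle[-1][1]
            raise ValidationError(f"ontology contains a cycle: {path}")

    def digraph(self, relation: Relation) -> nx.DiGraph:
        """Child -> parent digraph restricted to one relation."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, r in self.edges if r is relation)
        return g

    def union_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for c, p, r in self.edges:
            if g.has_edge(c, p):
                g[c][p]["relations"].add(r)
            else:
                g.add_edge(c, p, relations={r})
        return g

    @property
    def roots(self) -> frozenset[TermId]:
        """Terms with no parent of any relation, one or more per namespace."""
        has_parent = {c for c, _, _ in self.edges}
        return frozenset(t for t in self.terms if t not in has_parent)

    def __contains__(self, term: TermId) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GoGraph):
            return NotImplemented
        return self.terms == other.terms and self.edges == other.edges


@dataclass
class AnnotationSet:
    """Direct gene -> term annotations (no ancestor propagation).

    ``evidence`` optionally records the evidence code of each (gene, term)
    pair so that IEA filtering stays possible downstream.  ``n_dropped``
    counts input pairs discarded because their term was absent from the
    companion graph.
    """

    by_gene: dict[str, set[TermId]] = field(default_factory=dict)
    evidence: dict[tuple[str, TermId], str] = field(default_factory=dict)
    n_dropped: int = 0

    def add(self, gene: str, term: TermId, evidence: Optional[str] = None) -> None:
        if not gene:
            raise ValidationError("empty gene identifier")
        self.by_gene.setdefault(gene, set()).add(term)
        if evidence is not None:
            self.evidence[(gene, term)] = evidence

    def genes_for_term(self, term: TermId) -> frozenset[str]:
        return frozenset(g for g, ts in self.by_gene.items() if term in ts)

    def terms_for_gene(self, gene: str) -> frozenset[TermId]:
        return frozenset(self.by_gene.get(gene, ()))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.by_gene)

    def validate_against(self, graph: GoGraph) -> None:
        for gene, terms in self.by_gene.items():
            for t in terms:
                if t not in graph:
                    raise ValidationError(f"annotation {gene} -> {t}: unknown term")


@dataclass(frozen=True)
class KeywordContext:
    """A term directly annotating a query gene (the searchable unit)."""

    gene: str
    term: TermId


@dataclass(frozen=True)
class MicroarrayReference:
    """Gene universe of a microarray plus its significant subset.

    ``a`` (universe size) and ``c`` (significant count) are the fixed margins
    of the hypergeometric term score.
    """

    universe: frozenset[str]
    significant: frozenset[str]

    def __post_init__(self) -> None:
        if not self.significant <= self.universe:
            raise ValidationError("significant genes must be a subset of the universe")

    @property
    def a(self) -> int:
        return len(self.universe)

    @property
    def c(self) -> int:
        return len(self.significant)


@dataclass(frozen=True)
class Query:
    """Ordered gene keywords; duplicates removed keeping first occurrence."""

    genes: tuple[str, ...]

    def __init__(self, *genes: str) -> None:
        flat: list[str] = []
        for g in genes:
            if g and g not in flat:
                flat.append(g)
        if not flat:
            raise QueryError("empty query")
        object.__setattr__(self, "genes", tuple(flat))


class Aggregation(enum.Enum):
    MAX = "max"
    SUM = "sum"


@dataclass(frozen=True)
class RankParams:
    """Tunable ranking parameters.

    decay
        per-level attenuation of a KC's rank, in (0, 1].
    p1 / p2
        navigation probabilities toward parents / children in the
        PageRank-style KC rank; p1 + p2 <= 1.
    aggregation
        how per-KC ranks of one gene are combined (max by default).
    """

    decay: float = 0.7
    p1: float = 0.4
    p2: float = 0.6
    aggregation: Aggregation = Aggregation.MAX
    exclude_query_genes: bool = True
    iea_filter: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.decay <= 1.0):
            raise ValidationError("decay must be in (0, 1]")
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValidationError("p1 and p2 must be in [0, 1]")
        if self.p1 + self.p2 > 1.0 + 1e-12:
            raise ValidationError("p1 + p2 must not exceed 1")


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def _as_text_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_obo(stream: IO[str] | str) -> GoGraph:
    """Read an OBO 1.2 stream into a :class:`GoGraph`.

    Only ``is_a`` and ``relationship: part_of`` lines become edges; other
    relationship types are ignored with a warning.  Obsolete terms are
    skipped.  Acyclicity is verified on load.
    """
    try:
        multi = obonet.read_obo(_as_text_stream(stream), ignore_obsolete=True)
    except ValidationError:
        raise
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise ParseError(f"malformed OBO input: {exc}") from exc
    terms = [
        Term(n, data.get("name", ""), data.get("namespace", ""))
        for n, data in multi.nodes(data=True)
    ]
    edges: list[tuple[TermId, TermId, Relation]] = []
    ignored: set[str] = set()
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent, Relation.IS_A))
        elif key == "part_of":
            edges.append((child, parent, Relation.PART_OF))
        else:
            ignored.add(key)
    if ignored:
        logger.warning("ignoring relationship types: %s", ", ".join(sorted(ignored)))
    return GoGraph(terms, edges)


def serialize_obo(graph: GoGraph) -> str:
    """Write the ``[Term]`` stanza subset this package reads (round-trips)."""
    lines = ["format-version: 1.2", "ontology: go", ""]
    parents: dict[TermId, list[tuple[Relation, TermId]]] = {}
    for c, p, r in graph.edges:
        parents.setdefault(c, []).append((r, p))
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        if t.name:
            lines.append(f"name: {t.name}")
        if t.namespace:
            lines.append(f"namespace: {t.namespace}")
        for rel, parent in sorted(parents.get(tid, []), key=lambda x: (x[0].value, x[1])):
            if rel is Relation.IS_A:
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    return "\n".join(lines)


def parse_annotations(
    stream: IO[str] | str,
    format: str,
    graph: GoGraph,
) -> AnnotationSet:
    """Read gene -> term annotations from GAF 2.x or 2-column TSV.

    GAF columns used: 3 (symbol), 5 (term), 7 (evidence); ``!`` comments are
    skipped.  Pairs whose term is unknown to ``graph`` are dropped and
    counted; zero surviving pairs is an error.
    """
    fmt = format.strip().lower()
    if fmt not in ("gaf", "tsv"):
        raise ParseError(f"unknown annotation format: {format!r}")
    ann = AnnotationSet()
    for lineno, raw in enumerate(_as_text_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if fmt == "gaf":
            if len(cols) < 7:
                raise ParseError(f"line {lineno}: GAF row has fewer than 7 columns")
            gene, term, evidence = cols[2], cols[4], cols[6]
        else:
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: expected gene<TAB>term")
            gene, term = cols[0].strip(), cols[1].strip()
            evidence = None
        if not gene or not term:
            raise ParseError(f"line {lineno}: empty gene or term field")
        if term not in graph:
            ann.n_dropped += 1
            continue
        ann.add(gene, term, evidence)
    if not ann.by_gene:
        raise ParseError("no annotation pair references a known term")
    if ann.n_dropped:
        logger.warning("dropped %d annotation(s) with unknown terms", ann.n_dropped)
    ann.validate_against(graph)
    return ann


def parse_microarray(stream: IO[str] | str) -> MicroarrayReference:
    """Read a ``gene<TAB>significant`` TSV (flag 0/1; optional header).

    Duplicate genes collapse into one row; a gene is significant if any of
    its rows is flagged 1.
    """
    universe: set[str] = set()
    significant: set[str] = set()
    for lineno, raw in enumerate(_as_text_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ParseError(f"line {lineno}: expected gene<TAB>significant")
        gene, flag = cols[0].strip(), cols[1].strip()
        if lineno == 1 and flag.lower() == "significant":
            continue  # header
        if flag not in ("0", "1"):
            raise ParseError(f"line {lineno}: significance flag must be 0 or 1, got {flag!r}")
        universe.add(gene)
        if flag == "1":
            significant.add(gene)
    return MicroarrayReference(frozenset(universe), frozenset(significant))


def map_query_to_kcs(
    query: Query,
    ann: AnnotationSet,
    iea_filter: bool = False,
) -> dict[str, frozenset[TermId]]:
    """Per query gene, the set of directly annotated terms (its KCs).

    Genes without any annotation are reported with a warning; if no query
    gene is annotated the query is unanswerable.
    """
    kcs: dict[str, frozenset[TermId]] = {}
    missing: list[str] = []
    for gene in query.genes:
        terms = ann.terms_for_gene(gene)
        if iea_filter:
            terms = frozenset(
                t for t in terms if ann.evidence.get((gene, t)) != "IEA"
            )
        if terms:
            kcs[gene] = terms
        else:
            missing.append(gene)
    if missing:
        logger.warning("query gene(s) without annotation: %s", ", ".join(missing))
    if not kcs:
        raise QueryError("query unanswerable: no query gene has any annotation")
    return kcs
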