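"""Worked-example fixture, synthetic data generators, and evaluation helpers.

:func:`figure1_fixture` builds a 29-term biological-process fragment around
nephron development.  The facts it must satisfy (specific edges, depth
equalities, annotations, POG reachability, and the meaningful/meaningless
verdicts of the worked examples) are fixed; the remaining wiring is a
minimal deterministic completion.  :func:`assert_fixture_facts` re-checks
every fact on demand and is run by the test suite on each build.

The simulators produce layered random typed DAGs, uniform annotations and
Bernoulli significance flags for property-based testing.  They emulate the
*shape* of GO-style data (layered specialisation, sparse part-of relations),
not its semantic content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .depth import DepthMap, assign_depths
from .lca_tcd import Role, is_meaningful, lowest_common_ancestors, top_common_descendants
from .model import (
    AnnotationSet,
    GoGraph,
    GrankError,
    MicroarrayReference,
    Relation,
    Term,
    TermId,
)
from .pog import Provenance, build_pog, pog_ancestors, pog_descendants


@dataclass
class FixtureBundle:
    graph: GoGraph
    annotations: AnnotationSet
    microarray: MicroarrayReference


# ---------------------------------------------------------------------------
# The 29-term worked-example fragment
# ---------------------------------------------------------------------------

# (id, name, is-a parent or None)  -- one is-a parent each keeps depths exact
_FIXTURE_TERMS: list[tuple[str, str, Optional[str]]] = [
    # depth 0
    ("GO:0008150", "biological_process", None),
    # depth 1
    ("GO:0032501", "multicellular organismal process", "GO:0008150"),
    ("GO:0032502", "developmental process", "GO:0008150"),
    ("GO:0048869", "cellular developmental process", "GO:0008150"),
    # depth 2
    ("GO:0007275", "multicellular organismal development", "GO:0032501"),
    ("GO:0001822", "kidney development", "GO:0032501"),
    ("GO:0009653", "anatomical structure morphogenesis", "GO:0032502"),
    ("GO:0048731", "system development", "GO:0032502"),
    ("GO:0048856", "anatomical structure development", "GO:0032502"),
    ("GO:0009790", "embryo development", "GO:0032502"),
    ("GO:0030154", "cell differentiation", "GO:0048869"),
    # depth 3
    ("GO:0048513", "organ development", "GO:0048856"),
    ("GO:0009887", "organ morphogenesis", "GO:0009653"),
    ("GO:0009888", "tissue development", "GO:0048856"),
    ("GO:0072001", "renal system development", "GO:0048731"),
    ("GO:0001655", "urogenital system development", "GO:0048731"),
    # depth 4
    ("GO:0072006", "nephron development", "GO:0048513"),
    ("GO:0060429", "epithelium development", "GO:0009888"),
    ("GO:0001657", "ureteric bud development", "GO:0072001"),
    # depth 5
    ("GO:0072009", "nephron epithelium development", "GO:0060429"),
    ("GO:0072077", "renal vesicle morphogenesis", "GO:0060429"),
    ("GO:0072028", "nephron morphogenesis", "GO:0072006"),
    ("GO:0072210", "metanephric nephron development", "GO:0072006"),
    ("GO:0072163", "mesonephric epithelium development", "GO:0060429"),
    # depth 6
    ("GO:0072073", "kidney epithelium development", "GO:0072163"),
    ("GO:0072088", "nephron epithelium morphogenesis", "GO:0072028"),
    ("GO:0072164", "mesonephric tubule development", "GO:0072163"),
    ("GO:0072273", "metanephric nephron morphogenesis", "GO:0072210"),
    # depth 7
    ("GO:0072283", "metanephric renal vesicle morphogenesis", "GO:0072088"),
]

_FIXTURE_PART_OF: list[tuple[str, str]] = [
    ("GO:0048731", "GO:0007275"),
    ("GO:0009887", "GO:0009653"),
    ("GO:0072283", "GO:0072077"),
    ("GO:0072283", "GO:0072088"),
    ("GO:0072283", "GO:0072006"),
    ("GO:0072077", "GO:0072009"),
    ("GO:0072088", "GO:0072009"),
    ("GO:0072088", "GO:0072073"),
    ("GO:0072006", "GO:0048513"),
    ("GO:0072009", "GO:0048513"),
    ("GO:0072073", "GO:0048513"),
]

_FIXTURE_ANNOTATIONS: dict[str, set[str]] = {
    "JAG1": {"GO:0009887", "GO:0072009"},
    "LHX1": {"GO:0072006", "GO:0072077"},
    "Gga.4082": {"GO:0072088"},
    "Ssc.22980": {"GO:0072283"},
    "Ci-FoxI-c": {"GO:0048513"},
    "FKH-4": {"GO:0048513"},
    "fkh-5": {"GO:0048513"},
    "TFAP2B": {"GO:0072009"},
    "PANDA_003456": {"GO:0072009"},
}

# Synthetic significance flags for the fixture genes (deterministic; the
# worked microarray example uses its own 14500-gene margins directly).
_FIXTURE_SIGNIFICANT = {"LHX1", "Gga.4082", "Ssc.22980", "TFAP2B"}


def figure1_fixture() -> FixtureBundle:
    """Build the 29-term fragment with annotations and a small microarray."""
    terms = [Term(tid, name, "biological_process") for tid, name, _ in _FIXTURE_TERMS]
    edges: list[tuple[str, str, Relation]] = []
    for tid, _, parent in _FIXTURE_TERMS:
        if parent is not None:
            edges.append((tid, parent, Relation.IS_A))
    for child, parent in _FIXTURE_PART_OF:
        edges.append((child, parent, Relation.PART_OF))
    graph = GoGraph(terms, edges)

    ann = AnnotationSet()
    for gene, ts in sorted(_FIXTURE_ANNOTATIONS.items()):
        for t in sorted(ts):
            ann.add(gene, t, evidence="EXP")
    ann.validate_against(graph)

    ref = MicroarrayReference(
        frozenset(_FIXTURE_ANNOTATIONS), frozenset(_FIXTURE_SIGNIFICANT)
    )
    return FixtureBundle(graph, ann, ref)


def assert_fixture_facts(bundle: FixtureBundle) -> None:
    """Assert every encoded worked-example fact; raise listing violations."""
    g = bundle.graph
    failures: list[str] = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            failures.append(msg)

    check(len(g) == 29, f"expected 29 terms, got {len(g)}")
    check(
        ("GO:0032501", "GO:0008150", Relation.IS_A) in g.edges,
        "missing GO:0032501 is-a GO:0008150",
    )
    check(
        ("GO:0007275", "GO:0032501", Relation.IS_A) in g.edges,
        "missing GO:0007275 is-a GO:0032501",
    )
    check(
        ("GO:0048731", "GO:0007275", Relation.PART_OF) in g.edges,
        "missing GO:0048731 part-of GO:0007275",
    )

    depths = assign_depths(g)
    for group in (
        ("GO:0032501", "GO:0032502"),
        ("GO:0001822", "GO:0048731", "GO:0007275", "GO:0009653"),
        ("GO:0072009", "GO:0072077"),
        ("GO:0072073", "GO:0072088"),
    ):
        ds = {depths[t] for t in group}
        check(len(ds) == 1, f"depth equality violated for {group}: {ds}")

    for gene, ts in _FIXTURE_ANNOTATIONS.items():
        check(
            bundle.annotations.terms_for_gene(gene) == frozenset(ts),
            f"annotation mismatch for {gene}",
        )

    pog = build_pog(g)
    check(
        pog.edges.get(("GO:0048731", "GO:0008150")) is Provenance.INFERRED,
        "missing inferred GO:0048731 part-of GO:0008150",
    )
    anc = lambda t: pog_ancestors(pog, t)
    desc = lambda t: pog_descendants(pog, t)
    check("GO:0072009" in anc("GO:0072077"), "GO:0072009 not ancestor of GO:0072077")
    check("GO:0072009" in anc("GO:0072088"), "GO:0072009 not ancestor of GO:0072088")
    check("GO:0048513" in anc("GO:0072006"), "GO:0048513 not ancestor of GO:0072006")
    check("GO:0048513" in anc("GO:0072088"), "GO:0048513 not ancestor of GO:0072088")
    check("GO:0072073" in anc("GO:0072088"), "GO:0072073 not on GO:0072088 ancestry")
    for kc in ("GO:0072006", "GO:0072077", "GO:0072088"):
        check(
            "GO:0072283" in desc(kc), f"GO:0072283 not descendant of {kc}"
        )

    # Worked-example verdicts (the six boolean assertions)
    cases = [
        ("GO:0072009", Role.LCA, {"GO:0072088", "GO:0072077"}, False),
        ("GO:0048513", Role.LCA, {"GO:0072006", "GO:0072088"}, False),
        ("GO:0072283", Role.TCD, {"GO:0072006", "GO:0072088"}, True),
        ("GO:0072283", Role.TCD, {"GO:0072088", "GO:0072077"}, True),
        ("GO:0048513", Role.LCA, {"GO:0072006", "GO:0072009"}, True),
        ("GO:0072283", Role.TCD, {"GO:0072006", "GO:0072009"}, False),
    ]
    for cand, role, kcs, expected in cases:
        v = is_meaningful(pog, depths, kcs, cand, role)
        check(
            v.meaningful == expected,
            f"{cand} as {role.value} of {sorted(kcs)}: "
            f"expected meaningful={expected}, got {v.meaningful}",
        )

    check(
        "GO:0072009" in lowest_common_ancestors(pog, {"GO:0072088", "GO:0072077"}),
        "GO:0072009 not an LCA of {GO:0072088, GO:0072077}",
    )
    check(
        "GO:0072283" in top_common_descendants(pog, {"GO:0072006", "GO:0072088"}),
        "GO:0072283 not a TCD of {GO:0072006, GO:0072088}",
    )

    if failures:
        raise AssertionError(
            "fixture facts violated:\n  " + "\n  ".join(failures)
        )


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_ontology(
    n_terms: int,
    is_a_density: float = 0.15,
    part_of_fraction: float = 0.2,
    max_depth: int = 6,
    seed: int = 0,
) -> GoGraph:
    """Random layered typed DAG.

    Terms are placed on layers 0..max_depth; every non-root term gets one
    is-a parent on the layer directly above (so its longest is-a distance to
    the root equals its layer, bounded by ``max_depth``), plus extra is-a
    parents from any higher layer with probability ``is_a_density`` and
    part-of parents from strictly higher layers with probability
    ``part_of_fraction``.
    """
    if n_terms < 1:
        raise GrankError("n_terms must be positive")
    if max_depth < 0:
        raise GrankError("max_depth must be non-negative")
    if not (0 <= is_a_density <= 1 and 0 <= part_of_fraction <= 1):
        raise GrankError("densities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_layers = min(max_depth + 1, n_terms)
    layer_of: dict[str, int] = {}
    layers: list[list[str]] = [[] for _ in range(n_layers)]
    ids = [f"SIM:{i:07d}" for i in range(n_terms)]
    for i, tid in enumerate(ids):
        layer = 0 if i == 0 else (i % (n_layers - 1)) + 1 if n_layers > 1 else 0
        layer_of[tid] = layer
        layers[layer].append(tid)

    terms = [Term(tid, f"simulated term {tid}", "simulated") for tid in ids]
    edges: list[tuple[str, str, Relation]] = []
    edge_set: set[tuple[str, str]] = set()
    for tid in ids:
        layer = layer_of[tid]
        if layer == 0:
            continue
        parent = layers[layer - 1][int(rng.integers(len(layers[layer - 1])))]
        edges.append((tid, parent, Relation.IS_A))
        edge_set.add((tid, parent))
        for upper in range(layer):
            for cand in layers[upper]:
                if (tid, cand) in edge_set:
                    continue
                u = rng.random()
                if u < is_a_density:
                    edges.append((tid, cand, Relation.IS_A))
                    edge_set.add((tid, cand))
                elif u < is_a_density + part_of_fraction:
                    edges.append((tid, cand, Relation.PART_OF))
                    edge_set.add((tid, cand))
    return GoGraph(terms, edges)


def simulate_annotations(
    graph: GoGraph,
    n_genes: int,
    mean_terms_per_gene: float = 2.0,
    seed: int = 0,
) -> AnnotationSet:
    """Uniform random direct annotations, ~Poisson(mean) terms per gene."""
    if n_genes < 1 or mean_terms_per_gene <= 0:
        raise GrankError("need n_genes >= 1 and a positive mean")
    rng = np.random.default_rng(seed)
    terms = sorted(graph.terms)
    ann = AnnotationSet()
    for i in range(n_genes):
        gene = f"gene{i:05d}"
        n = max(1, int(rng.poisson(mean_terms_per_gene)))
        for t in rng.choice(terms, size=min(n, len(terms)), replace=False):
            ann.add(gene, str(t), evidence="IEA" if rng.random() < 0.5 else "EXP")
    ann.validate_against(graph)
    return ann


def simulate_microarray(
    genes: Iterable[str],
    significant_fraction: float = 0.1,
    seed: int = 0,
) -> MicroarrayReference:
    """Bernoulli significance flags over a gene universe."""
    if not (0 <= significant_fraction <= 1):
        raise GrankError("significant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(set(genes))
    significant = frozenset(
        g for g in universe if rng.random() < significant_fraction
    )
    return MicroarrayReference(frozenset(universe), significant)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalResult:
    recall: float
    precision: Optional[float]  # None when no gene was retrieved (m = 0)
    n: int
    m: int


def recall_precision(answer_genes: Iterable[str], pathway_genes: Iterable[str]) -> EvalResult:
    """Recall = |A ∩ P| / |P|, precision = |A ∩ P| / |A|.

    The pathway set must be non-empty; an empty answer leaves precision
    undefined (None) rather than zero.
    """
    answer = set(answer_genes)
    pathway = set(pathway_genes)
    if not pathway:
        raise GrankError("empty pathway gene set")
    hit = len(answer & pathway)
    n, m = len(pathway), len(answer)
    if m == 0:
        import logging

        logging.getLogger("grank").warning("no retrieved gene; precision undefined")
        return EvalResult(hit / n, None, n, m)
    return EvalResult(hit / n, hit / m, n, m)


@dataclass(frozen=True)
class CriterionLabel:
    """Graph-shape classification of a query's KCs.

    relation: 1 = is-a-only ancestry, 2 = part-of-only, 3 = mixed.
    level: 4 = all KCs shallow (depth < 6), 5 = all deep, 6 = mixed.
    """

    relation: int
    level: int

    def __post_init__(self) -> None:
        if self.relation not in (1, 2, 3) or self.level not in (4, 5, 6):
            raise GrankError("invalid criterion label")


def classify_criterion(
    graph: GoGraph, depths: DepthMap, kcs: Iterable[TermId]
) -> CriterionLabel:
    """Classify a KC set by ancestry relation types and depth regime."""
    kcs = sorted(set(kcs))
    if not kcs:
        raise GrankError("empty KC set")
    for t in kcs:
        if t not in graph:
            raise GrankError(f"unknown term: {t}")

    union = graph.union_digraph()
    rel_types: set[Relation] = set()
    for kc in kcs:
        frontier = [kc]
        seen = {kc}
        while frontier:
            node = frontier.pop()
            for _, parent, data in union.out_edges(node, data=True):
                rel_types |= data["relations"]
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
    if rel_types == {Relation.IS_A}:
        relation = 1
    elif rel_types == {Relation.PART_OF}:
        relation = 2
    else:
        relation = 3  # mixed (or no ancestry at all, treated as mixed)

    shallow = [depths[t] < 6 for t in kcs]
    if all(shallow):
        level = 4
    elif not any(shallow):
        level = 5
    else:
        level = 6
    return CriterionLabel(relation, level)
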