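"""End-to-end query pipeline.

Stages: map query genes to KCs -> build the Part-Of Graph -> assign is-a
depths -> enumerate and judge LCA/TCD candidates -> rank the meaningful ones
and convert them back to genes via direct annotation.  The POG and depth map
depend only on the ontology, so they are cached on disk keyed by a content
hash of the OBO input when a cache directory is configured.
"""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .depth import DepthMap, assign_depths, read_depths_tsv, write_depths_tsv
from .lca_tcd import (
    CandidateVerdict,
    meaningful_candidates,
    write_verdicts_tsv,
)
from .model import (
    AnnotationSet,
    GoGraph,
    GrankError,
    MicroarrayReference,
    Query,
    RankParams,
    map_query_to_kcs,
    parse_annotations,
    parse_microarray,
    parse_obo,
)
from .pog import Pog, build_pog, read_pog_tsv, write_pog_tsv
from .ranking import RankedAnswer, rank_answers, score_terms


@dataclass
class EngineConfig:
    obo_path: Path
    annotations_path: Path
    annotations_format: str = "tsv"
    microarray_path: Optional[Path] = None
    params: RankParams = field(default_factory=RankParams)
    path_semantics: str = "all"
    partof_transitivity: bool = True
    top: Optional[int] = None
    cache_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        for p in (self.obo_path, self.annotations_path, self.microarray_path):
            if p is not None and not Path(p).exists():
                raise GrankError(f"input file not found: {p}")


@dataclass
class QueryResult:
    query: Query
    answers: RankedAnswer
    kcs_per_gene: dict[str, frozenset[str]]
    discarded: list[CandidateVerdict]
    n_candidates: int
    elapsed_s: float

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("rank\tterm\trole\tscore\tgenes\n")
        for i, row in enumerate(self.answers, start=1):
            out.write(
                f"{i}\t{row.term}\t{row.role.value}\t{row.score:.6g}\t"
                f"{','.join(row.genes)}\n"
            )
        return out.getvalue()

    def to_json(self) -> str:
        payload = {
            "query": list(self.query.genes),
            "kcs": {g: sorted(ts) for g, ts in sorted(self.kcs_per_gene.items())},
            "answers": [
                {
                    "term": row.term,
                    "role": row.role.value,
                    "score": row.score,
                    "genes": list(row.genes),
                }
                for row in self.answers
            ],
            "discarded": io_verdicts(self.discarded),
            "n_candidates": self.n_candidates,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def io_verdicts(verdicts: list[CandidateVerdict]) -> list[dict]:
    buf = io.StringIO()
    write_verdicts_tsv(verdicts, buf)
    rows = buf.getvalue().splitlines()[1:]
    out = []
    for row in rows:
        cand, role, meaningful, witness = row.split("\t")
        out.append(
            {
                "candidate": cand,
                "role": role,
                "meaningful": bool(int(meaningful)),
                "witness": witness,
            }
        )
    return out


def _ontology_cache_key(obo_text: str, partof_transitivity: bool) -> str:
    h = hashlib.sha256()
    h.update(obo_text.encode())
    h.update(b"partof_transitivity=1" if partof_transitivity else b"0")
    return h.hexdigest()[:16]


def prepare_ontology(
    graph: GoGraph,
    obo_text: Optional[str] = None,
    cache_dir: Optional[Path] = None,
    partof_transitivity: bool = True,
) -> tuple[Pog, DepthMap]:
    """Build (or load from cache) the POG and depth map for an ontology."""
    if cache_dir is not None and obo_text is not None:
        key = _ontology_cache_key(obo_text, partof_transitivity)
        pog_file = Path(cache_dir) / f"{key}.pog.tsv"
        dep_file = Path(cache_dir) / f"{key}.depths.tsv"
        if pog_file.exists() and dep_file.exists():
            return (
                read_pog_tsv(pog_file.read_text().splitlines()),
                read_depths_tsv(dep_file.read_text().splitlines()),
            )
    pog = build_pog(graph, partof_transitivity=partof_transitivity)
    depths = assign_depths(graph)
    if cache_dir is not None and obo_text is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        with open(pog_file, "w") as fh:
            write_pog_tsv(pog, fh)
        with open(dep_file, "w") as fh:
            write_depths_tsv(depths, fh)
    return pog, depths


def run_query_objects(
    graph: GoGraph,
    ann: AnnotationSet,
    ref: Optional[MicroarrayReference],
    query: Query,
    params: Optional[RankParams] = None,
    path_semantics: str = "all",
    partof_transitivity: bool = True,
    pog: Optional[Pog] = None,
    depths: Optional[DepthMap] = None,
) -> QueryResult:
    """Run the full pipeline on in-memory objects.

    Without a microarray reference every term scores 0, so ranking degrades
    to the deterministic candidate/proximity structure (scores all zero).
    """
    t0 = time.perf_counter()
    params = params or RankParams()
    if pog is None:
        pog = build_pog(graph, partof_transitivity=partof_transitivity)
    if depths is None:
        depths = assign_depths(graph)
    kcs = map_query_to_kcs(query, ann, iea_filter=params.iea_filter)
    verdicts = meaningful_candidates(pog, depths, kcs, path_semantics)

    if ref is None:
        ref = MicroarrayReference(frozenset(), frozenset())
    needed = {t for ts in kcs.values() for t in ts}
    for t in set(needed):
        needed |= pog.parents(t) | pog.children(t)
    scores = score_terms(ref, ann, needed)

    answers = rank_answers(verdicts, kcs, pog, depths, scores, params, ann, query)
    discarded = [v for v in verdicts if not v.meaningful]
    return QueryResult(
        query=query,
        answers=answers,
        kcs_per_gene={g: frozenset(ts) for g, ts in kcs.items()},
        discarded=discarded,
        n_candidates=len(verdicts),
        elapsed_s=time.perf_counter() - t0,
    )


def run_query(config: EngineConfig, query: Query) -> QueryResult:
    """File-based entry point: parse all inputs, then run the pipeline."""
    obo_text = Path(config.obo_path).read_text()
    graph = parse_obo(obo_text)
    ann = parse_annotations(
        Path(config.annotations_path).read_text(),
        config.annotations_format,
        graph,
    )
    ref = None
    if config.microarray_path is not None:
        ref = parse_microarray(Path(config.microarray_path).read_text())
    pog, depths = prepare_ontology(
        graph, obo_text, config.cache_dir, config.partof_transitivity
    )
    result = run_query_objects(
        graph,
        ann,
        ref,
        query,
        params=config.params,
        path_semantics=config.path_semantics,
        pog=pog,
        depths=depths,
    )
    if config.top is not None:
        result.answers.rows = result.answers.rows[: config.top]
    return result
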