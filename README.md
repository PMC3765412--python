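# grank

Ontology-driven gene search: given a set of query genes, find and rank other
genes that are *semantically related* to them through the structure of the
Gene Ontology (GO), using existence-dependency reasoning over part-of
relations rather than plain term proximity.

**Who it is for.** Biologists and bioinformaticians who have a gene list
(e.g. genes implicated in a disease) and want candidate genes with closely
related function, with an explanation of *why* each candidate is related
(which shared ancestor or descendant term links them, and why that link is
structurally sound).

## Method

1. **Keyword contexts (KCs).** Each query gene g is mapped to the GO terms
   directly annotating it. These terms are the KCs of the query.

2. **Part-Of Graph (POG).** The GO DAG (is-a + part-of edges) is converted
   to a graph of part-of relations only: explicit part-of edges plus every
   edge inferable from *A is-a B, B part-of C ⇒ A part-of C* and
   *A part-of B, B is-a C ⇒ A part-of C* (and part-of transitivity),
   applied to a fixed point.

3. **Depths.** Every term gets a depth DPT(x) = length of its longest
   is-a-only chain from the root; part-of edges never contribute.

4. **Meaningful LCAs / TCDs.** Candidates are the lowest common ancestors
   and top common descendants of the KCs in the POG. A candidate is
   *meaningful* iff (i) its depth differs from every KC's depth and
   (ii) no POG path between candidate and KC contains two equal-depth terms
   (terms of equal depth cannot be existence-dependent on each other).

5. **Ranking.** Each term v gets a microarray score — the cumulative
   hypergeometric mass

   S(v) = Σ_{i=0}^{k−1} C(b,i)·C(a−b, c−i) / C(a,c)

   with a = microarray universe size, b = universe genes annotated to v,
   c = significant genes, k = significant genes annotated to v. A
   PageRank-style rank mixes a KC's own score with its POG neighbours':
   R(KC) = (1−p1−p2)·S(KC) + p1·Σ_parents S(v)/Ni(v) + p2·Σ_children S(v)/Ni(v),
   with Ni(v) the number of POG edges entering v (defaults p1 = 0.4,
   p2 = 0.6). A candidate's rank w.r.t. one KC is R(KC)·decay^(j−1) with
   j the level separation (default decay 0.7); per-gene ranks are
   aggregated (max by default), summed over query genes, and multiplied by
   a keyword-proximity factor 1/(height × width) of the smallest drawing
   window containing all KCs. Genes annotated to the surviving candidates
   are returned, best candidate first.

## Worked example

The package ships a 29-term nephron-development fragment of GO with ten
annotated genes (`grank fixture` writes it as OBO/TSV files):

```sh
grank fixture --out-dir demo
grank query --obo demo/fixture.obo --annotations demo/annotations.tsv \
            --array demo/microarray.tsv --genes Gga.4082,LHX1
```

prints

```
rank	term	role	score	genes
1	GO:0060429	LCA	0.0989418
2	GO:0072283	TCD	0.0989418	Ssc.22980
3	GO:0009888	LCA	0.0840741
```

The KCs are GO:0072088 (for Gga.4082) and GO:0072006 / GO:0072077 (for
LHX1). Their only meaningful annotated candidate is the top common
descendant GO:0072283 (*metanephric renal vesicle morphogenesis*), so the
gene annotated to it — **Ssc.22980** — is the answer. The shared ancestors
GO:0072009 and GO:0048513 are rejected: GO:0072009 has the same depth as
the KC GO:0072077, and the POG path from GO:0072088 up to GO:0048513 passes
two equal-depth terms (GO:0072073, GO:0072088). Querying `JAG1,LHX1`
instead makes GO:0048513 a *meaningful* LCA and returns Ci-FoxI-c, FKH-4
and fkh-5 while excluding Ssc.22980 — the candidate set is query-dependent,
not a fixed neighbourhood.

The same pipeline is available as a library:

```python
from grank import figure1_fixture, run_query_objects, Query
b = figure1_fixture()
result = run_query_objects(b.graph, b.annotations, b.microarray,
                           Query("Gga.4082", "LHX1"))
result.answers.genes   # ('Ssc.22980',)
```

`grank simulate` generates random layered typed DAGs with annotations and
microarray flags for experimentation, and `grank eval` computes per-pathway
recall/precision of a result file against reference gene sets.

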