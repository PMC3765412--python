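# Methods

## Model

The search operates on a typed DAG G = (V, E) of ontology terms with two
relation kinds, is-a and part-of, both stored child → parent. Genes attach
to terms by *direct* annotation only; annotations are never propagated to
ancestors, because the worked examples the package encodes return a gene
only through its own term. A query Q(g1..gm) is answered in five stages:
KC mapping → POG construction → depth assignment → meaningful-candidate
detection → ranking. Each stage is a pure function of its inputs, so the
pipeline is deterministic end to end (byte-identical output for identical
input, which the tests verify by hashing).

### Part-Of Graph

Part-of is read as (a proxy for) existence dependency: if B is part of A,
the presence of B implies the presence of A. Two composition rules create
inferred part-of edges — is-a ∘ part-of and part-of ∘ is-a — and part-of
composes with itself (GO treats part-of as transitive). Applied to a fixed
point, the inferred edge set is exactly: all ordered pairs (x, z) joined by
a directed path using at least one part-of edge. The implementation
computes this as a reachability problem on the product graph
(node, used-part-of?) in O(V·(V+E)) rather than by naive rule iteration;
the test suite checks equality with a repeat-until-stable rule-application
oracle on hundreds of random typed DAGs. `partof_transitivity=False`
(CLI `--no-partof-transitivity`) restricts the closure to the two
composition rules alone, which yields exactly the pairs joined by an
is-a* part-of is-a* path; that variant is cross-checked the same way.
Every node of the source graph is kept in the POG even when isolated, so
queries whose KCs are attached only by is-a edges still resolve (they
simply produce no candidates).

### Depth

DPT(x) is the length of the longest chain of is-a edges above x. Depth is
computed on the is-a subgraph alone by dynamic programming over a
topological order (linear time); consequently it is *invariant to part-of
edges*, a property the tests perturb-and-check. Terms without is-a parents
are the depth-0 bases. A base that is not a true root (it has part-of
parents but no is-a parent) is flagged "unrooted", as are its is-a
descendants; their depths are then measured from the local is-a source.
This keeps the two desired properties simultaneously — every is-a edge
strictly increases depth, and inserting or removing part-of edges never
changes any depth — at the cost of assigning small depths to part-of-only
subtrees, which real GO namespaces do not contain (every GO term has an
is-a path to its namespace root). Depths render as spreadsheet-style level
labels (0 → A, 26 → AA) for display only.

### Meaningful LCAs and TCDs

Candidate terms are the lowest common ancestors and top common descendants
of one KC chosen per query gene, in the POG, where each KC counts as its
own ancestor/descendant (so a singleton KC set returns the KC itself, and
single-gene queries return co-annotated genes). "Lowest" prunes any common
ancestor that still has a POG descendant in the common set; note that with
inferred edges the common set may contain chains linked only by is-a in the
source graph, which are *not* POG-comparable and therefore survive pruning
— candidate sets can be larger than the drawn examples, and the tests
assert membership, not exhaustiveness.

A candidate is meaningful w.r.t. a KC set iff for every KC (1) the depths
differ and (2) the POG paths between candidate and KC, endpoints included,
contain no two equal-depth terms. Two terms of equal depth are of the same
"type" and cannot be existence-dependent on each other; a chain containing
such a pair cannot transport dependency. Path quantification defaults to
*universal* (`--path-semantics=all`): one bad path anywhere condemns the
candidate. This reading is forced by the encoded worked example in which a
descendant reachable both directly and through an equal-depth intermediate
is judged meaningless; the lenient `exists` variant is provided and tested
but is not the default. Candidates identical to a KC (in multi-KC sets)
fail condition (1) trivially. All iteration — KC order, path enumeration,
candidate order — is lexicographic by term id, so the reported witness
(either the equal-depth KC or the offending path with its equal-depth
pair) is deterministic. Every discarded candidate is kept in the query
diagnostics with its witness.

Complexity caveat: condition (2) enumerates simple paths, which is
exponential in the worst case. Between a candidate and a KC in real
ontology fragments the path count is small; the package targets
desk-scale ontologies and documents this as its main scalability limit.

### Ranking

* **Term score.** S(v) = P(X ≤ k−1) for X hypergeometric with universe a,
  annotated b, draws c — the left tail of Fisher's exact test. b and k are
  computed on the intersection of the term's genes with the microarray
  universe; b = 0 scores 0. The sum is evaluated through scipy's log-space
  hypergeometric CDF and agrees with an exact rational (Fraction)
  enumeration to 1e−10 across randomised parameters; k−1 ≥ min(b, c)
  saturates at exactly 1, k = 0 is the empty sum 0. The printed value of
  the worked 14500/10153/417/300 example in the original write-up is 0.73;
  the exact sum evaluates to 0.7918, and the exact value is the frozen
  regression baseline (the discrepancy is documented in the acceptance
  test).
* **KC rank.** R(KC) = (1−p1−p2)·S(KC) + p1·Σ_parents S(v)/Ni(v) +
  p2·Σ_children S(v)/Ni(v) over the POG neighbourhood (the containment
  graph), with Ni(v) = number of POG edges entering v, floored at 1 for
  sources. The first sum runs over parents (navigating *from* the KC
  upward, weight p1 = 0.4) and the second over children (navigating toward
  the KC, weight p2 = 0.6), mirroring the in/out-link asymmetry of
  PageRank; at the defaults the S(KC) coefficient is exactly 0, which the
  tests pin down. `--kcrank` neighbourhood on the raw GO graph was
  considered and rejected: the method's own containment argument is about
  part-of edges.
* **Decay and aggregation.** Rank w.r.t. one KC is R(KC)·decay^(j−1),
  j = |DPT(candidate) − DPT(KC)| floored at 1; the same formula applies to
  TCDs (levels below) since only the magnitude of the separation matters.
  A gene's KC ranks combine by max (default) or sum; the overall score
  sums the per-gene combined ranks.
* **Proximity.** The KC set of the whole query spans a window of the
  canonical drawing: height = depth span + 1; width = horizontal span + 1,
  where a term's horizontal coordinate is its lexicographic rank among all
  graph terms of the same depth. prox = 1/(height·width) ∈ (0, 1], equal
  to 1 when all genes are co-annotated to one term. The original "left/
  right-most" wording presumes a figure; the lexicographic layout is the
  deterministic substitute and is documented as such.

Defaults decay = 0.7, p1 = 0.4, p2 = 0.6 are the method's stated operating
point and are not tuned here. Query genes are excluded from answers by
default (`--include-query-genes` reverts), matching both worked queries.

## Worked-example fixture

`figure1_fixture()` encodes the 29-term biological-process fragment used by
all worked examples. The published figure is not machine-readable, so the
fixture is the conjunction of its *stated facts* — the named is-a/part-of
edges, four depth-equality groups, ten gene annotations, the POG
reachability claims, and the six meaningful/meaningless verdicts — plus a
minimal deterministic completion (single is-a parents chosen so the depth
groups come out exact, filler terms to reach 29). `assert_fixture_facts`
re-verifies every fact computationally on each build; the fact suite, not
the completion, is the fixture's contract. One encoded inconsistency is
preserved deliberately: the gene JAG1 is annotated to both GO:0009887 (as
introduced) and GO:0072009 (as used in the second worked query). The
bundled 10-gene microarray reference is synthetic (deterministic flags);
the worked 14500-gene score example is exercised with explicitly
constructed gene sets instead.

## Synthetic data

`simulate_ontology` builds layered DAGs: every non-root term takes one is-a
parent on the layer directly above — making its longest is-a path equal to
its layer, so the depth bound is exact by construction — plus extra is-a
and part-of parents from higher layers with the given densities.
`simulate_annotations` draws ~Poisson(mean) uniform terms per gene with
random IEA/EXP evidence; `simulate_microarray` flags genes Bernoulli(f).
All generators take a seed and are reproducible. What they emulate is the
*shape* of GO-scale inputs (layering, sparse part-of, skewed annotation
counts), not biological semantics: passing property tests on them shows the
algorithms are correct on arbitrary typed DAGs, not that the ranking is
biologically validated — the latter would require the external pathway
benchmarks, which are out of scope here. Oracle-equivalence tests run on
~200 random graphs of ≤ 12–15 nodes per algorithm; sizes were chosen so
exhaustive path/fixpoint oracles stay exact and the whole suite runs in
seconds.

## Numerical and degenerate-input choices

* Hypergeometric tails in log space (scipy), never raw factorials.
* All floating comparisons in tests at 1e−10 or better; no tolerance hides
  an algorithmic difference.
* Ties in the final ordering break lexicographically by term id, then
  role.
* Degenerate inputs: empty query → error; query with no annotated gene →
  "query unanswerable" error; no meaningful candidate → empty answer with
  a warning (not an error); empty pathway set in evaluation → error;
  retrieved-set size 0 → precision undefined (None), not 0.
* Cycles, self-edges, dangling edge endpoints and non-binary significance
  flags are rejected at parse time with named offenders.

## Known limitations

* Simple-path enumeration in the meaningfulness test is exponential in
  pathological POGs (dense inferred closures).
* Depths of part-of-only subtrees are local, not global (see Depth above).
* The microarray reference treats significance as a given binary flag;
  no expression processing is performed.
* Recall/precision evaluation compares gene sets only; it does not model
  the ranking order (no precision-at-k).
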