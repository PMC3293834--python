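# Methods

## Filter semantics

All identifiers are compared case-insensitively after whitespace trimming;
edges are undirected and stored with lexicographically ordered endpoints.
Genetic interactions carry no sign or direction: the filters only ask
whether an edge exists.

**Alias resolution.** A name resolves to every canonical gene id whose
alias set contains it. Ambiguous names resolve to the full candidate set
and a filter passes if *any* candidate pair interacts; this biases toward
retention, which is the right failure mode for a filter whose job is to
keep true motifs. A motif whose source or target cannot be resolved
against the GI sources *fails* the basic and node filters with an
explanatory note rather than raising — filters run over thousands of rows
and must not abort on one. The HomoloGene filter instead falls back to the
raw canonical name, because a gene absent from every GI database can still
have homologs that interact.

**GI-node filter.** The iterative prose ("repeat for N iterations,
expanding the interacting gene sets") is ambiguous about whether the
expanded sets accumulate. We fix the semantics as *cumulative balls*: at
iteration *i* the radius-*i* balls around the resolved source and target
sets are checked for a joining edge. Consequences we rely on and test:

- pass(basic) ⊆ pass(node, N=1) ⊆ pass(node, N=2) ⊆ … (monotone chain),
  because the direct edge always joins the radius-1 balls;
- for distinct S ≠ T the decision is exactly "shortest GI path ≤ 2N + 1",
  which gives an independent BFS oracle.

The frontier-only alternative was rejected: it can miss the direct edge,
breaking the nesting that the filters' measured sensitivities display.
Edge cases: a motif with S = T passes the basic filter only if a self-loop
edge exists (conservative; such rows are legal input), while the node
filter additionally passes a self-pair whose ball contains any internal
edge (a closed interaction walk through a common neighbor) — the
shortest-path equivalence is only claimed for distinct pairs. Node counts
above 4 trigger a warning: selectivity degrades so badly there that
results are not meaningful; the shipped default is N = 2.

**GI-HomoloGene filter.** Cluster membership comes from a HomoloGene-style
flat file; a gene belongs to at most one cluster, and unmapped genes act
as singleton clusters with *unknown* taxon. The filter passes if any
member of the source's cluster interacts with any member of the target's
cluster. With the same-species constraint (default on), a qualifying pair
must share a taxon and unknown-taxon members never qualify; the
interacting pair may be S and T themselves, so on taxon-complete data the
filter retains a superset of the basic filter. Relaxing the constraint
can only add passes, never remove one.

**Composition and polarity.** Union passes iff any constituent passes,
intersection iff all; witnesses are merged. Exclude polarity complements
the verdict and moves the witness into the note so reports stay auditable.

## Evaluation

Selectivity here is the percentage of true negatives *accepted* — a
false-positive rate, deliberately kept in this nonstandard form because
the discrimination ratio DR = sensitivity/selectivity is only meaningful
under it (DR > 1 favorable). Display rounding is one decimal; internal
values keep full precision.

Negative sets are uniform random distinct source≠target gene pairs. The
`pure_random` policy does not exclude known interactions — the rationale
is quantitative: the known GIs are a negligible fraction of all n(n−1)/2
pairs. An `exclude_known` policy is available for stricter benchmarking.

The ROC needs a graded score, and "passes filter X" is binary, so the
harness defines a documented GI-evidence score: 1/(1 + d) with d the
shortest GI-path length between the resolved endpoint sets (0 when
disconnected or unresolved), plus a bonus of 1e-6 · m/(m + 1) where m
counts endpoint candidates at distance d. The bonus is bounded below the
gap between any two consecutive 1/(1 + d) values on graphs of reasonable
diameter, so score ordering always agrees with BFS distance; the AUC from
the threshold sweep equals the Mann–Whitney concordance estimate (ties
counted half), which the tests verify against exhaustive pair counting
and an independent library implementation. Published AUC values were
produced by an unspecified ranking construction and are therefore not
comparison targets; the ROC machinery is instead governed by these
property checks.

## Synthetic worlds

The generator emulates the structure of a motif-validation study rather
than real biology: genes partitioned across a few species, positive
motifs as distinct uniform same-species (S, T) pairs, GI edges planted
under positives with probability `p_pos_gi_edge` (default 0.212 — about
one in five validated motif pairs has a known GI), random-pair negatives
colliding with a GI edge with probability `p_neg_gi_edge` (default
0.029), optional Erdős–Rényi background edges within species, homolog
clusters spanning species, planted edges copied to homologous pairs in
other species with `gi_conservation_rate` (default 0.29, the ballpark GI
conservation between closely related yeasts), and PPI edges co-occurring
with GI evidence (`p_ppi_given_gi` = 0.885, `p_ppi_no_gi` = 0.13 — chosen
so that on 3000 positives the GI∪PPI union retains ~8.4% more motifs than
the PPI filter alone, matching the published overlap between the two
evidence types). Positive and negative pairs are mutually distinct, so
planted rates translate directly into binomial pass rates; evaluation
numbers computed on a world are expected to sit within ~3σ binomial error
of the planted rates, which is exactly what the acceptance checks assert
(3000 positives / 27,000 negatives gives 3σ ≈ 2.2 points on sensitivity
and ≈ 0.3 points on selectivity). Conserved-copy edges can coincide with
a sampled negative pair, adding a small (<0.1 point) positive bias to
measured selectivity; this is well inside the tolerance and left in
place as an honest artifact of cross-species copying.

Design choices worth noting:

- `per_activity_gi_rates` defaults to `None` (the flat `p_pos_gi_edge`
  governs all activities). The observed per-activity rates — 56% for
  posttranslational-modification motifs, 19% for binding motifs, with
  trafficking motifs assigned the binding rate for lack of a measured
  value — are exposed as `DEFAULT_ACTIVITY_GI_RATES` and used explicitly
  for stratification studies; making them the default would silently
  override the flat rate that the discrimination-ratio reproduction
  depends on.
- The homolog map is taxon-complete: every gene gets a cluster, singleton
  when not cross-clustered. Real HomoloGene files list only clustered
  genes; completeness is what lets the superset property of the
  HomoloGene filter be exercised on every motif.
- Background topology is Erdős–Rényi per species. The filters depend only
  on edge existence and path length, not degree distribution, and ER keeps
  the collision arithmetic analytic for the tests. Scale-free topology,
  sequence-level motif realism, and GI sign/strength are explicitly not
  modeled — passing tests on these worlds validates the filtering and
  evaluation machinery, not biological performance on real networks.
- Aliases are decorated gene names (`alt-<GENE>`) recorded in the alias
  table; tests rewrite motif endpoints to aliases to exercise resolution.

Everything is driven by one `numpy` generator seeded from the config, so
identical configs produce byte-identical world directories.

## Problem sizes

The default evaluation world uses 1500 genes over 3 species with 3000
positive motifs and 27,000 negative pairs — the scale at which the
planted-rate arithmetic above applies. Property suites run on graphs of
15–50 nodes (where exhaustive cross-product, BFS and Mann–Whitney oracles
are cheap) and on 100 small random worlds for the nesting chain.

## Known limitations

- The filters treat every GI source as equally reliable; no per-source
  weighting or evidence count.
- Alias tables are flat; no namespace handling (Entrez id vs symbol) —
  callers must supply aliases in the same namespace as the edge lists.
- The GI-evidence score is a ranking device, not a calibrated
  probability.
- `exclude_known` negative sampling enumerates eligible pairs when the
  request is dense relative to the pool, which is memory-heavy beyond
  ~10⁷ possible pairs.
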