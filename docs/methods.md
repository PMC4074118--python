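# Methods

## Model and assumptions

`slcnet` treats an organ's metabolic activity as a node-scored graph
problem.  Nodes are reactions — enzymatic conversions or Slc-mediated
plasma-membrane transports — and an edge joins two nodes whenever they
share a metabolite.  The graph is undirected: the cluster search uses only
connectivity, so reaction direction flags are carried through but never
interpreted.  Transport nodes are always reversible and carry exactly one
transported compound each (an Slc moving k solutes yields k transport
nodes); their mediating Slc genes are handled exactly like enzyme genes.

Two modelling assumptions matter most:

* **Currency exclusion.** Edges through ubiquitous cofactors (H₂O, ATP,
  ADP, NAD⁺/NADH, NADP⁺/NADPH, CO₂, phosphate, CoA, O₂, H⁺ by default)
  would collapse the network into one component, so these compounds are
  excluded from edge construction while remaining listed on nodes.  The
  list is configurable; when input tables already restrict reactions to
  their main substrates/products, the list can be empty.
* **OR gene semantics.** A node's score is the maximum of its genes'
  scores.  Enzyme complexes (AND relationships) are not modelled; for
  presence-style specificity scoring the maximum is the natural reduction
  and is idempotent under gene duplication.

## Scores

Per dataset: linear intensities are floored at a configurable positive
value (default 1.0, i.e. log score 0 — raw microarray summaries are
positive, but synthetic or preprocessed data may contain zeros),
log10-transformed, replicate samples averaged per organ (brain sub-regions
optionally averaged into one brain value), and median-centered per gene
across the configured organ list.  Dataset contributions are summed; a
gene absent from a dataset contributes 0 from it.  Consequences worth
noting: scores are invariant to per-dataset multiplicative rescaling; a
gene flat across organs scores 0 everywhere; scores below the median are
negative.  Multiple probes per gene are collapsed by per-sample maximum
before the log transform (robust to dead probes).  A node none of whose
genes appear in the score table scores 0 ("median-typical") and is flagged.

The median is taken over the configured organ list, not over whatever
extra samples a series may contain.

## Component tree and cluster selection

Thresholds run from 3.0 downward in steps of 0.1 for 27 levels (3.0 …
0.4).  At each level the connected components of the subgraph induced by
nodes scoring ≥ θ are computed; since nodes only enter as θ drops,
components are nested and form a forest.  Construction recomputes
components per level with networkx — at the intended scale (≤ a few
thousand nodes, 27 levels) this is well inside interactive time, and
correctness is pinned to an independent flood-fill oracle in the test
suite rather than to an asymptotically optimal algorithm.  A component
whose node set persists across levels is stored once with its level range.

A *seed* is a component born entirely from fresh nodes (none of its
members belonged to any higher-threshold component); each seed starts a
branch, the chain of containing components down to the lowest level.
Branch optima maximise F(G) = Σe⁄√N with these numerical choices:

* only F > 0 qualifies — a branch whose best score is non-positive
  contributes no cluster;
* ties along a branch break toward the smaller, higher-threshold
  component (the more organ-specific candidate);
* pooled optima are deduplicated; when two branches' optima are nested,
  the one with the **larger F** is kept (ties toward the smaller set).
  This mirrors the in-branch rule — an absorbing component replaces the
  cluster inside it exactly when its F is larger — and prevents a weak
  bottom-level component reached by a low-scoring branch from displacing
  a sharply defined high-F cluster it happens to contain.  The resulting
  set never contains one cluster strictly inside another.

## Permutation significance

The null re-assigns the organ's node-score multiset uniformly over the
nodes, leaving topology fixed.  Two statistics are tested: the F of a
fixed cluster, and the size of the largest selected cluster after
re-running tree + selection per replicate (default 100 replicates; one
master seed spawns independent substreams per replicate).  Both a
one-sample upper-tail t-test of the null values against the observed
statistic and the empirical p = (1 + #{null ≥ observed})/(1 + n_perm) are
reported.  The empirical p is floor-limited at 1/(n_perm+1); the t-test
can reach far smaller values but assumes an approximately normal null.  A
zero-variance null (e.g. the cluster is the whole network, whose total is
permutation-invariant) falls back to the empirical p with a warning.  Exact
ties are counted as ≥ under a 1e-9 relative tolerance so that
summation-order rounding cannot split them.

The tail/variant choice (one-sample, upper tail) is a design decision; the
within-cluster score-reassignment variant is exposed as `scope="cluster"`
and is distributionally equivalent for a fixed node set.

## Transport classification and connectivity

Within each selected cluster, a transport node sharing a metabolite edge
with an enzymatic node of the same cluster is class 1 (enzyme-coupled),
otherwise class 2 (isolated).  The organ × compound matrix M records, for
each organ and transportable compound, the maximum F over that organ's
clusters containing a transport node for the compound (0 when absent;
several Slcs for one compound in one cluster contribute that cluster's F
once).  Class-2 transports do contribute to M: they sit inside selected
clusters and represent real transport capability (e.g. excretion or
absorption), so excluding them would understate epithelial organs.
Connectivity is the Gram product C = M·Mᵀ — symmetric, positive
semidefinite, diagonal = per-organ sum of squared capabilities — and
per-category connectivity restricts M's columns first; over a partition of
compounds the category matrices sum exactly to C.

## Synthetic data

The generator emulates the *shape* of the real inputs, not their biology:
enzymatic nodes draw 2–3 metabolites uniformly from a registry (default
300 compounds for 200 nodes, giving a sparse graph of mean degree ≈ 4),
transport nodes draw one compound each, and planted clusters are chains
connected through dedicated linker metabolites, by default ending in one
transport node so classification and connectivity see coupled transports.
Scores are i.i.d. Normal(0, σ) — mimicking median-centered integrated
scores, which are zero-centered by construction — with planted members
shifted by a constant.  Defaults (185 + 15 nodes, σ = 0.5, one 15-node
cluster at +3.0) are the benchmark conditions used by the test suite and
the acceptance script.  One synthetic gene per node carries the score so
the max-over-genes path is exercised end-to-end; optional secondary genes
with strictly lower scores exercise the max rule.

What passing these benchmarks does **not** show: recovery on real data,
where topology is scale-free-ish and modular rather than uniform, scores
are correlated along pathways rather than i.i.d., and cluster boundaries
are softer.  The synthetic results validate the machinery (tree, search,
tests, matrices), not organism-level conclusions.

## Problem sizes

The shipped benchmarks use 200-node networks with 20 recovery replicates,
100 permutations per test, and 200 signal-free 30-node networks for null
calibration — sizes chosen so a full run stays interactive on a single
core while keeping Monte-Carlo error well below the decision margins
(e.g. the recovery criterion margin of 2/20 seeds).

## Known limitations

* No stoichiometry, compartments (beyond plasma-membrane transport), or
  flux estimation; connectivity is symmetric and direction-free.
* Enzyme complexes are treated as isozyme lists (OR).
* Normalisation stops at log-median-centering: no cross-platform quantile
  normalisation or batch correction.
* The empirical p cannot go below 1/(n_perm+1); headline "p < 1e-16"
  claims require the t-test and its normality assumption.
* Curated reference tables (reactions, transports, integrated organ
  scores) are consumed, never scraped; reproducing published organ-level
  numbers requires obtaining those tables separately (see
  `tests/test_acceptance.py::test_published_organ_scores_reproduce_reference_tables`).
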