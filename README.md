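# slcnet

Detection of tissue-specific **metabolism/transport clusters** from gene
expression, and estimation of **interorgan metabolic connectivity** through
solute-carrier (Slc) mediated transport.

## The problem

In a mammal, metabolism is divided across organs that exchange metabolites
through the blood.  Most polar metabolites cross the plasma membrane via
Slc transporters, and a transporter is physiologically informative mainly
when it is co-expressed with the enzymes that produce or consume its solute
in the same organ (the "membrane transport metabolon" picture).  `slcnet`
finds such locally co-expressed clusters of enzymatic reactions and Slc
transports, organ by organ, and turns them into a quantitative organ–organ
connectivity estimate — without any global flux-balance reconstruction.

It is intended for computational biologists with (a) a curated table of
enzymatic reactions with their main substrates/products and genes, (b) a
table of plasma-membrane Slc transports and their solutes, and (c)
multi-organ expression data (or a precomputed gene × organ score table).

## Method

1. **Reference network.** Reactions and transports are nodes; two nodes are
   joined whenever they share a non-currency metabolite (ubiquitous
   cofactors such as ATP, H₂O, NAD⁺ are excluded from edge construction).
2. **Scores.** Expression values are log10-transformed, replicate-averaged
   per organ, and median-centered per gene across organs; contributions are
   summed over datasets.  A node's score *e* in an organ is the maximum
   score of its genes (isozymes / alternative Slcs act as OR).
3. **Component tree.** Sweeping a threshold θ downward (3.0 → 0.4 in steps
   of 0.1), the connected components of {*i* : *eᵢ* ≥ θ} form a nested
   hierarchy.
4. **Cluster selection.** Each component *G* gets the subnetwork score

   F(G) = ( Σ_{i∈G} eᵢ ) / √N,  N = |G|.

   Walking every branch of the tree top-down, the component with maximal
   F (> 0) is that branch's optimal cluster; the pooled branch optima are
   the organ's tissue-specific clusters.
5. **Significance.** Node scores are randomly re-assigned within the organ
   (default 100 permutations); cluster F scores and largest-cluster sizes
   are compared against this null (t-test and empirical p).
6. **Classification & connectivity.** A clustered transport is *class 1*
   when an enzymatic node sharing its solute lies in the same cluster,
   otherwise *class 2* (isolated transport).  The organ × compound matrix
   M holds the best cluster F for each transported compound per organ;
   C = M·Mᵀ is the organ–organ connectivity (per-category sub-matrices by
   restricting columns).

## Worked example

The built-in generator reproduces the benchmark conditions used in the test
suite: a 200-node network (185 enzymatic + 15 transport nodes), background
scores Normal(0, 0.5), one planted 15-node connected cluster shifted +3.0.

```python
import slcnet as s
from slcnet.cluster_search import component_score

spec = s.SyntheticSpec(seed=7)
net = s.generate_network(spec)
table, scored = s.generate_scores(net, spec)
tree = s.build_component_tree(scored)
clusters = s.select_optimal_clusters(tree, scored)
largest = clusters.largest()
res = s.cluster_score_significance(largest.node_ids, scored, n_perm=100, seed=7)
c1, c2 = s.classify_transports(clusters, net).counts()
```

prints (via the obvious `print` calls):

```
network: 200 nodes, 477 edges
component tree: 34 components over 27 levels
selected clusters: 18
largest cluster: 16 nodes, F = 10.76
planted-cluster Jaccard: 0.94
permutation test: observed F = 10.76, empirical p = 0.0099, t-test p = 1.12e-108
clustered transports: 1 enzyme-coupled (class 1), 3 isolated (class 2)
```

The largest selected cluster recovers the planted 15-node cluster (Jaccard
0.94 — one background node with a high score was absorbed); its empirical
p sits at the floor 1/(100+1) attainable with 100 permutations, while the
t-test p-value quantifies how far the observed F lies above the null mean.
Most other "clusters" are single background nodes that happened to score
above threshold; the class-2 transports are high-scoring transport nodes
with no co-clustered enzyme, the synthetic analogue of epithelial
excretion/reabsorption transport.

The same pipeline runs from the shell on TSV tables:

```sh
slcnet simulate --seed 7 --outdir demo
slcnet connectivity --config demo/config.yaml   # clusters + matrices + GraphML/SIF
```

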