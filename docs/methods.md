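# Methods

This note documents the models and procedures implemented in `golden`, the
defaults they use, and what the synthetic validation does and does not
establish.

## Problem setting

Gene-set collections (pathways, annotated gene lists, gene signatures —
"PAGs") are redundant: many sets share most of their genes and describe
overlapping biology. `golden` groups a collection into a smaller number of
*super gene-sets* by combining two complementary similarity signals:

1. **Connection signal** — which sets share genes, summarised as a weighted
   *m-type* overlap network.
2. **Semantic signal** — what the sets' free-text descriptions say,
   summarised as text-embedding vectors.

The two are blended into one embedding, checked for clusterability, and
clustered with a consensus-selected number of clusters; each resulting
cluster is given a one-sentence summary.

## Overlap network

For sets A and B with |A| = n_a, |B| = n_b and overlap k in a gene universe
of size N, the edge test is the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, n_a, n_b). Overlap significance is an enrichment
question, so no lower tail is used. Edges with p ≤ `p_cutoff` (default
0.05) and overlap ≥ `min_overlap` (default 1) are kept, weighted by
−log10 p ≥ 0. The universe defaults to the union of all member sets and can
be overridden, since the proper background depends on where the collection
came from. No multiple-testing adjustment is applied by default; the cutoff
is config-exposed, as is a post-hoc `min_weight` threshold for users who
want a higher-confidence network. p-values are floored at the smallest
positive double so that weights remain finite.

## Graph embeddings

Node vectors are learned by biased second-order random walks plus skip-gram
with negative sampling. Walk defaults follow common practice for this graph
family: walk length 80, 10 walks per node, context window 10, 5 negative
samples, return parameter p = 1.0, in–out parameter q = 0.25, dimension 64
(library default; 256 for large collections). Transition preferences are
edge weight × the p/q bias; an unweighted toggle exists. Each walk draws
its own RNG stream seeded by (seed, start node, walk index), so the walk
set is reproducible regardless of execution order.

The skip-gram trainer is a small batched numpy implementation: all
(center, context) pairs within the window are shuffled each epoch and
processed in scatter-add mini-batches (batch size scales with the
vocabulary so that per-node update accumulation stays bounded), with
negatives drawn from the unigram^0.75 distribution, a linearly decaying
learning rate from 0.025, and 5 epochs. This is adequate for the network
sizes this package targets (tens to a few thousand nodes); it makes no
attempt at the throughput of a dedicated word2vec implementation.

Rows are L2-normalised. Isolated nodes never appear in walks and receive
zero vectors, so no set is dropped from downstream stages.

## Semantic embeddings

Text encoding is a port with a deterministic offline default: token counts
hashed into 4096 buckets (blake2 hashing, lowercase alphanumeric tokens)
followed by a fixed-seed Gaussian random projection to 512 dimensions.
Cosine similarity under this encoder reflects token overlap only — it is
*not* a language model, and the test-suite fixtures are deliberately
bag-of-words so this is the right instrument for them. Remote embedding
APIs can be plugged in through the same `TextEncoder` protocol; nothing in
the package or tests requires one.

Semantic vectors are PCA-projected to the graph dimension before fusion
(the blend requires equal dimensions) and L2-normalised. The retained
variance is reported, with a logged warning when it falls below 0.95; the
dimension match always wins over the variance goal because the blend
formula requires it.

## Fusion

With mixing weight α ∈ [0, 1]:

* blend mode: `D_f = (1 − α) · D_g + α · D_s` (α = 0 graph only, α = 1
  text only);
* concat mode: `[√(1−α) · D_g , √α · D_s]`, which reproduces the same
  α-weighted inner-product structure when dimensions differ.

α = 0 and α = 1 return the inputs bitwise. α is tuned by grid search
(default grid 0.0–1.0 step 0.1) maximising mean ARI over labelled
validation groups, ties broken toward larger α (in our experience, and in
this method family generally, the semantic channel is the stronger one —
typical optima sit around α ≈ 0.8). Fused vectors are not re-normalised by
default (flag available): a deliberate choice because the blend of two unit
vectors already has norm ≤ 1 and renormalising distorts the α-weighting.

## Clusterability (CDI)

The Connection Disparity Index is the calibrated probability that a network
contains recoverable block structure, from a classifier trained entirely on
synthetic graphs:

* **Sweep**: two-block stochastic block models, intra- and inter-block edge
  probabilities each over {0.1, …, 1.0}, 10 replicate graphs per cell,
  n = 200 nodes, equal blocks (proportions (0.7, 0.3) and (0.9, 0.1)
  available as options). Defaults give 1000 graphs per sweep — enough for
  stable held-out metrics in about 20 s per sweep on one CPU.
* **Labels**: each graph is clustered by spectral clustering with k = 2 and
  labelled clusterable iff ARI against the planted partition ≥ τ = 0.7
  (ARI clipped at 0; below-chance agreement is "no recovery"). The
  labelling uses the *general* spectral mode — k-means on the k
  eigenvectors of the normalised adjacency with largest |eigenvalue| — so
  that disassortative (inter ≫ intra) planted structure also counts as
  recoverable; the classic bottom-Laplacian mode only sees assortative
  communities and would label barely a third of the sweep positive, which
  is inconsistent with the operating point this classifier family is known
  to reach. Retraining at τ ∈ {0.65, 0.75} moves held-out accuracy by
  < 0.1.
* **Features**: mean and standard deviation of the local clustering
  coefficients (triangles/wedges, 0 for degree < 2). Computed by dense
  matrix algebra; identical to the standard per-node definition.
* **Model**: logistic regression, SVM (with calibrated probabilities),
  k-nearest-neighbours and random forest are fitted on a stratified 75%
  split and compared on the held-out 25%; the best by F1 is kept (in our
  sweeps, the random forest, with logistic regression showing its
  characteristic recall-1.0 profile). The model's native
  `predict_proba` output is reported as the CDI; no extra calibration
  layer is applied.

A degree-corrected SBM generator and an extended feature set (density,
degree mean/std/skew, transitivity, assortativity, largest-component
fraction) with gradient boosting and MLP candidates are provided for the
broader *CDI-β* variant; the exact published feature list for that variant
is not public, so ours is a documented superset.

**Known limitation.** The two coefficient features cannot distinguish a
union of complete cliques from one complete graph — both sit at (mean 1,
std 0) — and the dense corner of the sweep trains that point as
unclusterable. Networks that are nearly unions of cliques (e.g. synthetic
collections in which sibling sets share an identical gene core) therefore
score *low* despite being trivially clusterable. Real overlap networks are
rarely complete, but the score should be read as a screen, not a verdict;
the pipeline accordingly warns rather than aborts (a hard-gate flag
exists).

## Consensus selection of k

For each candidate k the clusterer (k-means by default, deterministic seed)
runs on `n_resamples` = 100 random 80% subsamples; consensus entry (i, j)
is the fraction of co-sampled runs in which i and j landed in the same
cluster (pairs never co-sampled are imputed 0 and counted in the log). The
CDF of the off-diagonal consensus values is summarised by its area A(k) and
the relative change Δ(k) between consecutive k, both reported per run.

Selection does **not** use Δ(k) directly: A(k) equals one minus the mean
consensus value, and a *stable* half-split of a true cluster moves the mean
exactly as much as an unstable one, so on clean data the Δ curve never
flattens at the planted k for any partitioning clusterer. Instead we use
the crispness of the consensus distribution — the ambiguity fraction
(share of off-diagonal values strictly between 0.1 and 0.9, the PAC
statistic of Şenbabaoğlu et al. 2014). A candidate is stable when its
ambiguity ≤ `stability_tolerance` (default 0.05); the selected k is the
largest stable candidate, i.e. the finest reproducible structure, falling
back to the smallest candidate when nothing is stable (no structure beyond
the floor). On planted-blob fixtures this selects the true k for 2 and 3
blobs across all tested seeds, where the Δ-plateau rule selects none.

## Ontology benchmarks

Ground truth for super gene-set recovery comes from is-a hierarchies: a
benchmark group is a pair of parent terms plus their direct children,
labelled by parent. Constraints: both parents at the same shortest-path
depth from the root (over reversed is-a edges; minimum over paths for
multi-parent terms), parents not sharing an immediate parent, children
belonging to exactly one of the two parents (shared children are dropped so
labels stay unique). Two size regimes mirror candidate super-set
definitions: parents with ≥ 5 and < 10 direct children, and ≥ 10 and
< 100. "Child" means *direct* is-a child — the regime bounds only make
sense for direct children. Counts of eligible pairs depend entirely on the
ontology release used, so the enumerator is validated against a brute-force
O(n²) check on synthetic hierarchies rather than against any published
count.

Evaluation uses repeated random sampling: per trial (default 300), two
categories are drawn uniformly, up to 20 members sampled without
replacement from each, and the sampled rows are clustered (agglomerative,
k = number of drawn categories) and scored by ARI/NMI; per-trial tables are
retained.

## Summaries

Cluster descriptions are concatenated (space-separated); over a character
budget (default 8000, standing in for encoder input limits) each member is
first condensed to its first sentence, then the longest contributions are
halved, so every member keeps a footprint before anything is truncated.
The summariser port defaults to a deterministic extractive method: the
sentence with the highest mean corpus-token-frequency score (earlier
sentence wins ties). Summary quality metrics: cosine similarity under the
text-encoder port, plus ROUGE-1 F1 (clipped unigram overlap) and ROUGE-L F1
(longest common subsequence), with tokenisation fixed bit-exactly as
lowercase split on non-alphanumerics, since ROUGE values are
tokenisation-sensitive. ROUGE-L ≤ ROUGE-1 always. Scores from generative
LLM summarisers are model- and prompt-dependent and are out of scope here;
such summarisers plug into the same port.

## Synthetic fixtures

The fixture generator emulates the statistical structure of an ontology
benchmark: one root, branch nodes, parents, children. Child gene sets mix a
global pool (cross-parent overlap fraction b), a parent core (bringing
sibling overlap to w ≥ b) and unique genes, so realised overlap fractions
are exact by construction; descriptions are bags of words from
parent-specific and shared vocabularies. Presets: `clusterable`
(w = 0.8, b = 0, disjoint vocabularies), `no-signal` (w = b, one shared
vocabulary), `graph-only`, `text-only`. A structureless generator
(`make_random_collection`) draws every set independently from one universe,
producing an Erdős–Rényi-like overlap network — the canonical unclusterable
input.

What the fixtures do *not* emulate: real description text (the offline
encoder only measures token overlap, so template text is sufficient and
appropriate), heavy-tailed set sizes, partial within-parent connectivity
(sibling sets share an exact core, so within-parent networks are complete —
which is also why the CDI limitation above shows up on these fixtures), and
annotation noise. Passing the fixture suite therefore demonstrates the
machinery is correct and directionally sensitive, not that any particular
ARI level will be reached on real collections.

## Determinism and problem sizes

Every stochastic step (graph draws, walks, skip-gram, subsampling,
classifier seeds) derives from an explicit seed; pipeline reruns with the
same config produce byte-identical outputs (logs carry no timestamps). The
validation suite uses reduced problem sizes chosen for signal rather than
scale: 20-node clique graphs for embedding checks, 60–140-point blob
fixtures for consensus, 120-node SBMs for CDI behaviour, and the full
1000-graph sweep (three seeds) for the classifier operating point, which
reproduces held-out random-forest accuracy ≈ 0.92 and F1 ≈ 0.95 and
logistic F1 ≈ 0.89 with logistic recall pinned at 1.0.
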