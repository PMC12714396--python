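# Methods

## The model

The package predicts microbe–drug associations (MDAs) by embedding a
heterogeneous graph with three node types (microbe `Vs`, metabolite `Vm`,
drug `Vd`) and five undirected edge types — `ss`, `sm`, `mm`, `dm`, `dd` —
and classifying pairs of embeddings. The central modeling assumption is
that metabolites mediate microbe–drug interaction: the graph contains **no
microbe–drug edges**, so every path between a microbe and a drug passes
through the metabolite space (or through same-type similarity edges).
Labeled associations enter only (a) the GIP similarity that gates `ss`/`dd`
edges and (b) the supervision of the final classifier.

### Similarities

* **GIP kernel.** `GM(i,j) = exp(−η ‖I(i) − I(j)‖²)` over binary profiles;
  `η = η′ / (mean_i ‖I(i)‖²)` with `η′ = 1`. Profiles: rows of the
  association matrix I for microbes, columns for drugs; additionally rows
  of the microbe–metabolite (SM) and drug–metabolite (DM) incidence
  matrices, using the identical formula. An all-zero profile matrix has no
  defined bandwidth; the identity matrix is returned with a warning.
* **Functional similarity.** Microbes: genomic `1 − d_mash` (ingested as a
  precomputed distance matrix; distances outside [0,1] are rejected,
  asymmetric matrices symmetrized by averaging) and evolutionary
  `1 − d_p / max d_p` from patristic distances on a Newick tree (missing
  branch lengths count as 0, with a warning). Drugs: Tanimoto coefficient
  over 2048-bit topological path fingerprints computed from SMILES;
  unparsable SMILES exclude the drug from this component only.
* **Aggregation.** Two-level equal-weight mean: the GIP components are
  averaged first, then averaged with the functional family
  (microbes: mean(genomic, evolutionary); drugs: fingerprint). The
  grouping reflects the two-aspect design (profile-based vs
  knowledge-based); the weights inside each aspect are exposed because no
  canonical weighting exists. Entries not covered by every component fall
  back to the mean of the available components.

### Graph assembly

An `ss` (`dd`) edge is created iff the aggregated similarity is **strictly
greater** than the threshold α (default 0.65, the empirically best value in
the 0.50–0.70 range) and carries the similarity as its weight; `sm`, `mm`,
`dm` edges carry weight 1. Ids are strings, case-sensitive and trimmed;
rows of edge tables referencing unknown ids are dropped and reported rather
than auto-registered, so the node registry stays the single source of
truth. Metabolites without edges are retained as isolated nodes; they
simply contribute length-1 walks.

### Random walks

From every node, `walks_per_node = 100` walks of `walk_length = 10` nodes
(9 transitions) are generated.

* At a **metabolite** v with previous node u, the next node n is drawn with
  probability ∝ `w_vn · M[Q(u,v), Q(v,n)]`, where `Q` is the edge-type map
  and `M` the 5×5 symmetric edge-type transition matrix. At a walk start
  (no u) the `M` factor is 1. The normalization factor α_pq and default
  edge weight w are both 1.
* At a **microbe/drug** v, the gate ρ(v) is 1 when v has no metabolite
  edges (T = 0, with T the row sum of SM or DM); otherwise
  `f(S_v^max) = 1/(1 + e^{−k(S_v^max − t)})` with k = 100, t = 0.85, where
  `S_v^max` is the largest similarity among v's *same-type graph neighbors*
  (not all registry members — only nodes already connected by `ss`/`dd`
  edges, whose weights are the similarities). A node with metabolite edges
  but no same-type neighbors gets ρ = 0. Mass ρ is distributed over
  same-type neighbors ∝ similarity; mass 1 − ρ over metabolite neighbors
  ∝ w. The steep sigmoid makes the gate nearly binary: only a node with a
  very similar same-type neighbor (> 0.85) prefers the same-type move.

Walks truncate at dead ends and short walks are kept (the skip-gram
handles short sentences). Randomness: one master seed; each walk draws from
an independent stream keyed by (node index, walk index), so the corpus is
independent of generation order. Step distributions are precomputed per
(node, incoming-edge-type), making each step O(log degree).

### Edge-type transition matrix (EM)

`M` starts uniform (all ones, so the factor cancels). Each iteration
(default 5) generates 10 trial walks of length 10 per node with the full
walker under the current `M`, records per-walk count vectors over the five
edge types, and sets `M_ij = σ(Pearson r(counts_i, counts_j))` with
`σ(x) = 1/(1+e^{−x})`. Numerical conventions: zero-variance counts give
r = 0 (hence 0.5); the diagonal of a type present in the graph is pinned at
r = 1 (a count vector is perfectly self-correlated; the variance-based
formula would be undefined for constant counts); edge types absent from the
graph keep the prior value and are logged. Entries therefore stay in
(0, 1] and `M` symmetric at every iteration.

### Heterogeneous skip-gram

Skip-gram with negative sampling where, for each (center, context) pair,
the 5 negatives are drawn from **the node type of the context** using
per-type unigram^0.75 noise distributions; a negative never equals the
context (resampled, up to a bounded number of tries; a type with a single
node yields no negative). Type-blind sampling would mostly contrast
metabolites against the majority type and learn type separation instead of
node structure. Defaults: d = 1024, window = 9 (the operating point of the
framework; the synthetic benchmark uses d = 64, window = 5 — see below),
5 negatives, 5 epochs, learning rate 0.025 decaying linearly to 1e−4,
min_count = 1. Context windows are fixed-width rather than randomly
shrunk: sentences are at most 10 tokens, so shrinking buys little, and
fixed windows make determinism exact. Training is sequential SGD compiled
with numba, with an explicit xorshift64* RNG so runs are bit-reproducible;
only the input (center) vectors are exported.

### Classifier

Pair feature: Hadamard product `d_uv = z_u ⊙ z_v` (element-wise; symmetric
in u and v). Default model: XGBoost, `K = 564` trees, binary logistic loss,
other tree hyperparameters at library defaults. ACC/F1 use threshold 0.5
(a standard choice; the framework itself does not prescribe one). Ranked
candidate lists sort by descending score with ties broken by node id.
Because features need only an embedding, nodes absent from the labeled
data but present in the graph receive complete rankings.

### Cross-validation

Positives are split into k equal folds (sizes differ by ≤ 1). Per fold, the
GIP-from-I similarity is recomputed from **training positives only**, the
graph reassembled, `M` refit, walks, embeddings and classifier retrained —
no held-out positive influences any training-time quantity. Metabolite
edges and functional similarities are label-free and fold-invariant.
Negatives are sampled uniformly 1:1 from unlabeled pairs (the ratio is a
knob); training negatives are additionally kept disjoint from the fold's
test negatives. AUROC is the rank statistic, AUPR the step integration of
the precision–recall curve (average precision).

## The synthetic benchmark

The generator emulates the real inputs with a planted partition: microbes,
metabolites and drugs get latent groups (assignments redrawn if a group
would be empty); SM and DM edges appear with probability `p_in` within
group and `p_out` across; MM edges are Erdős–Rényi; a microbe–drug pair is
truly associated iff the two share a group, and a fraction (default 50%)
of true pairs is observed as labels. Functional similarity matrices are a
group indicator scaled by the normalized edge contrast
`(p_in − p_out)/p_in`, plus symmetric Gaussian noise (σ = 0.1), clipped to
[0, 1]. Tying the similarity amplitude to the edge contrast makes the two
planted channels rise and fall together, so `p_in = p_out` is a *complete*
null: group membership is then recoverable from nothing — not from the
metabolite edges, not from the similarities, and therefore not from the
labels either. Without this coupling a "null" dataset would still leak
group structure through the similarity matrices and the labeled positives,
and the null AUROC would sit well above 0.5 for reasons unrelated to
metabolite mediation.

Default benchmark size: 30 microbes, 40 metabolites, 30 drugs, 3 groups,
`p_in = 0.5`, `p_out = 0.02`, run with d = 64, window = 5, K = 100 trees —
small enough for a few-minute, single-CPU run while leaving the planted
structure clearly recoverable. When evaluating recovery, the generator's
ground-truth pairs can be excluded from the negative-sampling universe
(`run_cv(..., negative_exclude=truth)`): under the default configuration
about a fifth of uniformly sampled "negatives" would otherwise be true
planted pairs, capping the attainable AUROC near 0.9 and measuring label
noise rather than recovery. The default (no exclusion) matches what is
possible on real data, where the complete truth is unknown.

What the generator does *not* emulate: real chemistry (drug similarity is
injected at the similarity-matrix level, not computed from SMILES), degree
heterogeneity and the extreme sparsity of real association catalogues
(thousands of drugs, hundreds of microbes, ~1 positive per thousand
pairs), correlated noise between similarity aspects, and curation biases
in the labels. Passing the recovery test therefore shows the pipeline's
machinery is sound end to end, not that real-data performance will match.

## Numerical choices and degenerate inputs

* Similarity exactly equal to α creates **no** edge (strict threshold).
* GIP on an all-zero matrix → identity + warning; Tanimoto with an empty
  union → 0 off-diagonal; a tree whose maximum patristic distance is 0 is
  rejected.
* Step distributions are validated to sum to 1 within 1e−9; isolated nodes
  yield empty distributions and truncated walks.
* Embeddings are float32; the word2vec text format round-trips to 1e−6.
* Fold seeds, walk streams and the EM trial-walk streams are all derived
  from the master seed, so two runs with the same seed are bit-identical
  (corpora, embeddings, predictions).

## Known limitations

* The EM objective for `M` is a fixed-point heuristic (correlation +
  sigmoid), not the maximizer of an explicit likelihood; it can drift over
  iterations when edge-type counts are structurally anti-correlated within
  walks (e.g. strict alternation), which is why the iteration count is a
  knob.
* The skip-gram trainer is single-threaded by design (determinism over
  throughput); embedding very large graphs would need a parallel trainer
  with per-thread streams.
* The guilty-by-association negative sampler is declared as a classifier
  ablation hook but intentionally not implemented; negatives are uniform.
* Probabilities from the boosted trees are used unchanged (no
  calibration); ACC/F1 at 0.5 should be read accordingly.
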