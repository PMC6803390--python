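# Methods

## Network model

An interactome is a simple undirected graph over uppercased gene symbols:
the subgraph induced by a bait's interactor list over a table of physical
interactions.  The "direct and physical" filter is an allow-list of
interaction-type tokens; the shipped default accepts MI:0407 (direct
interaction) and MI:0915 (physical association) and excludes MI:0914
(association), which admits co-complex inferences.  The exact MI term set
behind any published network depends on curation choices, so the list is a
user-visible parameter, not a constant.  Self-loops are dropped, duplicate
unordered pairs collapsed (first source retained), and species merging by
symbol is left to the caller so the core stays species-agnostic.

All statistics run on the largest connected component (LCC); ties between
equal-sized components are broken by the lexicographically smallest member
symbol so runs are deterministic.  Distances are unweighted BFS hop counts
— interaction confidence weights are deliberately out of scope.

## Centralities

The centrality table reports degree, betweenness (unnormalized pair
counts), closeness, clustering coefficient, PageRank (damping 0.85,
tolerance 1e-10), mean shortest path, and semi-local centrality

    N(w)  = |{x : 1 <= d(w,x) <= 2}|
    Q(u)  = Σ_{w∈Γ(u)} N(w)
    Cl(v) = Σ_{u∈Γ(v)} Q(u),

unity-normalized to [0,1].  When every node ties (e.g., a star graph),
normalization is undefined; all nodes are assigned 0.5 rather than an
arbitrary extreme, so a fully symmetric graph lands on no influence
quadrant boundary.  PageRank's damping and tolerance are conventional
defaults; nothing downstream is sensitive to them.

## Communities and soft membership

Hard partitions come from python-igraph: walktrap (4-step random walks),
SpinGlass (25 spins), leading-eigenvector spectral splitting, and Infomap
(10 trials).  Stochastic algorithms read the stdlib RNG, which is seeded
per run, so every partition is reproducible from its recorded seed.  A
fifth slot for a mixed-membership stochastic blockmodel exists in the
interface but has no backend in this build; pipelines proceed with the
remaining algorithms and log the reduced set.

Soft membership rows u_v are estimated by bootstrap: each replicate
resamples the edge multiset with replacement (collapsing duplicates),
keeps the replicate's LCC, re-detects communities, aligns labels to the
reference partition by greedy maximum-overlap matching, and increments
per-node community counts; rows are normalized by each node's replicate
appearances.  A `resample=False` mode re-runs the algorithm with fresh
seeds on the fixed graph instead — meaningful for stochastic algorithms,
degenerate (one-hot) for deterministic ones.  Edge resampling retains each
edge with probability ≈ 1 − 1/e ≈ 0.63 per replicate; modularity-based
algorithms can fragment a dense clique thinned that far, which flow-based
Infomap resists.  This is a property of the perturbation, not a defect:
membership uncertainty under resampling is exactly what the bridgeness
score consumes.

The consensus partition joins two nodes when they co-classify in more than
half of the input partitions and takes connected components of that graph.
Community ids are always re-ranked 1..c by decreasing size, ties by
smallest member symbol.

## Bridgeness and influence regions

Ba(v) = 1 − √( c/(c−1) · Σ_j (u_jv − 1/c)² ): 0 for a one-hot row, 1 for
the uniform row.  The square root is part of the definition — it is the
only reading under which the uniform row scores exactly 1 with the
c/(c−1) normalizer; an unrooted compatibility variant is available via
`sqrt=False`.  Br(v) averages Ba over the configured algorithm set
(default: SpinGlass, spectral, Infomap — the soft-membership producers).
Membership matrices that collapse to a single community carry no bridging
signal and are skipped with a log entry.

Regions partition [0,1]² with half-open boundaries so the classification
is total and disjoint: Br ≥ 0.5 splits into R1 (Cl < 0.5, global bridges)
and R2 (Cl ≥ 0.5, mixed); below that, Cl ≥ 0.5 is R4 (locally influential
only), and low-Cl nodes split at Br = 0.1 into R3 (local hubs) versus R4.
Nodes with Br < 0.1 are treated as R4 regardless of Cl: on disassortative
PPI networks the bulk of nodes sit there and have no bridging effect.
Semi-local centrality is computed once on the full LCC, not per bootstrap
replicate.

## Enrichment

p = P(X ≥ k) from the hypergeometric distribution with background size N,
M annotated genes, list size n and k annotated list members, evaluated
through scipy's log-space survival function; k = 0 returns exactly 1.
The Bonferroni family is all (cluster, term) pairs tested in one
invocation — the family choice is logged because alternatives (per-cluster
families) are defensible.  Stars mark Bonferroni-adjusted 0.05/0.01/0.001.
Benjamini-Yekutieli values are reported alongside.

The permutation strength test redraws the term's M annotated genes
uniformly from the background (equivalent to shuffling annotation labels),
n_perm = 1000 times by default, and reports the percentage of permuted
p-values ≤ the observed one, ties inclusive; strengths below 1% are
flagged.  Because label permutation *is* the hypergeometric null, the
strength converges to the exact tail probability × 100, which the tests
exploit as an oracle (n_perm = 2000, 3 Monte-Carlo σ tolerance).  A
`permute within network` restriction would condition on network
membership; the default permutes over the full background.

## Disease-module separation

d_AA is the mean, over a disease's genes, of the hop distance to the
nearest other gene of the same disease; d_AB is the symmetric
nearest-neighbor mean over all |A|+|B| genes, shared genes contributing 0;
S_AB = d_AB − (d_AA + d_BB)/2.  Identical sets give S_AB = −d_AA < 0, and
|S_AB| never exceeds the network diameter (asserted per result).  Pairs
with S_AB < −3 or S_AB > 0.1 are flagged "of interest" (thresholds taken
as given).  The null redraws same-sized gene sets uniformly from the
network nodes, independently per disease, 1000 iterations by default;
z = (S_AB − null mean)/null sd, two-sided normal p, Bonferroni over all
pairs in the call.  Null distributions are cached per size pair.  Genes
off the LCC are dropped with a logged count; diseases left with fewer
than 2 mapped genes are skipped in batch mode.

## Synthetic data

Generators emulate the statistical structure of real interactome inputs,
not their content: planted-partition graphs (default 60 nodes, 3 blocks,
p_in = 0.5, p_out = 0.01 — giving LCCs of ~60 nodes and ~290 edges, sparse
and modular like real bait-interactome LCCs, though smaller for test
economy); bridge nodes wired to 3 uniformly chosen members of each of 2
communities; annotation terms covering 80% of one community versus 1% of a
500-gene background, plus uniform decoys; disease pairs sampled from
distinct communities (separated) or one community with a configured
Jaccard overlap (overlapping); and interactor-list pairs with an exact
planted overlap (defaults 373/351 sharing 39 of a 24,402-gene genome).
All generators are deterministic in their seed and emit their ground
truth.  What they do not emulate: degree heterogeneity and disassortative
mixing of real PPI networks (blocks are homogeneous), annotation-term
overlap structure (terms are independent), and literature-curation biases.
Passing recovery tests therefore demonstrate correctness of the machinery
under clean modular structure, not performance guarantees on real
databases.

## Recovery experiments and problem sizes

The benchmark module scores: community recovery (ARI ≥ 0.9, walktrap and
Infomap, 10 seeds), bridge detection (AUC of Br for planted bridges versus
interior nodes, mean ≥ 0.9 over 10 seeds, bootstrap n_boot = 30), planted
enrichment (rank-1 within the target community in ≥ 95% of 20 seeds,
decoy Bonferroni significance ≤ 5%), and S_AB sign recovery (≥ 9/10 seeds
per mode).  These sizes keep the whole suite around two minutes on one
CPU while leaving each statistic well away from its decision threshold;
observed values sit at or near the ceiling (ARI = 1.0, AUC ≈ 1.0, rank-1
= 100%, decoy = 0%).

## Numerical and design notes

- Network JSON serialization (sorted nodes, sorted edge pairs) and 6-
  significant-digit TSV floats make reruns byte-identical and diffable;
  membership TSVs are renormalized on read to absorb rounding.
- Degenerate inputs: single-node graphs reject centrality normalization;
  c < 2 rejects bridgeness; disconnected graphs are rejected by stages
  that require the LCC, with an instructive message.
- The bootstrap's label alignment is greedy maximum-overlap, ties to the
  smaller reference id; fresh ids are appended for unmatched replicate
  communities, so the membership matrix can be wider than the reference
  partition.
- Limitations: no ortholog mapping beyond symbol matching; no ontology
  DAG-aware enrichment (flat GMT terms only); the community-pair overlap
  background defaults to the union of both node sets and published
  community-overlap p-values depend on that unstated choice; printed
  enrichment values against live annotation databases are
  snapshot-dependent and are not reproduction targets.
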