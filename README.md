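# interactoscope

Network-topology analysis of bait-protein interactomes.

Affinity-purification proteomics yields, for a bait protein studied in some
biological context (a tumor cell line, a synaptosome preparation), a list of
a few hundred co-purifying proteins.  `interactoscope` turns such a list
into quantitative network biology:

1. **Network construction** — the interactor list is induced over a filtered
   table of *direct and physical* protein-protein interactions (an MI-term
   allow-list over TSV or PSI-MI TAB 2.5 input), and all topology statistics
   run on the largest connected component (LCC).
2. **Community detection and consensus** — the LCC is partitioned with
   walktrap, SpinGlass, leading-eigenvector spectral splitting and Infomap
   (via python-igraph), with a co-classification consensus partition across
   algorithms.
3. **Influence classification** — per-node semi-local centrality
   Cl(v) = Σ_{u∈Γ(v)} Q(u), Q(u) = Σ_{w∈Γ(u)} N(w) with N(w) the size of
   w's two-hop neighborhood, unity-normalized to [0,1]; and bridgeness

   &nbsp;&nbsp;&nbsp;&nbsp;Ba(v) = 1 − √( c/(c−1) · Σ_j (u_jv − 1/c)² ),

   where u_v is the node's community-membership probability vector estimated
   by an edge-resampling bootstrap.  The mean Br(v) across algorithms,
   plotted against Cl, splits proteins into four influence regions; nodes
   with Br ≥ 0.5 are *bridging proteins* linking multiple complexes.
4. **Annotation enrichment** — hypergeometric over-representation
   p = P(X ≥ k) for each (community, term) pair over GMT gene sets, with
   Bonferroni / Benjamini-Yekutieli adjustment and a 1000-permutation
   strength-of-significance test (annotation labels shuffled over the
   background).
5. **Disease-module separation** — for two disease gene sets A and B on the
   network, S_AB = d_AB − (d_AA + d_BB)/2 from nearest-neighbor shortest
   paths; |S_AB| is bounded by the network diameter, negative values mean
   topologically overlapping disease modules.  Significance comes from a
   fully randomized null (1000 same-size uniform redraws) via z-scores.
6. **Cross-interactome comparison** — hypergeometric tests of shared genes
   between two interactor lists, and a community-pair overlap p-value
   matrix that identifies corresponding complexes across contexts.

A seeded synthetic-data module generates planted-partition networks with
bridge nodes, community-enriched annotation terms and disease gene sets of
controlled separation, so every stage is testable offline against known
ground truth.

## Worked example

Simulate a 3-block network with planted bridge nodes and a separated
disease pair, then run the full pipeline:

```sh
interactoscope simulate --preset diseases --seed 7 --out sim
interactoscope run --proteins sim/proteins.txt --edges sim/edges.tsv \
    --gda sim/gda.tsv --seed 7 --boot 30 --iters 500 --out run
head -3 run/influence.tsv
head -3 run/separation.tsv
```

```
gene    cl_norm   ba_spinglass  ba_spectral  ba_infomap  br        region
BRG01   0.0795626 0.427805      0.382958     0.45431     0.421691  R3_local_hub
BRG02   0.0784314 0.549486      0.336675     0.427805    0.437989  R3_local_hub

disease_a  disease_b  d_aa  d_bb  d_ab  s_ab  null_mean  null_sd   z        p            of_interest ...
DISEASE_A  DISEASE_B  1     1     3.15  2.15  -0.2097    0.179654  13.1347  2.08281e-39  True
```

The planted bridge nodes (`BRG*`) carry the highest mean bridgeness in the
network — each connects two of the three communities, so its membership
row approaches (½, ½, 0) and Ba approaches 0.5, against ≈ 0 for
community-interior nodes.  The two disease gene sets were planted in
different communities: their separation S_AB = 2.15 sits 13 standard
deviations above the randomized null (z = 13.1), i.e., clearly separated
disease modules.

Comparing two interactor lists of 373 and 351 genes that share 39 against
a 24,402-gene genome:

```
$ interactoscope compare --a cancer.txt --b synaptic.txt --genome-size 24402
|A|=373 |B|=351 overlap=39 N=24402 P=3.01e-22
```

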