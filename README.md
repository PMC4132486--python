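# topodiff

Differential network-topology analysis of gene coexpression networks.

When the same genes are measured under two related conditions — two brain
regions of the same disease, or affected versus control tissue — most of the
coexpression structure is shared, and the interesting biology hides in the
genes whose *wiring* changes. `topodiff` implements a complete pipeline for
finding and characterizing those genes:

1. **Coexpression networks.** For each condition, genes are linked when their
   Pearson correlation r and mutual correlation ranks satisfy either
   `r > 0.3` with one gene in the other's top-3 most-correlated, or `r > 0.7`
   with one gene in the other's top-50. The result is a sparse, unweighted,
   undirected binary adjacency matrix.
2. **Topological overlap (TO).** For gene *i* with direct-neighbor sets
   X<sub>i1</sub>, X<sub>i2</sub> in the two networks and
   d<sub>i</sub> = max(|X<sub>i1</sub>|, |X<sub>i2</sub>|):

   TO<sub>i</sub> = (|X<sub>i1</sub> ∩ X<sub>i2</sub>| + 1) /
   (d<sub>i</sub> · √(|X<sub>i1</sub>|·|X<sub>i2</sub>|)),
   with 1/d<sub>i</sub>² ≤ TO<sub>i</sub> ≤ (d<sub>i</sub>+1)/d<sub>i</sub>².

   Genes are ranked ascending; the lowest 10% ("low-TO genes") are the genes
   whose neighborhoods differ most, with large-but-divergent neighborhoods
   ranked as most extreme. Each gene's neighborhood pair is also classified
   into one of nine size/overlap scenarios.
3. **Rewiring nulls.** The selected set's mean TO is compared against 100
   networks rewired by paired edge deletions/additions that preserve the
   exact edge count, via a one-sample t locating the observed mean in the
   null ensemble.
4. **Eigenvector centrality.** Bonacich centrality (nonnegative leading
   eigenvector of the adjacency, unit Euclidean norm for cross-network
   comparability) is computed by deterministic power iteration, and mean
   centralities of gene groups are compared with Welch's t-test.
5. **PPI subnetworks.** Low-TO genes seed a protein-interaction subnetwork
   that is pruned in three phases on the seed-pair geodesics (shortest
   paths), retaining the fewest nonseed connectors that keep all originally
   connected seed pairs connected; low-TO genes are split by which network
   they are better connected in and expanded into disjoint PPI modules.

A synthetic-data module generates expression matrices with block-correlated
structure, planted divergent genes, planted differential expression and
attenuated "affected" correlations, plus random PPI graphs — all with known
ground truth, so every stage can be validated end to end.

## Worked example

```python
import topodiff as td

cfg = td.SimConfig(n_genes=200, n_blocks=8, block_size=25,
                   n_samples_per_group=12, within_block_corr=0.8,
                   n_divergent=20, seed=7)
m1, m2, truth = td.simulate_region_pair(cfg)
net1, net2 = td.build_network(m1), td.build_network(m2)

records = td.rank_genes(net1, net2)
selected = td.select_low_to(records, fraction=0.10)
print(len(records), len(selected))
print(len(selected & truth.divergent_genes))

null = td.null_significance(net1, net2, selected, n_replicates=100, seed=1)
print(round(null.t, 2), f"{null.p:.2g}")
```

prints

```
200 20
20
-4.71 8.1e-06
```

All 200 genes are ranked, the lowest 10% (20 genes) are selected, and all 20
planted divergent genes are recovered. The rewiring null confirms the
selection is structural: the observed mean TO (0.0031) sits far below the
rewired-ensemble mean (0.0064), t = −4.71, p ≈ 8e−06.

The `examples/` directory holds one short script per capability (simulation,
TO ranking, rewiring nulls, centrality comparison, PPI pruning, full
pipeline). A thin CLI mirrors the stages:

```sh
topodiff simulate --seed 7 --out run/sim
topodiff pipeline --seed 7 --out run/full --n-regions 4
```

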