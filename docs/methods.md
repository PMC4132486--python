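# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions made where the design was genuinely open.

## Coexpression networks

Networks are built over a fixed gene list (in the pipeline: the DE genes
common to the two conditions being compared) from all samples of a
condition. Two genes are linked iff at least one rule fires on their Pearson
correlation r:

- rule 1: r > `r_low` (0.3) and either gene is among the other's `k_low` (3)
  most-correlated genes;
- rule 2: r > `r_high` (0.7) and either gene is among the other's `k_high`
  (50) most-correlated genes.

Decisions, with rationale:

- *Symmetry.* "One gene ranked in the top k of the other" is taken in either
  direction (union). The network is declared undirected; any one-directional
  reading would need an arbitrary orientation.
- *Signed ranking.* "Most correlated" uses the signed r descending; both
  thresholds are strict (>). An `absolute_corr` option exists but is off by
  default, since the thresholds are stated on r itself.
- *Boundary ties.* All genes tied with the k-th ranked gene count as within
  the top k. This makes the adjacency invariant under gene-order
  permutation, which is checked by test.
- *Isolated nodes.* The two rules do not guarantee a connected network. We
  keep the literal rules and emit a warning naming isolated genes rather
  than force-connecting them; genes isolated in either network are excluded
  from TO ranking (their TO is undefined).

## Topological overlap

For gene *i*, TO_i = (|X_i1 ∩ X_i2| + 1) / (d_i · sqrt(|X_i1|·|X_i2|)) with
d_i = max(|X_i1|, |X_i2|). The +1 keeps zero-overlap genes comparable by
neighborhood size. The statistic satisfies 1/d² ≤ TO ≤ (d+1)/d², attaining
the lower bound for disjoint equal-size neighborhoods and the upper bound
for identical ones; both equalities and the envelope are property-tested. An
alternative algebraic reading of the same expression,
(|∩|+1)/d · 1/(|X1|·|X2|), violates those bounds; it is kept behind
`formula="literal"` for comparison but is not the default.

Ranking is ascending by TO; ties break by larger d first (a large divergent
neighborhood is the more informative finding), then gene id, so the order is
total and deterministic. Selection takes the first
round-half-away-from-zero(fraction · N) genes; with fraction 0.10 this gives
204 of 2041, 140 of 1398, 242 of 2424, 125 of 1248, 312 of 3118 and 158 of
1582 — nearest-integer rounding is the only rule consistent with all six of
those counts simultaneously.

Scenario classification (nine classes crossing size {large, small} ×
overlap {zero, small, large}) needs cuts the qualitative scheme does not
provide. Defaults: a neighborhood is "large" when its size exceeds the
median degree of the union graph; the overlap ratio |∩|/min(|X1|,|X2|) is
"small" up to 0.2 and "large" from 0.8, with in-between values assigned to
the nearer class (ties to "small"). All three cuts are arguments.

## Rewiring null

Each move deletes one uniformly random edge and inserts one uniformly random
non-edge, so the total edge count is conserved exactly; `n_moves` defaults
to the edge count (one expected touch per edge). This chain has the uniform
distribution over graphs with that edge count as its stationary law, so the
ensemble is a density-matched random-graph null.

Both networks are rewired independently in each of `n_replicates` (default
100) replicates and the selected set's mean TO recomputed (genes isolated by
a rewiring are dropped from that replicate's mean). Significance is the
one-sample t statistic in its ensemble form,
t = (observed − mean(replicates)) / sd(replicates), two-tailed against
t(n_replicates − 1). The alternative of testing the replicate *means*
against the observed value with a standard error sd/√n is not used: the
observed value fluctuates on the scale of sd, not sd/√n, so that test
rejects essentially always regardless of signal and has no type-I control.
The implemented form is calibrated (≈0–5% rejections at the 5% level on
structureless data in the acceptance suite) while retaining high power
against planted divergence.

## Eigenvector centrality

Centrality is the nonnegative leading eigenvector of the binary adjacency
(Perron-Frobenius guarantees existence), normalized to unit Euclidean norm
so scores are comparable across networks of different sizes. Solver: power
iteration on A + I (the shift breaks the ±λ symmetry of bipartite graphs
that makes unshifted iterates oscillate) from a deterministic uniform start
vector — no RNG anywhere. Convergence is declared on the relative
eigen-residual ‖Av − λv‖ ≤ 1e−10·max(λ, 1) within 10,000 iterations; the
residual, unlike the successive-iterate difference, remains meaningful when
the top eigenvalues are nearly tied. Agreement with a dense symmetric
eigendecomposition is ~1e−10 on random 50-node graphs (tested at 1e−8).

Disconnected graphs are solved per component; all mass goes to the
component with the largest leading eigenvalue, ties resolved
deterministically in favor of the first component in gene-list order, with
a warning either way.

Group comparisons of mean centrality use Welch's unequal-variance t-test,
two-tailed, reporting means, t, Welch–Satterthwaite df, p and direction.

## PPI subnetwork pruning

Seed expansion returns the union of connected components containing a seed
(growing neighbor shells to a fixpoint reaches exactly that). Pruning
computes all geodesics between connected seed pairs once on the full
network and then only filters that path set:

- Phase 1 keeps nonseeds on at least one seed-pair geodesic.
- Phase 2, per pair, keeps only geodesics carrying the maximal seed count M
  for that pair; endpoint seeds are counted, so an all-seed geodesic
  dominates.
- Phase 3 counts n_i = surviving geodesics (over all pairs) through nonseed
  i, scores each geodesic N_p = Σ n_i over its nonseeds, and per pair keeps
  only geodesics attaining that pair's maximum N_p. The per-pair (rather
  than global) maximum mirrors Phase 2's per-pair M; a flag would be easy to
  add but the per-pair form is the one used throughout.

At least one geodesic per pair always survives, so seed-pair connectivity is
preserved by construction and re-verified on the output. The procedure is
*not* exactly idempotent: re-pruning its output can drop further nonseeds,
because removing one pair's geodesics changes another pair's Phase-3
frequencies. Re-pruning only ever shrinks the node set and never breaks
connectivity (property-tested).

Low-TO modules: genes split by which coexpression network gives them higher
degree; equal-degree genes join both sides' cores. Each core plus its direct
PPI neighbors forms a module; proteins occurring in both modules are removed
from both, guaranteeing disjointness. Ids that do not map onto the PPI node
set are dropped with a logged count.

## Synthetic data

The generator draws gene expression from a Gaussian block-factor model:
gene g in block b has x = σ(√ρ·f_b + √(1−ρ)·ε), giving within-block
correlation exactly ρ and ≈0 between blocks. Divergent genes are reassigned
to a different (random) block in the second region, replacing their
correlation neighborhood while preserving its size, so ground-truth low-TO
status is unambiguous. Differential expression is a mean shift of
`de_effect`·σ in the affected group for `n_de` planted genes. The
affected/control generator attenuates the affected group's within-block
correlation to ρ·(1−attenuation), emulating loss of coexpression
connectivity. One integer seed drives all streams through spawned
`SeedSequence` children, so every output is reproducible and sub-streams are
independent.

Default study conditions, chosen once:

- Region-pair/TO experiments: 500 genes in 20 blocks of 25, ρ = 0.8, 50
  divergent genes, 12 samples per group — sample sizes in the range
  typical of laser-capture brain-region cohorts (≈9–16 per group), block
  sizes and correlation strength typical of tight coexpression modules.
- Null-calibration experiments: 120 genes of pure noise, 30 samples per
  group; with no planted structure the resulting networks carry no signal a
  calibrated test should detect.
- Centrality (affected vs control) experiments: one 500-gene module, ρ =
  0.8, attenuation 0.8, 12 samples per group. A single connected module is
  used deliberately: the question is loss of connectivity, which requires a
  connected control network with a well-separated leading eigenvalue. An
  archipelago of equal-size cliques has a near-degenerate top spectrum, the
  eigenvector localizes on one arbitrary clique, and the group comparison
  degenerates — which says something about eigenvector centrality on
  modular graphs, not about the affected/control contrast.

What the generator does not emulate: probe-level microarray artifacts,
normalization effects, batch structure, heavy-tailed expression, overlapping
modules, or scale-free PPI degree distributions (PPI graphs are
Erdős–Rényi). Passing tests therefore demonstrate correctness of the
statistics and procedures under a clean covariance model, not robustness to
real-data pathology.

## Problem sizes and tolerances

Simulation-backed checks use: 100 datasets for null calibration, 20 seeds
for null power, recovery and centrality-drop rates (10 seeds in the
acceptance script's power/recovery section), 100 random graphs for the
centrality oracle, 200 random instances for pruning connectivity, and
8–12-node graphs for exhaustive pruning enumeration — sizes at which every
Monte-Carlo bound used in the tests was derived. Numerical tolerances:
1e−10 relative eigen-residual for centrality, 1e−12 slack on TO bound
comparisons, exact integer equality for edge-count conservation and
selection counts.

## Known limitations

- The two-rule network construction can leave isolated nodes; downstream
  stages warn and exclude rather than repair.
- Geodesic enumeration is exponential in the worst case; pruning is intended
  for seed-expanded subnetworks of modest size, not genome-scale graphs.
- The rewiring null matches density only, not the degree sequence; a
  degree-preserving null would be stricter but is not what this procedure
  specifies.
- Eigenvector centrality on strongly modular graphs concentrates on the
  dominant module; comparisons between such graphs should be interpreted
  with the localization caveat above.
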