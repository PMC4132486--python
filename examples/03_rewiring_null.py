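"""Assess a low-TO gene set against an edge-conserving rewiring null.

Each replicate rewires both networks (random paired edge deletions and
additions, total edge count preserved exactly) and recomputes the selected
set's mean TO; the observed mean is located in that null distribution with a
one-sample t statistic.
"""

import topodiff as td

cfg = td.SimConfig(n_genes=200, n_blocks=8, block_size=25,
                   n_samples_per_group=12, within_block_corr=0.8,
                   n_divergent=20, seed=7)
m1, m2, _ = td.simulate_region_pair(cfg)
net1, net2 = td.build_network(m1), td.build_network(m2)
selected = td.select_low_to(td.rank_genes(net1, net2), 0.10)

result = td.null_significance(net1, net2, selected, n_replicates=100, seed=1)
import numpy as np
print(f"observed mean TO of the selected set: {result.observed_mean:.4f}")
print(f"rewired-null mean: {np.mean(result.replicate_means):.4f} "
      f"(sd {np.std(result.replicate_means, ddof=1):.4f}, "
      f"{result.n_replicates} replicates)")
print(f"t = {result.t:.2f}, two-tailed p = {result.p:.3g}")
# A significantly *lower* observed mean than the rewired ensemble means the
# selected genes' neighborhoods diverge more than random edge placement
# would produce — the low-TO signal is structural, not a density artifact.
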