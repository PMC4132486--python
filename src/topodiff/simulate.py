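"""Synthetic expression and PPI data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: genes organised into equicorrelated coexpression blocks, a planted
subset of "divergent" genes whose block membership (hence correlation
neighborhood) differs between two regions, planted differentially expressed
genes shifted between affected and control groups, and Erdos-Renyi protein
interaction graphs with designated seed nodes.

The sampling model for a gene in block b is

    x = sqrt(rho) * f_b + sqrt(1 - rho) * e

with f_b a shared block factor and e independent noise, which yields a
within-block correlation of exactly rho and ~0 between blocks; both terms are
scaled by ``noise_sd``. Genes outside any block are pure noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_region_pair",
    "simulate_regions",
    "simulate_affected_control",
    "simulate_ppi",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the block-covariance expression simulator.

    ``attenuation`` is the fraction by which within-block correlation is
    reduced in the affected group (0 = no effect, 1 = fully decorrelated);
    ``n_de`` is the number of planted differentially expressed genes, each
    shifted by ``de_effect`` (in units of ``noise_sd``-scaled expression) in
    the affected group.
    """

    n_genes: int = 500
    n_blocks: int = 20
    block_size: int = 25
    n_samples_per_group: int = 12
    within_block_corr: float = 0.8
    n_divergent: int = 50
    noise_sd: float = 1.0
    de_effect: float = 0.0
    n_de: int = 0
    attenuation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError(
                f"n_blocks*block_size = {self.n_blocks * self.block_size} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if not 0.0 < self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in (0, 1)")
        if self.n_divergent > self.n_genes:
            raise ValueError("n_divergent exceeds n_genes")
        if self.n_de > self.n_genes:
            raise ValueError("n_de exceeds n_genes")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if min(self.n_genes, self.n_blocks, self.block_size,
               self.n_samples_per_group) < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    divergent_genes: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    block_assignment_per_region: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "divergent_genes": sorted(self.divergent_genes),
            "de_genes": sorted(self.de_genes),
            "block_assignment_per_region": self.block_assignment_per_region,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            divergent_genes=set(payload["divergent_genes"]),
            de_genes=set(payload["de_genes"]),
            block_assignment_per_region=payload["block_assignment_per_region"],
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _base_blocks(cfg: SimConfig) -> np.ndarray:
    """Block index per gene; -1 marks genes outside any block."""
    blocks = np.full(cfg.n_genes, -1, dtype=int)
    for b in range(cfg.n_blocks):
        blocks[b * cfg.block_size:(b + 1) * cfg.block_size] = b
    return blocks


def _sample_group(rng: np.random.Generator, blocks: np.ndarray, cfg: SimConfig,
                  n_samples: int, rho: float | np.ndarray) -> np.ndarray:
    """Draw a genes x samples matrix under the block-factor model.

    ``rho`` may be scalar or per-gene, allowing attenuated correlations for a
    subset of genes.
    """
    n_genes = blocks.size
    rho_vec = np.broadcast_to(np.asarray(rho, dtype=float), (n_genes,)).copy()
    rho_vec[blocks < 0] = 0.0
    factors = rng.standard_normal((cfg.n_blocks, n_samples))
    noise = rng.standard_normal((n_genes, n_samples))
    shared = np.zeros((n_genes, n_samples))
    in_block = blocks >= 0
    shared[in_block] = factors[blocks[in_block]]
    x = np.sqrt(rho_vec)[:, None] * shared + np.sqrt(1.0 - rho_vec)[:, None] * noise
    return cfg.noise_sd * x


def _sample_frame(cfg: SimConfig, blocks: np.ndarray, rng: np.random.Generator,
                  region: str, de_idx: np.ndarray, rho_affected) -> ExpressionMatrix:
    """Two-group (control/affected) expression matrix for one region."""
    n = cfg.n_samples_per_group
    control = _sample_group(rng, blocks, cfg, n, cfg.within_block_corr)
    affected = _sample_group(rng, blocks, cfg, n, rho_affected)
    if de_idx.size:
        affected[de_idx] += cfg.de_effect * cfg.noise_sd
    data = np.hstack([control, affected])
    sample_ids = [f"{region}_ctl_{i + 1}" for i in range(n)] + \
                 [f"{region}_aff_{i + 1}" for i in range(n)]
    genes = _gene_ids(cfg.n_genes)
    samples = pd.DataFrame(
        {"group": ["control"] * n + ["affected"] * n, "region": region},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=sample_ids), samples)


def simulate_regions(config: SimConfig, n_regions: int = 2,
                     region_names: list[str] | None = None
                     ) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Simulate ``n_regions`` expression matrices over one shared gene list.

    Region 1 carries the base block assignment. Every other region reassigns
    the same ``n_divergent`` planted genes to a different (per-region random)
    block, so a divergent gene's correlation neighborhood is replaced while
    its neighborhood size stays comparable. Non-divergent genes share block
    membership across all regions. Planted DE genes are shifted by
    ``de_effect`` in each region's affected group.
    """
    config.validate()
    if region_names is None:
        region_names = [f"R{i + 1}" for i in range(n_regions)]
    if len(region_names) != n_regions:
        raise ValueError("region_names length must equal n_regions")

    root = np.random.SeedSequence(config.seed)
    plant_rng = np.random.default_rng(root.spawn(1)[0])
    genes = _gene_ids(config.n_genes)
    base = _base_blocks(config)

    eligible = np.flatnonzero(base >= 0)
    if config.n_divergent > eligible.size:
        raise ValueError("n_divergent exceeds the number of block-assigned genes")
    divergent = np.sort(plant_rng.choice(eligible, config.n_divergent, replace=False))
    de_idx = np.sort(plant_rng.choice(config.n_genes, config.n_de, replace=False))

    assignments = {region_names[0]: base}
    for name in region_names[1:]:
        alt = base.copy()
        for i in divergent:
            choices = [b for b in range(config.n_blocks) if b != base[i]]
            alt[i] = plant_rng.choice(choices)
        assignments[name] = alt

    matrices = []
    for name, child in zip(region_names, root.spawn(1 + n_regions)[1:]):
        rng = np.random.default_rng(child)
        matrices.append(_sample_frame(config, assignments[name], rng, name,
                                      de_idx, config.within_block_corr))

    truth = GroundTruth(
        divergent_genes={genes[i] for i in divergent},
        de_genes={genes[i] for i in de_idx},
        block_assignment_per_region={
            name: {genes[i]: int(b) for i, b in enumerate(a)}
            for name, a in assignments.items()
        },
    )
    return matrices, truth


def simulate_region_pair(config: SimConfig
                         ) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two-region special case of :func:`simulate_regions`."""
    (m1, m2), truth = simulate_regions(config, n_regions=2)
    return m1, m2, truth


def simulate_affected_control(config: SimConfig, region: str = "R1") -> ExpressionMatrix:
    """One region, two groups; affected-group correlations attenuated.

    In the affected group the within-block correlation becomes
    ``within_block_corr * (1 - attenuation)``, emulating the loss of network
    connectivity seen in disease, and planted DE genes are shifted by
    ``de_effect``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    plant_child, sample_child = root.spawn(2)
    plant_rng = np.random.default_rng(plant_child)
    rng = np.random.default_rng(sample_child)
    blocks = _base_blocks(config)
    de_idx = np.sort(plant_rng.choice(config.n_genes, config.n_de, replace=False))
    rho_aff = config.within_block_corr * (1.0 - config.attenuation)
    return _sample_frame(config, blocks, rng, region, de_idx, rho_aff)


def simulate_ppi(n_nodes: int, edge_prob: float, n_seeds: int, seed: int
                 ) -> tuple[nx.Graph, set[str]]:
    """Erdos-Renyi PPI graph plus a uniformly chosen seed-node subset."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    if n_seeds > n_nodes:
        raise ValueError(f"n_seeds = {n_seeds} exceeds n_nodes = {n_nodes}")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_nodes)))
    names = [f"p{i + 1:0{width}d}" for i in range(n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(names)
    if edge_prob > 0:
        iu, ju = np.triu_indices(n_nodes, k=1)
        mask = rng.random(iu.size) < edge_prob
        graph.add_edges_from((names[i], names[j]) for i, j in zip(iu[mask], ju[mask]))
    seeds = {names[i] for i in rng.choice(n_nodes, n_seeds, replace=False)}
    return graph, seeds


def write_ppi_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
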