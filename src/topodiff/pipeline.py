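"""End-to-end orchestration: simulate/load -> DE -> networks -> TO -> nulls
-> centrality -> PPI modules, with a reproducible JSON run manifest.

For R regions the pipeline performs all R(R-1)/2 pairwise comparisons and
builds two coexpression networks per comparison (one per region, both over
that pair's common DE genes), selecting the low-TO genes of each pair and,
optionally, assessing them against rewiring nulls, comparing eigenvector
centralities and extracting pruned PPI modules seeded by the low-TO genes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionMatrix
from .simulate import SimConfig, simulate_regions, simulate_ppi, write_ppi_edge_list
from .de import de_table, common_de, write_de_table
from .coexpr import NetworkParams, build_network
from .overlap import rank_genes, select_low_to, null_significance, records_to_frame
from .centrality import eigenvector_centrality, compare_centrality
from .ppi import (read_edge_list, seed_expansion, prune, split_by_connectivity,
                  build_modules, modules_to_rows, write_edge_list, intersect_seeds)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from a YAML file."""

    out_dir: str = "topodiff_run"
    seed: int = 0

    # stages
    run_null: bool = True
    run_centrality: bool = True
    run_ppi: bool = True

    # thresholds
    r_low: float = 0.3
    k_low: int = 3
    r_high: float = 0.7
    k_high: int = 50
    select_fraction: float = 0.10
    n_null: int = 100
    q_threshold: float = 0.005

    # inputs: either expression TSV paths per region, or simulation
    regions: dict[str, dict[str, str]] = field(default_factory=dict)
    ppi_path: str | None = None
    simulate: dict = field(default_factory=dict)
    n_regions: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def network_params(self) -> NetworkParams:
        return NetworkParams(self.r_low, self.k_low, self.r_high, self.k_high)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_regions(config: RunConfig) -> tuple[dict[str, ExpressionMatrix], dict]:
    if config.regions:
        matrices = {
            name: ExpressionMatrix.from_tsv(paths["matrix"], paths["samples"])
            for name, paths in config.regions.items()
        }
        return matrices, {"source": "files"}
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimConfig(**sim_kwargs)
    names = [f"R{i + 1}" for i in range(config.n_regions)]
    mats, truth = simulate_regions(sim, config.n_regions, names)
    return dict(zip(names, mats)), {
        "source": "simulation",
        "sim_config": asdict(sim),
        "ground_truth_divergent": sorted(truth.divergent_genes),
        "ground_truth_de": sorted(truth.de_genes),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.network_params()
    outputs: list[Path] = []

    matrices, provenance = _load_regions(config)
    region_names = sorted(matrices)
    logger.info("pipeline start: %d region(s), seed %d", len(region_names),
                config.seed)

    # per-region DE
    de_sets: dict[str, set[str]] = {}
    for name, expr in matrices.items():
        table = de_table(expr)
        path = out / f"de_{name}.tsv"
        write_de_table(table, path, config.q_threshold)
        outputs.append(path)
        de_sets[name] = set(table.loc[table["q"] <= config.q_threshold, "gene"])
        logger.info("region %s: %d/%d genes DE at q<=%g", name,
                    len(de_sets[name]), len(expr.genes), config.q_threshold)

    # PPI input (shared across pairs)
    ppi_graph = None
    if config.run_ppi:
        if config.ppi_path:
            ppi_graph = read_edge_list(config.ppi_path)
        else:
            all_genes = matrices[region_names[0]].genes
            ppi_graph, _ = simulate_ppi(len(all_genes), 0.01, 1, config.seed + 7)
            ppi_graph = _relabel_ppi(ppi_graph, all_genes)
            path = out / "ppi_simulated.edges.tsv"
            write_ppi_edge_list(ppi_graph, path)
            outputs.append(path)

    pair_summaries = {}
    n_networks = 0
    for r1, r2 in combinations(region_names, 2):
        pair = f"{r1}-{r2}"
        pair_dir = out / f"pair_{pair}"
        pair_dir.mkdir(exist_ok=True)
        shared = common_de(de_sets[r1], de_sets[r2])
        if len(shared) < 3:
            logger.warning("pair %s: only %d common DE genes; skipping", pair,
                           len(shared))
            continue
        nets = {}
        for region in (r1, r2):
            net = build_network(matrices[region], shared, params)
            nets[region] = net
            path = pair_dir / f"network_{region}.edges.tsv"
            net.to_edge_list(path, pair_dir / f"network_{region}.nodes.txt")
            outputs += [path, pair_dir / f"network_{region}.nodes.txt"]
            n_networks += 1
            logger.info("pair %s: network %s has %d genes, %d edges", pair,
                        region, net.n_genes, net.n_edges)

        records = rank_genes(nets[r1], nets[r2])
        selected = select_low_to(records, config.select_fraction) if records else set()
        frame = records_to_frame(records, selected)
        path = pair_dir / "to_records.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        logger.info("pair %s: %d genes ranked, %d selected as low-TO", pair,
                    len(records), len(selected))

        summary = {
            "common_de": len(shared),
            "ranked": len(records),
            "selected": len(selected),
            "edges": {r1: nets[r1].n_edges, r2: nets[r2].n_edges},
        }

        if config.run_null and selected:
            null = null_significance(nets[r1], nets[r2], selected,
                                     n_replicates=config.n_null,
                                     seed=config.seed + 17)
            null.to_json(pair_dir / "null.json")
            outputs.append(pair_dir / "null.json")
            summary["null_p"] = null.p
            logger.info("pair %s: rewiring null p = %.3g", pair, null.p)

        if config.run_centrality and selected:
            cents = {}
            for region in (r1, r2):
                cent = eigenvector_centrality(nets[region])
                cent.to_tsv(pair_dir / f"centrality_{region}.tsv")
                outputs.append(pair_dir / f"centrality_{region}.tsv")
                cents[region] = cent.as_series()
            low = sorted(selected)
            cmp = compare_centrality(cents[r1][low], cents[r2][low])
            payload = {"pair": pair, "genes": len(low), **asdict(cmp)}
            with open(pair_dir / "centrality_comparison.json", "w") as fh:
                json.dump(payload, fh, indent=1)
            outputs.append(pair_dir / "centrality_comparison.json")
            summary["centrality_p"] = cmp.p
            summary["centrality_direction"] = cmp.direction

        if config.run_ppi and selected:
            present = intersect_seeds(ppi_graph, selected)
            if present:
                expanded = seed_expansion(ppi_graph, present)
                pruned = prune(expanded, present)
                write_edge_list(pruned.to_graph(), pair_dir / "ppi_pruned.edges.tsv")
                outputs.append(pair_dir / "ppi_pruned.edges.tsv")
                side1, side2, ties = split_by_connectivity(selected, nets[r1],
                                                           nets[r2])
                try:
                    mod1, mod2 = build_modules(side1, side2, ties,
                                               pruned.to_graph(), (r1, r2))
                    rows = modules_to_rows(mod1, ties) + modules_to_rows(mod2, ties)
                    pd.DataFrame(rows).to_csv(pair_dir / "modules.tsv", sep="\t",
                                              index=False)
                    outputs.append(pair_dir / "modules.tsv")
                    summary["modules"] = {mod1.side: len(mod1.members),
                                          mod2.side: len(mod2.members)}
                except ValueError as exc:
                    logger.warning("pair %s: module construction skipped (%s)",
                                   pair, exc)
                summary["ppi"] = {"seeds_mapped": len(present),
                                  "pruned_nodes": len(pruned.retained_nodes),
                                  "pruned_edges": len(pruned.retained_edges)}

        pair_summaries[pair] = summary

    manifest = {
        "topodiff_version": __version__,
        "seed": config.seed,
        "parameters": {
            "r_low": config.r_low, "k_low": config.k_low,
            "r_high": config.r_high, "k_high": config.k_high,
            "select_fraction": config.select_fraction,
            "n_null": config.n_null, "q_threshold": config.q_threshold,
        },
        "provenance": provenance,
        "n_regions": len(region_names),
        "n_comparisons": len(pair_summaries),
        "n_networks": n_networks,
        "pairs": pair_summaries,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _relabel_ppi(graph, genes):
    """Relabel a simulated PPI's nodes with the expression gene ids."""
    import networkx as nx
    mapping = dict(zip(sorted(graph.nodes()), genes))
    return nx.relabel_nodes(graph, mapping)
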