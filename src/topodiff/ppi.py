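"""Seed-induced protein-interaction subnetworks and geodesic pruning.

Given an undirected PPI graph and a set of seed proteins of interest, the
goal is the smallest informative subnetwork that keeps every originally
connected seed pair connected. Construction expands from the seeds to their
full connected components, then prunes nonseed proteins in three phases, all
operating on the complete set of geodesics (shortest paths) between connected
seed pairs computed once on the full network:

  Phase 1  keep only nonseeds lying on at least one seed-pair geodesic;
  Phase 2  per seed pair, let M be the maximum number of seeds (endpoints
           included) found on any of its geodesics; discard geodesics of that
           pair carrying fewer than M seeds;
  Phase 3  count n_i = number of surviving geodesics (over all pairs) through
           each nonseed i; score each surviving geodesic N_p = sum of n_i
           over its nonseeds; per pair, keep only geodesics attaining that
           pair's maximal N_p. A nonseed survives iff it lies on a retained
           geodesic.

Because at least one geodesic per pair is always retained, seed-pair
connectivity is preserved by construction; it is re-verified on the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .coexpr import CoexprNetwork

logger = logging.getLogger(__name__)

__all__ = ["PrunedPPI", "LowTOModule", "read_edge_list", "write_edge_list",
           "seed_expansion", "all_shortest_paths", "prune",
           "split_by_connectivity", "build_modules"]


@dataclass
class PrunedPPI:
    retained_nodes: set[str]
    retained_edges: set[tuple[str, str]]
    seeds: set[str]
    per_pair_M: dict[tuple[str, str], int] = field(default_factory=dict)
    path_frequencies: dict[tuple[str, ...], int] = field(default_factory=dict)
    node_counts: dict[str, int] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.retained_nodes)
        g.add_edges_from(self.retained_edges)
        return g


@dataclass
class LowTOModule:
    side: str
    core: set[str]
    neighbors: set[str]
    members: set[str]


def read_edge_list(path) -> nx.Graph:
    """Two-column tab/whitespace-delimited undirected edge list.

    Reversed duplicates collapse to one edge; self-loops are dropped with a
    logged count; an optional single header line is tolerated.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {line!r}")
            u, v = parts[0], parts[1]
            if lineno == 1 and {u.lower(), v.lower()} & \
                    {"protein1", "protein2", "source", "target", "node1", "node2"}:
                continue  # header
            if u == v:
                n_self += 1
                continue
            graph.add_edge(u, v)
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    if graph.number_of_nodes() == 0:
        logger.warning("edge list %s is empty", path)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def intersect_seeds(graph: nx.Graph, seeds: set[str]) -> set[str]:
    """Seeds present in the network; absent ones are logged and dropped."""
    present = set(seeds) & set(graph.nodes())
    dropped = len(seeds) - len(present)
    if dropped:
        logger.info("dropped %d seed(s) not present in the network", dropped)
    return present


def seed_expansion(ppi: nx.Graph, seeds: set[str]) -> nx.Graph:
    """Union of the connected components that contain at least one seed.

    Growing neighbor-of-neighbor shells from the seeds until fixpoint reaches
    exactly the seeds' connected components.
    """
    present = intersect_seeds(ppi, seeds)
    if not present:
        raise ValueError("no seed is present in the network")
    keep: set[str] = set()
    for comp in nx.connected_components(ppi):
        if comp & present:
            keep |= comp
    return ppi.subgraph(keep).copy()


def all_shortest_paths(ppi: nx.Graph, u: str, v: str) -> set[tuple[str, ...]]:
    """Every geodesic between u and v; empty set if disconnected."""
    for node in (u, v):
        if node not in ppi:
            raise KeyError(f"unknown node {node!r}")
    if not nx.has_path(ppi, u, v):
        return set()
    return {tuple(p) for p in nx.all_shortest_paths(ppi, u, v)}


def prune(full: nx.Graph, seeds: set[str]) -> PrunedPPI:
    """Three-phase geodesic pruning of a seed-expanded PPI network."""
    seed_set = intersect_seeds(full, seeds)
    if not seed_set:
        raise ValueError("no seed is present in the network")

    # Geodesics are computed once here and only filtered afterwards.
    pair_paths: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for u, v in combinations(sorted(seed_set), 2):
        paths = all_shortest_paths(full, u, v)
        if paths:
            pair_paths[(u, v)] = sorted(paths)
    connected_pairs = set(pair_paths)

    # Phase 2: per pair keep only geodesics carrying the maximal seed count
    per_pair_M: dict[tuple[str, str], int] = {}
    surviving: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for pair, paths in pair_paths.items():
        counts = [sum(1 for node in p if node in seed_set) for p in paths]
        M = max(counts)
        per_pair_M[pair] = M
        surviving[pair] = [p for p, c in zip(paths, counts) if c == M]

    # Phase 3: node frequencies over all surviving geodesics, then per-pair
    # retention of the highest-frequency paths
    node_counts: dict[str, int] = {}
    for paths in surviving.values():
        for p in paths:
            for node in p:
                if node not in seed_set:
                    node_counts[node] = node_counts.get(node, 0) + 1

    path_frequencies: dict[tuple[str, ...], int] = {}
    retained_nonseeds: set[str] = set()
    for pair, paths in surviving.items():
        freqs = [sum(node_counts.get(node, 0) for node in p if node not in seed_set)
                 for p in paths]
        top = max(freqs)
        for p, f in zip(paths, freqs):
            path_frequencies[p] = f
            if f == top:
                retained_nonseeds.update(node for node in p if node not in seed_set)

    retained_nodes = seed_set | retained_nonseeds
    sub = full.subgraph(retained_nodes)
    retained_edges = {tuple(sorted(e)) for e in sub.edges()}

    pruned = PrunedPPI(retained_nodes, retained_edges, seed_set,
                       per_pair_M, path_frequencies, node_counts)
    graph = pruned.to_graph()
    for u, v in connected_pairs:
        if not nx.has_path(graph, u, v):
            raise AssertionError(
                f"pruning disconnected seed pair ({u}, {v}); this is a bug")
    return pruned


def split_by_connectivity(low_to: set[str], net1: CoexprNetwork,
                          net2: CoexprNetwork
                          ) -> tuple[set[str], set[str], set[str]]:
    """Split low-TO genes by which coexpression network they are better
    connected in; equal-degree genes go to ``ties`` and later join both
    modules."""
    shared = set(net1.genes) & set(net2.genes)
    unknown = set(low_to) - shared
    if unknown:
        raise ValueError(f"low-TO genes absent from the networks: "
                         f"{sorted(unknown)[:5]}")
    side1, side2, ties = set(), set(), set()
    for gene in low_to:
        d1, d2 = net1.degree(gene), net2.degree(gene)
        if d1 > d2:
            side1.add(gene)
        elif d2 > d1:
            side2.add(gene)
        else:
            ties.add(gene)
    return side1, side2, ties


def build_modules(side1: set[str], side2: set[str], ties: set[str],
                  ppi: nx.Graph, names: tuple[str, str] = ("side1", "side2")
                  ) -> tuple[LowTOModule, LowTOModule]:
    """Two disjoint low-TO modules: cores (side plus ties) with their direct
    PPI neighbors, proteins shared between the modules removed from both."""
    nodes = set(ppi.nodes())

    def mapped(genes: set[str], label: str) -> set[str]:
        present = set(genes) & nodes
        dropped = len(genes) - len(present)
        if dropped:
            logger.info("%s: dropped %d id(s) not present in the PPI network",
                        label, dropped)
        return present

    core1 = mapped(set(side1) | set(ties), names[0])
    core2 = mapped(set(side2) | set(ties), names[1])
    if not core1 and not core2:
        raise ValueError("both module cores are empty after mapping onto the PPI")

    def direct_neighbors(core: set[str]) -> set[str]:
        out: set[str] = set()
        for gene in core:
            out.update(ppi.neighbors(gene))
        return out - core

    nbr1, nbr2 = direct_neighbors(core1), direct_neighbors(core2)
    members1, members2 = core1 | nbr1, core2 | nbr2
    common = members1 & members2
    members1 -= common
    members2 -= common
    return (
        LowTOModule(names[0], core1, nbr1, members1),
        LowTOModule(names[1], core2, nbr2, members2),
    )


def modules_to_rows(mod: LowTOModule, ties: set[str]) -> list[dict]:
    rows = []
    for node in sorted(mod.members):
        if node in mod.core:
            role = "tie" if node in ties else "core"
        else:
            role = "neighbor"
        rows.append({"id": node, "module": mod.side, "role": role})
    return rows
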