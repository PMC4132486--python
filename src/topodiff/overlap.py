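"""Cross-network topological overlap: scoring, ranking, scenarios, nulls.

For a gene i present in two coexpression networks built over the same gene
list, let X_i1 and X_i2 be its direct-neighbor sets and d = max(|X_i1|,
|X_i2|). Its topological overlap is

    TO_i = (|X_i1 ∩ X_i2| + 1) / ( d * sqrt(|X_i1| * |X_i2|) )

which satisfies 1/d^2 <= TO_i <= (d+1)/d^2, attaining the lower bound for
disjoint equal-size neighborhoods and the upper bound for identical ones. Low
TO flags genes whose wiring differs between the two networks while rewarding
large neighborhoods: a gene with big but disjoint neighbor sets ranks below
(i.e. more extreme than) one with small disjoint sets.

Significance of a selected low-TO gene set is assessed against an ensemble of
edge-rewired networks that preserve the exact edge count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import CoexprNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TORecord", "NullResult", "neighborhood", "topological_overlap",
    "rank_genes", "select_low_to", "classify_scenario", "rewire",
    "null_significance",
]


@dataclass
class TORecord:
    gene: str
    size1: int
    size2: int
    intersection: int
    d: int
    to_value: float
    rank: int | None = None
    scenario: int | None = None


@dataclass
class NullResult:
    n_replicates: int
    replicate_means: list[float]
    observed_mean: float
    t: float
    p: float
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def neighborhood(net: CoexprNetwork, gene: str) -> set[str]:
    """Direct neighbors of ``gene`` in ``net``; excludes the gene itself."""
    return net.neighborhood(gene)


def topological_overlap(x1, x2, formula: str = "bounded") -> float:
    """TO of two neighborhoods (sets or sizes-plus-intersection tuples).

    ``formula="bounded"`` is the default statistic documented above.
    ``formula="literal"`` evaluates (|∩|+1)/d * 1/(|x1|·|x2|) instead, an
    alternative reading of the same expression that does not respect the
    stated bounds; it is kept for comparison only.
    """
    x1, x2 = set(x1), set(x2)
    n1, n2 = len(x1), len(x2)
    inter = len(x1 & x2)
    return to_from_counts(n1, n2, inter, formula)


def to_from_counts(n1: int, n2: int, inter: int, formula: str = "bounded") -> float:
    if n1 < 1 or n2 < 1:
        raise ValueError("TO is undefined for an empty neighborhood")
    if inter > min(n1, n2):
        raise ValueError("intersection larger than a neighborhood")
    d = max(n1, n2)
    if formula == "bounded":
        return (inter + 1) / (d * np.sqrt(n1 * n2))
    if formula == "literal":
        return (inter + 1) / d / (n1 * n2)
    raise ValueError(f"unknown formula {formula!r}")


def to_bounds(n1: int, n2: int) -> tuple[float, float]:
    """The printed envelope 1/d^2 <= TO <= (d+1)/d^2."""
    d = max(n1, n2)
    return 1.0 / d**2, (d + 1.0) / d**2


def classify_scenario(size1: int, size2: int, intersection: int,
                      size_cut: float, overlap_small_cut: float = 0.2,
                      overlap_large_cut: float = 0.8) -> int:
    """Map a neighborhood pair to one of nine overlap scenarios.

    Size classes: a neighborhood is "large" when its size exceeds
    ``size_cut``. Overlap classes are computed on |∩| / min(size1, size2):
    exactly 0 -> "zero"; up to ``overlap_small_cut`` -> "small"; at or above
    ``overlap_large_cut`` -> "large"; ratios strictly between the cuts go to
    the nearer class. Scenarios: both large -> 1/2/6 (zero/small/large
    overlap), mixed sizes -> 3/4/5, both small -> 7/8/9.
    """
    if overlap_small_cut >= overlap_large_cut:
        raise ValueError("overlap_small_cut must be below overlap_large_cut")
    if size1 < 1 or size2 < 1:
        raise ValueError("scenario undefined for empty neighborhoods")

    large1, large2 = size1 > size_cut, size2 > size_cut
    ratio = intersection / min(size1, size2)
    if intersection == 0:
        overlap = "zero"
    elif ratio <= overlap_small_cut:
        overlap = "small"
    elif ratio >= overlap_large_cut:
        overlap = "large"
    else:  # between the cuts: nearer class wins, ties to "small"
        overlap = "small" if (ratio - overlap_small_cut) <= (overlap_large_cut - ratio) \
            else "large"

    table = {
        (True, True): {"zero": 1, "small": 2, "large": 6},
        (True, False): {"zero": 3, "small": 4, "large": 5},
        (False, True): {"zero": 3, "small": 4, "large": 5},
        (False, False): {"zero": 7, "small": 8, "large": 9},
    }
    return table[(large1, large2)][overlap]


def rank_genes(net1: CoexprNetwork, net2: CoexprNetwork,
               formula: str = "bounded",
               overlap_small_cut: float = 0.2,
               overlap_large_cut: float = 0.8,
               size_cut: float | None = None) -> list[TORecord]:
    """Score every shared gene and rank ascending by TO.

    Genes isolated in either network have undefined TO and are excluded with
    a warning. Ties are broken by larger d first (a big divergent
    neighborhood is the more interesting finding), then by gene id. The
    scenario size cut defaults to the median degree of the union graph.
    """
    if set(net1.genes) != set(net2.genes):
        raise ValueError("networks must share the same gene set")

    union_degrees = []
    records = []
    skipped = []
    for gene in net1.genes:
        x1, x2 = net1.neighborhood(gene), net2.neighborhood(gene)
        union_degrees.append(len(x1 | x2))
        if not x1 or not x2:
            skipped.append(gene)
            continue
        n1, n2, inter = len(x1), len(x2), len(x1 & x2)
        records.append(TORecord(gene, n1, n2, inter, max(n1, n2),
                                to_from_counts(n1, n2, inter, formula)))
    if skipped:
        logger.warning("%d gene(s) isolated in at least one network excluded "
                       "from TO ranking: %s%s", len(skipped),
                       ", ".join(skipped[:10]), "..." if len(skipped) > 10 else "")

    if size_cut is None:
        size_cut = float(np.median(union_degrees)) if union_degrees else 0.0
    for rec in records:
        rec.scenario = classify_scenario(rec.size1, rec.size2, rec.intersection,
                                         size_cut, overlap_small_cut,
                                         overlap_large_cut)

    records.sort(key=lambda r: (r.to_value, -r.d, r.gene))
    for i, rec in enumerate(records):
        rec.rank = i + 1
    return records


def select_low_to(records: list[TORecord], fraction: float = 0.10) -> set[str]:
    """The lowest-TO ``fraction`` of ranked genes.

    The count is fraction * N rounded half away from zero, so e.g. 2041 ranked
    genes at 10% give 204 selections and 1398 give 140.
    """
    if not records:
        raise ValueError("no TO records to select from")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(np.floor(fraction * len(records) + 0.5))  # round half away from zero
    ordered = sorted(records, key=lambda r: (r.to_value, -r.d, r.gene))
    return {rec.gene for rec in ordered[:n]}


def records_to_frame(records: list[TORecord],
                     selected: set[str] | None = None) -> pd.DataFrame:
    rows = [{"gene": r.gene, "size1": r.size1, "size2": r.size2,
             "intersection": r.intersection, "to": r.to_value, "rank": r.rank,
             "scenario": r.scenario,
             "selected": (r.gene in selected) if selected is not None else None}
            for r in records]
    frame = pd.DataFrame(rows)
    if selected is None and not frame.empty:
        frame = frame.drop(columns=["selected"])
    return frame


# -- edge-conserving rewiring null -------------------------------------------

class _EdgeSampler:
    """Mutable edge set over node indices supporting O(1) random moves."""

    def __init__(self, adjacency: np.ndarray):
        self.n = adjacency.shape[0]
        iu, ju = np.nonzero(np.triu(adjacency, k=1))
        self.edges = [(int(i), int(j)) for i, j in zip(iu, ju)]
        self.edge_set = set(self.edges)

    def delete_random(self, rng: np.random.Generator) -> None:
        k = int(rng.integers(len(self.edges)))
        e = self.edges[k]
        self.edges[k] = self.edges[-1]
        self.edges.pop()
        self.edge_set.remove(e)

    def add_random_nonedge(self, rng: np.random.Generator) -> None:
        while True:
            i = int(rng.integers(self.n))
            j = int(rng.integers(self.n))
            if i == j:
                continue
            e = (i, j) if i < j else (j, i)
            if e not in self.edge_set:
                self.edges.append(e)
                self.edge_set.add(e)
                return

    def to_adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n, self.n), dtype=np.uint8)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = 1
        return adj


def _rewire_edges(adjacency: np.ndarray, n_moves: int,
                  rng: np.random.Generator) -> _EdgeSampler:
    n = adjacency.shape[0]
    sampler = _EdgeSampler(adjacency)
    n_edges = len(sampler.edges)
    if n_edges == 0 or n_edges == n * (n - 1) // 2:
        raise ValueError("rewiring impossible on an empty or complete graph")
    for _ in range(n_moves):
        sampler.delete_random(rng)
        sampler.add_random_nonedge(rng)
    return sampler


def rewire(net: CoexprNetwork, n_moves: int | None = None,
           seed: int = 0) -> CoexprNetwork:
    """Randomize a network by paired edge deletions/additions.

    Each move deletes one uniformly random edge and adds one uniformly random
    non-edge, so the total edge count is conserved exactly. ``n_moves``
    defaults to the edge count (one expected touch per edge).
    """
    if n_moves is None:
        n_moves = net.n_edges
    rng = np.random.default_rng(seed)
    sampler = _rewire_edges(net.adjacency, n_moves, rng)
    return CoexprNetwork(list(net.genes), sampler.to_adjacency(), net.params)


def _mean_selected_to(neigh1: list[set[int]], neigh2: list[set[int]],
                      selected_idx: list[int], formula: str) -> float | None:
    values = []
    for i in selected_idx:
        x1, x2 = neigh1[i], neigh2[i]
        if x1 and x2:
            values.append(to_from_counts(len(x1), len(x2), len(x1 & x2), formula))
    return float(np.mean(values)) if values else None


def _neighbor_sets(edges) -> dict[int, set[int]]:
    neigh: dict[int, set[int]] = {}
    for i, j in edges:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)
    return neigh


def null_significance(net1: CoexprNetwork, net2: CoexprNetwork,
                      selected: set[str], n_replicates: int = 100,
                      seed: int = 0, n_moves: int | None = None,
                      formula: str = "bounded") -> NullResult:
    """Compare the selected set's mean TO against a rewired-network ensemble.

    Both networks are rewired independently in each replicate and the mean TO
    of ``selected`` recomputed; genes left isolated by a rewiring are dropped
    from that replicate's mean. The observed mean is located within the
    replicate distribution by the one-sample statistic
    t = (observed − mean(replicates)) / sd(replicates), with a two-tailed p
    from Student's t with n_replicates − 1 degrees of freedom.
    """
    if not selected:
        raise ValueError("selected gene set is empty")
    if set(net1.genes) != set(net2.genes):
        raise ValueError("networks must share the same gene set")
    unknown = set(selected) - set(net1.genes)
    if unknown:
        raise ValueError(f"selected genes not in networks: {sorted(unknown)[:5]}")

    index = {g: i for i, g in enumerate(net1.genes)}
    selected_idx = sorted(index[g] for g in selected)
    order2 = [index[g] for g in net2.genes]  # align net2 rows to net1 order

    def neighborhoods(adj: np.ndarray, mapping=None) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(adj.shape[0])]
        iu, ju = np.nonzero(np.triu(adj, k=1))
        for i, j in zip(iu, ju):
            a = mapping[i] if mapping else i
            b = mapping[j] if mapping else j
            out[a].add(b)
            out[b].add(a)
        return out

    obs1 = neighborhoods(net1.adjacency)
    obs2 = neighborhoods(net2.adjacency, order2)
    observed = _mean_selected_to(obs1, obs2, selected_idx, formula)
    if observed is None:
        raise ValueError("all selected genes isolated; observed TO undefined")

    moves1 = net1.n_edges if n_moves is None else n_moves
    moves2 = net2.n_edges if n_moves is None else n_moves
    root = np.random.SeedSequence(seed)
    replicate_means: list[float] = []
    for child in root.spawn(n_replicates):
        rng = np.random.default_rng(child)
        s1 = _rewire_edges(net1.adjacency, moves1, rng)
        s2 = _rewire_edges(net2.adjacency, moves2, rng)
        n1 = _neighbor_sets(s1.edges)
        n2_raw = _neighbor_sets(s2.edges)
        neigh1 = [n1.get(i, set()) for i in range(net1.n_genes)]
        neigh2: list[set[int]] = [set() for _ in range(net1.n_genes)]
        for i, nb in n2_raw.items():
            neigh2[order2[i]] = {order2[j] for j in nb}
        mean = _mean_selected_to(neigh1, neigh2, selected_idx, formula)
        if mean is not None:
            replicate_means.append(mean)

    reps = np.asarray(replicate_means)
    sd = reps.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if observed == reps.mean() else np.inf * np.sign(observed - reps.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float((observed - reps.mean()) / sd)
        p = float(2.0 * stats.t.sf(abs(t), df=len(reps) - 1))
    return NullResult(n_replicates, [float(v) for v in reps], float(observed),
                      t, p, seed)
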