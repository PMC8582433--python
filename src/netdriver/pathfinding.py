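"""Best-first enumeration of high-probability paths between mutated genes.

For every mutated gene present on the network, the search enumerates the
top-scoring simple paths (default at most 25) of bounded length (default
4 edges) that end in another gene mutated in a *different* sample. A
path's score is the product of its edge probabilities times the terminal
weight: the best product of per-mutation relevance scores over pairs of
mutations in distinct samples at the two endpoints. Restricting endpoint
pairs to distinct samples makes recurrence across the cohort, not within
one tumor, the signal being chased.

The search is branch-and-bound: a priority queue is ordered by the
current prefix product times an admissible upper bound on the best
completion (computed by reverse dynamic programming over remaining hop
counts), so high-scoring paths surface first and the queue can be
abandoned as soon as no remaining prefix can beat the score threshold or
the current k-th best retained path.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from netdriver.cohort import CohortTable, gene_relevance_map
from netdriver.network_prior import WeightedNetwork

__all__ = [
    "PathfindingConfig",
    "Path",
    "PathIndex",
    "terminal_weight",
    "completion_bound",
    "enumerate_paths",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class PathfindingConfig:
    max_paths_per_source: int = 25
    min_path_prob: float = 0.2
    max_edges: int = 4

    def __post_init__(self) -> None:
        if self.max_paths_per_source < 1:
            raise ValueError("max_paths_per_source must be >= 1")
        if not (0.0 < self.min_path_prob <= 1.0):
            raise ValueError("min_path_prob must be in (0,1]")
        if self.max_edges < 1:
            raise ValueError("max_edges must be >= 1")


@dataclass(frozen=True)
class Path:
    """A retained simple path with its probability decomposition."""

    source: str
    target: str
    edges: tuple[Edge, ...]
    edge_product: float
    terminal_weight: float
    score: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.edges[0][0],) + tuple(v for (_u, v) in self.edges)


@dataclass
class PathIndex:
    """Per source gene, the retained paths sorted by descending score."""

    paths_by_source: dict[str, list[Path]] = field(default_factory=dict)
    skipped_genes: int = 0  # mutated genes absent from the network

    def __iter__(self):
        return iter(self.paths_by_source.items())

    def __len__(self) -> int:
        return len(self.paths_by_source)


def _top_two(rel: dict[str, float]) -> list[tuple[str, float]]:
    """Two highest (sample, relevance) entries, deterministic tie order."""
    return sorted(rel.items(), key=lambda kv: (-kv[1], kv[0]))[:2]


class _TerminalWeights:
    """O(1) best distinct-sample relevance-pair products between genes.

    The optimum pair always uses each gene's best or second-best sample,
    so only the top two relevances per gene are needed.
    """

    def __init__(self, relevance: dict[str, dict[str, float]]):
        self.top2 = {g: _top_two(r) for g, r in relevance.items() if r}
        self.best = {g: t[0][1] for g, t in self.top2.items()}

    def weight(self, source: str, target: str) -> float:
        a = self.top2.get(source)
        b = self.top2.get(target)
        if not a or not b:
            return 0.0
        if a[0][0] != b[0][0]:
            return a[0][1] * b[0][1]
        w = 0.0
        if len(b) > 1:
            w = a[0][1] * b[1][1]
        if len(a) > 1:
            w = max(w, a[1][1] * b[0][1])
        return w


def _relevance_of(cohort) -> dict[str, dict[str, float]]:
    if isinstance(cohort, CohortTable):
        return gene_relevance_map(cohort)
    return cohort  # precomputed gene -> {sample: relevance}


def terminal_weight(source: str, target: str, cohort) -> float:
    """Best relevance product over mutation pairs in distinct samples.

    ``cohort`` is a :class:`CohortTable` or a precomputed relevance map
    (gene -> {sample: relevance}). Returns 0 when the two genes are only
    mutated in the same samples (such paths are excluded).
    """
    return _TerminalWeights(_relevance_of(cohort)).weight(source, target)


def _completion_bounds(
    adj: dict[str, list[tuple[str, float]]],
    tw: dict[str, float],
    max_edges: int,
) -> dict[str, list[float]]:
    """bounds[node][r]: upper bound on (edge product x terminal weight)
    achievable from ``node`` in at most r further edges, ignoring the
    simple-path constraint (hence admissible)."""
    bounds = {n: [tw.get(n, 0.0)] for n in adj}
    for r in range(1, max_edges + 1):
        for n, nbrs in adj.items():
            b = bounds[n][0]
            for v, w in nbrs:
                cand = w * bounds[v][r - 1]
                if cand > b:
                    b = cand
            bounds[n].append(b)
    return bounds


def completion_bound(
    node: str,
    remaining_edges: int,
    net: WeightedNetwork,
    cohort,
    source: str,
) -> float:
    """Admissible bound on the best completion score from ``node``.

    Upper-bounds the product (continuation edge probabilities) x
    (terminal weight with ``source``) over all continuations of at most
    ``remaining_edges`` edges; at 0 remaining edges this is the terminal
    weight of ``node`` itself.
    """
    if remaining_edges < 0:
        raise ValueError("remaining_edges must be >= 0")
    weights = _TerminalWeights(_relevance_of(cohort))
    tw = {
        g: weights.weight(source, g)
        for g in weights.top2
        if g != source and g in net.nodes
    }
    tw = {g: w for g, w in tw.items() if w > 0.0}
    bounds = _completion_bounds(net.successors(), tw, remaining_edges)
    return bounds.get(node, [0.0])[remaining_edges] if node in bounds else 0.0


def _search_source(
    source: str,
    adj: dict[str, list[tuple[str, float]]],
    tw: dict[str, float],
    bounds: dict[str, list[float]],
    cfg: PathfindingConfig,
    use_bound: bool = True,
) -> list[Path]:
    results: list[tuple[float, tuple[Edge, ...], str, float]] = []
    topk: list[float] = []  # min-heap of the current best scores, size <= cap

    def threshold() -> float:
        if len(topk) >= cfg.max_paths_per_source:
            return max(cfg.min_path_prob, topk[0])
        return cfg.min_path_prob

    root_bound = bounds[source][cfg.max_edges] if use_bound else 1.0
    heap = [(-root_bound, (), source, 1.0, frozenset((source,)))]
    while heap:
        nprio, edges, node, product, visited = heapq.heappop(heap)
        if -nprio < threshold():
            break
        for v, w in adj.get(node, ()):
            if v in visited:
                continue
            prod2 = product * w
            edges2 = edges + ((node, v),)
            t = tw.get(v, 0.0)
            if t > 0.0:
                score = prod2 * t
                if score >= cfg.min_path_prob:
                    results.append((score, edges2, v, prod2))
                    if len(topk) < cfg.max_paths_per_source:
                        heapq.heappush(topk, score)
                    elif score > topk[0]:
                        heapq.heapreplace(topk, score)
            remaining = cfg.max_edges - len(edges2)
            if remaining > 0:
                b = prod2 * (bounds[v][remaining] if use_bound else 1.0)
                if b >= threshold():
                    heapq.heappush(heap, (-b, edges2, v, prod2, visited | {v}))
    results.sort(key=lambda r: (-r[0], r[1]))
    return [
        Path(source=source, target=target, edges=edges,
             edge_product=prod, terminal_weight=score / prod, score=score)
        for score, edges, target, prod in results[: cfg.max_paths_per_source]
    ]


def enumerate_paths(
    net: WeightedNetwork,
    cohort,
    cfg: PathfindingConfig | None = None,
    use_bound: bool = True,
) -> PathIndex:
    """Retain, per mutated source gene, the top-scoring simple paths.

    The retained set per source is exactly the ``max_paths_per_source``
    best simple paths of at most ``max_edges`` edges with score at least
    ``min_path_prob`` that end at a gene with positive terminal weight;
    ties at the cap break lexicographically on the edge sequence.
    ``use_bound=False`` disables pruning (same output, slower) and exists
    for verification.
    """
    cfg = cfg or PathfindingConfig()
    relevance = _relevance_of(cohort)
    weights = _TerminalWeights(relevance)
    adj = {n: sorted(nbrs) for n, nbrs in net.successors().items()}
    mutated = sorted(weights.top2)
    on_net = [g for g in mutated if g in net.nodes]
    index = PathIndex(skipped_genes=len(mutated) - len(on_net))
    for source in on_net:
        tw = {
            g: weights.weight(source, g)
            for g in on_net
            if g != source
        }
        tw = {g: w for g, w in tw.items() if w > 0.0}
        if not tw:
            continue
        bounds = _completion_bounds(adj, tw, cfg.max_edges) if use_bound else {
            n: [1.0] * (cfg.max_edges + 1) for n in adj
        }
        paths = _search_source(source, adj, tw, bounds, cfg, use_bound)
        if paths:
            index.paths_by_source[source] = paths
    return index


def save_paths(index: PathIndex, path) -> None:
    """Optional dump: one TSV row per retained path."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tchain\tedge_product\tterminal_weight\tscore\n")
        for source in sorted(index.paths_by_source):
            for p in index.paths_by_source[source]:
                chain = "->".join(p.nodes)
                fh.write(
                    f"{p.source}\t{p.target}\t{chain}\t{p.edge_product:.6g}"
                    f"\t{p.terminal_weight:.6g}\t{p.score:.6g}\n"
                )
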