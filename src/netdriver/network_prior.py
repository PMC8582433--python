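"""Interaction-network prior: loading, degree modeling, and hub reweighting.

The driver search operates on a directed gene graph whose edge weights are
interpreted as probabilities that the interaction is real and usable by a
path. Because hub genes would otherwise dominate the path search, every
edge leaving node ``i`` is relaxed toward 1 by a sigmoidal factor of the
node's out-degree relative to the 90th percentile of a power law fitted to
the out-degree distribution: low-degree nodes get their edges boosted close
to 1 while hub edges stay near their original weight, which downweights
hubs *relative* to the rest of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "WeightedNetwork",
    "DegreeModel",
    "NetworkParseError",
    "load_network",
    "save_network",
    "fit_degree_model",
    "reweight_edges",
]


class NetworkParseError(ValueError):
    """Raised for malformed edge-list input."""


@dataclass
class WeightedNetwork:
    """Directed gene graph with per-edge probabilities in (0, 1].

    ``edges`` maps ``(source, target)`` to its weight; ``nodes`` includes
    every edge endpoint (isolated nodes may be added explicitly).
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u},{v}) weight {w} outside (0,1]")
            self.nodes.add(u)
            self.nodes.add(v)

    def out_degree(self, node: str) -> int:
        return sum(1 for (u, _v) in self.edges if u == node)

    def out_degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for (u, _v) in self.edges:
            deg[u] += 1
        return deg

    def successors(self) -> dict[str, list[tuple[str, float]]]:
        """Adjacency view: node -> [(neighbor, weight), ...]."""
        adj: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
        for (u, v), w in self.edges.items():
            adj[u].append((v, w))
        return adj

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(edges=dict(self.edges), nodes=set(self.nodes))


@dataclass(frozen=True)
class DegreeModel:
    """Discrete power law fitted to the positive out-degrees.

    exponent
        Power-law exponent alpha (> 1).
    xmin
        Smallest degree included in the fit.
    cdf90
        Smallest degree d with fitted CDF(d) >= 0.90.
    """

    exponent: float
    xmin: int
    cdf90: int

    def __post_init__(self) -> None:
        if self.exponent <= 1:
            raise ValueError("power-law exponent must exceed 1")
        if self.cdf90 < 1:
            raise ValueError("cdf90 must be >= 1")


def load_network(
    path,
    default_weight: float = 1.0,
    undirected: bool = False,
) -> WeightedNetwork:
    """Load a 2- or 3-column tab-separated edge list.

    Rows are ``source<TAB>target[<TAB>weight]``; ``#`` lines are comments.
    Two-column rows receive ``default_weight``. With ``undirected=True``
    every row is expanded to both directions. Duplicate (source, target)
    pairs collapse to the maximum weight; self-loops are dropped (they can
    never appear on a simple path).
    """
    if not (0.0 < default_weight <= 1.0):
        raise ValueError("default_weight must be in (0,1]")
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-separated input
                parts = line.split()
            if len(parts) not in (2, 3):
                raise NetworkParseError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise NetworkParseError(f"line {lineno}: empty gene symbol")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(
                        f"line {lineno}: unparseable weight {parts[2]!r}"
                    ) from exc
                if not (0.0 < w <= 1.0):
                    raise NetworkParseError(
                        f"line {lineno}: weight {w} outside (0,1]"
                    )
            else:
                w = default_weight
            nodes.add(u)
            nodes.add(v)
            if u == v:
                continue
            pairs = [(u, v), (v, u)] if undirected else [(u, v)]
            for pair in pairs:
                if pair not in edges or edges[pair] < w:
                    edges[pair] = w
    return WeightedNetwork(edges=edges, nodes=nodes)


def save_network(net: WeightedNetwork, path) -> None:
    """Write the 3-column TSV dialect with 6-significant-digit weights."""
    with open(path, "w") as fh:
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.edges[(u, v)]:.6g}\n")


def _powerlaw_loglik(alpha: float, logsum: float, n: int, xmin: int) -> float:
    return -n * np.log(zeta(alpha, xmin)) - alpha * logsum


def fit_degree_model(net: WeightedNetwork, xmin: int | None = None) -> DegreeModel:
    """Fit a discrete power law to the out-degree distribution by ML.

    Zero out-degree nodes are excluded (the support starts at ``xmin``,
    which defaults to the smallest positive out-degree observed). The
    likelihood P(d) = d^-alpha / zeta(alpha, xmin) is maximized over
    alpha in (1, 20]; cdf90 is the smallest degree whose fitted CDF
    reaches 0.90.
    """
    degrees = np.array([d for d in net.out_degrees().values() if d > 0])
    if degrees.size == 0:
        raise ValueError("cannot fit degree model: all out-degrees are zero")
    if xmin is None:
        xmin = int(degrees.min())
    degrees = degrees[degrees >= xmin]
    if degrees.size == 0:
        raise ValueError(f"no out-degrees >= xmin={xmin}")
    logsum = float(np.log(degrees).sum())
    n = degrees.size
    if np.all(degrees == xmin):
        # ML exponent diverges: the fitted law collapses to a point mass
        # at xmin, so the 90th percentile is xmin itself.
        return DegreeModel(exponent=20.0, xmin=xmin, cdf90=xmin)
    res = minimize_scalar(
        lambda a: -_powerlaw_loglik(a, logsum, n, xmin),
        bounds=(1.0001, 20.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(res.x)
    # CDF(d) = 1 - zeta(alpha, d+1)/zeta(alpha, xmin); walk up from xmin.
    z0 = zeta(alpha, xmin)
    d = xmin
    while 1.0 - zeta(alpha, d + 1) / z0 < 0.90:
        d += 1
        if d > 10**7:  # alpha ~ 1 pathologies; refuse silently absurd tails
            raise RuntimeError("power-law tail too heavy to locate cdf90")
    return DegreeModel(exponent=alpha, xmin=xmin, cdf90=d)


def hub_factor(out_degree: int, cdf90: int) -> float:
    """Sigmoidal hub factor s(i) = 1 + exp(3 * (out_degree/cdf90 - 1))."""
    return 1.0 + float(np.exp(3.0 * (out_degree / cdf90 - 1.0)))


def reweight_edges(net: WeightedNetwork, model: DegreeModel) -> WeightedNetwork:
    """Relax each edge toward 1 according to its source node's degree.

    For edge (i, j): w_new = 1 - (1 - 1/s(i)) * (1 - w_old) with
    s(i) = 1 + exp(3 * (out_degree(i)/cdf90 - 1)). Weight-1 edges are a
    fixed point; the transform never lowers a weight and, for fixed w_old,
    is strictly decreasing in out_degree(i). Returns a new network; the
    input is not modified. Apply exactly once per pipeline run.
    """
    if model.cdf90 <= 0:
        raise ValueError("cdf90 must be positive")
    deg = net.out_degrees()
    factors = {n: hub_factor(d, model.cdf90) for n, d in deg.items()}
    new_edges = {
        (u, v): 1.0 - (1.0 - 1.0 / factors[u]) * (1.0 - w)
        for (u, v), w in net.edges.items()
    }
    return WeightedNetwork(edges=new_edges, nodes=set(net.nodes))
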