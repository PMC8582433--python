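import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from netdriver.cohort import CohortTable
from netdriver.network_prior import WeightedNetwork

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_network(edge_list) -> WeightedNetwork:
    """Network from [(u, v, w), ...]."""
    return WeightedNetwork(edges={(u, v): w for u, v, w in edge_list})


def make_cohort(rows) -> CohortTable:
    """Cohort from [(sample, gene, vaf, coverage, impact, consequence), ...]."""
    df = pd.DataFrame(
        rows,
        columns=["sample", "gene", "vaf", "coverage", "impact", "consequence"],
    )
    df.insert(2, "variant", [f"v{i}" for i in range(len(df))])
    return CohortTable(records=df)


def brute_force_paths(net, relevance, max_edges, tw_func):
    """All simple paths up to max_edges between mutated genes, scored.

    Independent oracle: plain DFS enumeration, no pruning, no queue.
    Returns {source: [(score, edge_tuple), ...]} unsorted, unfiltered.
    """
    adj = {}
    for (u, v), w in net.edges.items():
        adj.setdefault(u, []).append((v, w))
    mutated = [g for g in sorted(relevance) if relevance[g] and g in net.nodes]
    out = {}
    for source in mutated:
        found = []

        def dfs(node, product, edges, visited):
            if edges:
                tw = tw_func(source, node)
                if tw > 0:
                    found.append((product * tw, tuple(edges)))
            if len(edges) == max_edges:
                return
            for v, w in adj.get(node, ()):
                if v in visited:
                    continue
                edges.append((node, v))
                dfs(v, product * w, edges, visited | {v})
                edges.pop()

        dfs(source, 1.0, [], {source})
        out[source] = found
    return out


def inclusion_exclusion_probability(clauses, weights):
    """P(at least one clause fires) by inclusion-exclusion over clause
    subsets; clause = (edge frozenset, terminal weight).

    Independent of the decision-diagram path: treats each subset's edge
    union as a joint conjunction and the auxiliary terminal variables as
    independent multipliers.
    """
    total = 0.0
    n = len(clauses)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            edge_union = frozenset().union(*(clauses[i][0] for i in subset))
            p = 1.0
            for e in edge_union:
                p *= weights[e]
            for i in subset:
                p *= clauses[i][1]
            total += (-1) ** (r + 1) * p
    return total


def brute_force_pb_pmf(probs):
    """Poisson-binomial pmf via full 2^n outcome enumeration (n <= ~16)."""
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    outcomes = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    joint = np.where(outcomes == 1, probs, 1.0 - probs).prod(axis=1)
    return np.bincount(outcomes.sum(axis=1), weights=joint, minlength=n + 1)


def inclusion_exclusion_bitmask(clause_masks, clause_tws, edge_probs):
    """Inclusion-exclusion P(at least one clause fires) over clause
    subsets, with clauses encoded as edge bitmasks.

    Same alternating-sum oracle as
    :func:`inclusion_exclusion_probability`, organised for larger clause
    counts: subset edge-unions and terminal products are built by
    subset DP, and the edge-product of each distinct union mask is
    cached.
    """
    n = len(clause_masks)
    union = np.zeros(2**n, dtype=np.int64)
    twprod = np.ones(2**n)
    sign = np.zeros(2**n)
    mask_prob: dict[int, float] = {0: 1.0}
    total = 0.0
    for s in range(1, 2**n):
        low = s & -s
        i = low.bit_length() - 1
        prev = s ^ low
        union[s] = union[prev] | clause_masks[i]
        twprod[s] = twprod[prev] * clause_tws[i]
        sign[s] = -sign[prev] if prev else 1.0
        u = int(union[s])
        p = mask_prob.get(u)
        if p is None:
            p = 1.0
            m = u
            while m:
                b = m & -m
                p *= edge_probs[b.bit_length() - 1]
                m ^= b
            mask_prob[u] = p
        total += sign[s] * p * twprod[s]
    return total


@pytest.fixture
def chain_net():
    """A -> B -> C chain with weights 0.8, 0.8."""
    return make_network([("A", "B", 0.8), ("B", "C", 0.8)])


@pytest.fixture
def chain_cohort():
    """A mutated in s1, C in s2, full relevance."""
    return make_cohort(
        [
            ("s1", "A", 1.0, 50, 1.0, "missense"),
            ("s2", "C", 1.0, 50, 1.0, "missense"),
        ]
    )
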