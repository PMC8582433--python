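"""Synthetic networks and cohorts with planted ground truth.

Real discovery cohorts for this kind of analysis are access-restricted,
so the generators here reproduce the statistical structure the methods
rely on: a scale-free interaction prior (preferential attachment, edge
probabilities in [0.5, 1]); a mutation cohort with one recurrently hit
connected module planted on the network, Poisson background mutations
with a hypermutator minority, Beta-distributed impact scores and
realistic VAFs; and two-group cohorts whose per-gene mutation
probability depends logistically on tumor mutational burden, with an
optional group effect and an optional TMB shift to create confounding.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from netdriver.cohort import CohortTable
from netdriver.network_prior import WeightedNetwork
from netdriver.oncompare import GroupedCohort

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_cohort",
    "generate_grouped_cohort",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted_genes: set[str]
    planted_edges: set[tuple[str, str]]
    per_sample_hits: dict[str, list[str]]
    params: dict = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_nodes: int, attachment: int = 2, seed: int = 0
) -> WeightedNetwork:
    """Scale-free gene network via preferential attachment.

    Each undirected attachment edge becomes two directed edges sharing a
    weight drawn uniformly from [0.5, 1].
    """
    if n_nodes < attachment + 1:
        raise ValueError("n_nodes must exceed the attachment parameter")
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(seed))
    rng = np.random.default_rng(int(seed))
    edges: dict[tuple[str, str], float] = {}
    for u, v in sorted(map(tuple, map(sorted, g.edges()))):
        w = float(rng.uniform(0.5, 1.0))
        a, b = _gene_name(u), _gene_name(v)
        edges[(a, b)] = w
        edges[(b, a)] = w
    return WeightedNetwork(edges=edges)


def _plant_module(net: WeightedNetwork, module_size: int, rng) -> set[str]:
    """Random-BFS connected subgraph of ``module_size`` genes."""
    und: dict[str, set[str]] = {n: set() for n in net.nodes}
    for (u, v) in net.edges:
        und[u].add(v)
        und[v].add(u)
    comps = []
    seen: set[str] = set()
    for n in sorted(und):
        if n in seen:
            continue
        comp = {n}
        frontier = [n]
        while frontier:
            x = frontier.pop()
            for y in und[x]:
                if y not in comp:
                    comp.add(y)
                    frontier.append(y)
        seen |= comp
        comps.append(comp)
    big = max(comps, key=len)
    if module_size > len(big):
        raise ValueError(
            f"module_size {module_size} exceeds the largest connected "
            f"component ({len(big)} genes)"
        )
    start = sorted(big)[int(rng.integers(len(big)))]
    module = {start}
    frontier = [start]
    while len(module) < module_size:
        candidates = sorted(
            {y for x in frontier for y in und[x]} - module
        )
        nxt = candidates[int(rng.integers(len(candidates)))]
        module.add(nxt)
        frontier.append(nxt)
    return module


def generate_cohort(
    net: WeightedNetwork,
    n_samples: int = 120,
    module_size: int = 6,
    hit_rate: float = 0.7,
    background_rate: float = 8.0,
    hypermut_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[CohortTable, SyntheticTruth]:
    """Cohort with one planted recurrently mutated module.

    Each sample hits one random planted gene with probability
    ``hit_rate`` (impact ~ Beta(5,1): damaging; VAF ~ U(0.2, 0.9);
    coverage >= 30; missense) and receives Poisson(``background_rate``)
    background mutations on random non-planted genes (impact ~ Beta(1,3):
    mostly benign; a mixture of consequence classes so the variant
    filters have work to do). A ``hypermut_fraction`` of samples gets a
    20-fold background rate, emulating hypermutator tumors.
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    rng = np.random.default_rng(int(seed))
    planted = _plant_module(net, module_size, rng)
    planted_sorted = sorted(planted)
    others = sorted(net.nodes - planted)
    planted_edges = {
        (u, v) for (u, v) in net.edges if u in planted and v in planted
    }
    n_hyper = int(round(hypermut_fraction * n_samples))
    hyper_idx = set(rng.choice(n_samples, size=n_hyper, replace=False).tolist()) \
        if n_hyper else set()

    consequences = np.array(
        ["missense", "nonsense", "frameshift", "silent", "intron"]
    )
    cons_p = np.array([0.55, 0.10, 0.10, 0.15, 0.10])

    rows = []
    hits: dict[str, list[str]] = {}
    variant_counter = 0
    for i in range(n_samples):
        sample = f"S{i:04d}"
        hits[sample] = []
        if rng.random() < hit_rate:
            gene = planted_sorted[int(rng.integers(len(planted_sorted)))]
            hits[sample].append(gene)
            variant_counter += 1
            rows.append((
                sample, gene, f"chr1:{variant_counter}:A:T",
                float(rng.uniform(0.2, 0.9)),
                int(rng.integers(30, 200)),
                float(rng.beta(5, 1)),
                "missense",
            ))
        rate = background_rate * (20.0 if i in hyper_idx else 1.0)
        n_bg = int(rng.poisson(rate))
        if n_bg and others:
            genes = rng.choice(len(others), size=n_bg)
            cons = rng.choice(consequences, size=n_bg, p=cons_p)
            vafs = rng.uniform(0.05, 0.9, size=n_bg)
            covs = rng.integers(3, 200, size=n_bg)
            imps = rng.beta(1, 3, size=n_bg)
            for g, c, vaf, cov, imp in zip(genes, cons, vafs, covs, imps):
                variant_counter += 1
                rows.append((
                    sample, others[int(g)], f"chr1:{variant_counter}:A:T",
                    float(vaf), int(cov), float(imp), str(c),
                ))
    records = pd.DataFrame(
        rows,
        columns=["sample", "gene", "variant", "vaf", "coverage", "impact",
                 "consequence"],
    )
    truth = SyntheticTruth(
        planted_genes=planted,
        planted_edges=planted_edges,
        per_sample_hits=hits,
        params=dict(
            n_samples=n_samples, module_size=module_size, hit_rate=hit_rate,
            background_rate=background_rate,
            hypermut_fraction=hypermut_fraction, seed=int(seed),
        ),
    )
    return CohortTable(records=records), truth


def generate_grouped_cohort(
    n1: int,
    n2: int,
    n_genes: int = 1,
    beta_tmb: float = 0.002,
    beta_group: float = 0.0,
    tmb_shift: float = 1.0,
    seed: int = 0,
    alpha: float = -3.0,
    tmb_meanlog: float = math.log(300.0),
    tmb_sdlog: float = 0.6,
) -> tuple[GroupedCohort, dict]:
    """Two-group cohort with TMB-driven mutation probabilities.

    TMB is lognormal (median ~300 mutations, a typical whole-genome
    burden scale for this logistic slope); group 2's TMB is multiplied
    by ``tmb_shift`` to create confounding. Per gene,
    P(mutated) = logistic(alpha + beta_tmb * TMB + beta_group * [group 2]).
    ``beta_group`` may be a scalar or a length-``n_genes`` sequence; the
    returned truth maps each gene to its group effect.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(int(seed))
    n = n1 + n2
    samples = [f"S{i:04d}" for i in range(n)]
    group1, group2 = samples[:n1], samples[n1:]
    tmb = rng.lognormal(tmb_meanlog, tmb_sdlog, size=n)
    tmb[n1:] *= tmb_shift
    is_g2 = np.zeros(n)
    is_g2[n1:] = 1.0
    betas = np.broadcast_to(
        np.asarray(beta_group, dtype=float), (n_genes,)
    )
    genes = [f"GENE{j:03d}" for j in range(n_genes)]
    logit = alpha + beta_tmb * tmb
    ind = np.empty((n_genes, n), dtype=int)
    for j, bg in enumerate(betas):
        p = 1.0 / (1.0 + np.exp(-(logit + bg * is_g2)))
        ind[j] = rng.random(n) < p
    cohort = GroupedCohort(
        group1=group1,
        group2=group2,
        indicators=pd.DataFrame(ind, index=genes, columns=samples),
        confounders=pd.DataFrame({"tmb": tmb}, index=samples),
    )
    truth = dict(
        beta_group={g: float(b) for g, b in zip(genes, betas)},
        beta_tmb=beta_tmb, alpha=alpha, tmb_shift=tmb_shift, seed=int(seed),
    )
    return cohort, truth
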