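"""Penalized subnetwork selection over probabilistic path formulas.

Each mutated source gene contributes a disjunctive formula: one clause
per retained path, a clause being the conjunction of its edges (each an
independent Bernoulli with the edge's probability) and an auxiliary
Bernoulli carrying the path's terminal weight. The probability that at
least one path of a gene exists inside a candidate subnetwork S is
computed *exactly* by weighted model counting: recursive Shannon
expansion on shared edges with connected-component decomposition and
memoization. The subnetwork score is

    sum_g P(at least one path of g exists | S)  -  penalty * |S|

maximized by greedy local search over single-edge removals/re-additions
from several start points. A per-formula cache keyed by the subset of
the formula's relevant edges present in S lets probabilities be reused
across the many subnetworks visited during the search and across the
penalty scan.

The scan runs the optimizer several times per penalty; a penalty is kept
only when the best run scores positive, the mean pairwise Jaccard index
of the run subnetworks is at least 0.5 (stability), and the best
subnetwork has at most 80 edges (parsimony). The union of the accepted
best subnetworks is the final network; each mutated gene is ranked by
the highest accepted penalty at which it appears, since surviving a
harsher penalty demands stronger recurrent connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from netdriver.network_prior import WeightedNetwork
from netdriver.pathfinding import PathIndex

__all__ = [
    "PathFormula",
    "Subnetwork",
    "PenaltyResult",
    "PenaltyScanResult",
    "FormulaEvaluator",
    "build_formulas",
    "satisfaction_probability",
    "score_subnetwork",
    "optimize_subnetwork",
    "jaccard",
    "scan_penalties",
    "label_components",
    "default_penalty_grid",
]

Edge = tuple[str, str]

MAX_INTERACTIONS = 80
MIN_JACCARD = 0.5


@dataclass(frozen=True)
class PathFormula:
    """Disjunction of path clauses for one source gene."""

    source: str
    clauses: tuple[tuple[frozenset[Edge], float], ...]
    relevant_edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for edges, tw in self.clauses:
            if not edges:
                raise ValueError("empty clause edge set")
            if not (0.0 < tw <= 1.0):
                raise ValueError(f"terminal weight {tw} outside (0,1]")


@dataclass
class Subnetwork:
    """An edge-induced subnetwork with its penalized score."""

    edges: dict[Edge, float]
    score: float
    mutated_nodes: set[str] = field(default_factory=set)
    connector_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return {u for (u, _v) in self.edges} | {v for (_u, v) in self.edges}

    @property
    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges)


def build_formulas(index: PathIndex) -> list[PathFormula]:
    """One formula per source gene with at least one retained path.

    Paths with identical edge sets collapse to a single clause keeping
    the larger terminal weight. Formulas are returned sorted by source.
    """
    formulas = []
    for source in sorted(index.paths_by_source):
        paths = index.paths_by_source[source]
        if not paths:
            continue
        by_edges: dict[frozenset[Edge], float] = {}
        for p in paths:
            key = frozenset(p.edges)
            if p.terminal_weight > by_edges.get(key, 0.0):
                by_edges[key] = p.terminal_weight
        clauses = tuple(
            sorted(by_edges.items(), key=lambda kv: (sorted(kv[0]), kv[1]))
        )
        relevant = frozenset().union(*by_edges)
        formulas.append(PathFormula(source, clauses, relevant))
    return formulas


# ---------------------------------------------------------------------------
# Exact weighted model counting


def _none_fires(clauses, probs, memo):
    """P(no clause fires); clauses = tuple of (edge bitmask, tw).

    Edge variables are bit positions with success probabilities
    ``probs`` in (0, 1). Connected-component decomposition plus Shannon
    expansion on the bit shared by the most clauses; memoized on the
    canonical clause multiset.
    """
    if not clauses:
        return 1.0
    key = clauses if len(clauses) == 1 else tuple(sorted(clauses))
    hit = memo.get(key)
    if hit is not None:
        return hit

    # Connected components of the clause-overlap graph.
    if len(clauses) > 1:
        groups: list[tuple[int, list]] = []  # (combined mask, clauses)
        for c in clauses:
            mask = c[0]
            merged = [c]
            rest = []
            for gm, gc in groups:
                if gm & mask:
                    mask |= gm
                    merged.extend(gc)
                else:
                    rest.append((gm, gc))
            rest.append((mask, merged))
            groups = rest
        if len(groups) > 1:
            val = 1.0
            for _gm, gc in groups:
                val *= _none_fires(tuple(gc), probs, memo)
            memo[key] = val
            return val

    # Single component: branch on the most shared edge bit.
    counts: dict[int, int] = {}
    for mask, _tw in clauses:
        m = mask
        while m:
            low = m & -m
            counts[low] = counts.get(low, 0) + 1
            m ^= low
    branch = max(counts, key=lambda b: (counts[b], b))
    p = probs[branch.bit_length() - 1]

    # branch present: clear the bit; fully satisfied clauses fire
    # independently with their terminal weight.
    present_clauses = []
    present_factor = 1.0
    for mask, tw in clauses:
        if mask & branch:
            rest = mask ^ branch
            if rest:
                present_clauses.append((rest, tw))
            else:
                present_factor *= 1.0 - tw
        else:
            present_clauses.append((mask, tw))
    val = p * present_factor * _none_fires(tuple(present_clauses), probs, memo)
    if p < 1.0:
        absent = tuple(c for c in clauses if not c[0] & branch)
        val += (1.0 - p) * _none_fires(absent, probs, memo)
    memo[key] = val
    return val


class FormulaEvaluator:
    """Exact P(formula fires | present edges), with a result cache.

    The formula's relevant edges are numbered into a bit-vector; the
    cache key is the bitmask of relevant edges present in the queried
    subnetwork, so distinct subnetworks sharing that intersection reuse
    the computed probability.
    """

    def __init__(self, formula: PathFormula, weights: dict[Edge, float],
                 use_cache: bool = True):
        self.formula = formula
        self.use_cache = use_cache
        self.edges = sorted(formula.relevant_edges)
        self.bit_of: dict[Edge, int] = {}
        probs = []
        for i, e in enumerate(self.edges):
            w = weights.get(e)
            if w is None:
                raise KeyError(f"no weight defined for edge {e}")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight of edge {e} outside (0,1]")
            self.bit_of[e] = 1 << i
            probs.append(w)
        self._probs = probs
        # per clause: full mask, mask over uncertain (p < 1) edges, tw
        self._clauses = []
        for edges, tw in formula.clauses:
            full = 0
            uncertain = 0
            for e in edges:
                b = self.bit_of[e]
                full |= b
                if weights[e] < 1.0:
                    uncertain |= b
            self._clauses.append((full, uncertain, tw))
        self._cache: dict[int, float] = {}
        self._memo: dict = {}

    def key_for(self, present_edges) -> int:
        key = 0
        if len(present_edges) < len(self.edges):
            for e in present_edges:
                b = self.bit_of.get(e)
                if b:
                    key |= b
        else:
            for e, b in self.bit_of.items():
                if e in present_edges:
                    key |= b
        return key

    def probability_for_key(self, key: int) -> float:
        if self.use_cache:
            hit = self._cache.get(key)
            if hit is not None:
                return hit
        fixed = 1.0
        live = []
        for full, uncertain, tw in self._clauses:
            if full & key == full:  # all clause edges present
                if uncertain:
                    live.append((uncertain, tw))
                else:
                    fixed *= 1.0 - tw
        prob = 1.0 - fixed * _none_fires(
            tuple(live), self._probs, self._memo if self.use_cache else {}
        )
        if prob < 0.0:
            prob = 0.0
        if self.use_cache:
            self._cache[key] = prob
        return prob

    def probability(self, present_edges) -> float:
        return self.probability_for_key(self.key_for(present_edges))


def satisfaction_probability(
    formula: PathFormula,
    present_edges,
    weights: dict[Edge, float],
    use_cache: bool = True,
) -> float:
    """Exact probability that at least one clause of ``formula`` fires.

    Each edge e is an independent Bernoulli with probability weights[e]
    when e is present in the subnetwork and 0 otherwise; each clause
    carries an extra independent Bernoulli with its terminal weight.
    """
    return FormulaEvaluator(formula, weights, use_cache).probability(present_edges)


def score_subnetwork(
    present_edges,
    formulas: list[PathFormula],
    penalty: float,
    weights: dict[Edge, float],
    evaluators: list[FormulaEvaluator] | None = None,
) -> float:
    """Sum of per-gene path-existence probabilities minus penalty * |S|."""
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    present = frozenset(present_edges)
    if evaluators is None:
        evaluators = [FormulaEvaluator(f, weights) for f in formulas]
    total = sum(ev.probability(present) for ev in evaluators)
    return total - penalty * len(present)


def jaccard(a, b) -> float:
    """|a & b| / |a | b|; defined as 1 for two empty sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Local search


class _LocalSearch:
    """Greedy steepest-ascent over single-edge toggles.

    Maintains, for every candidate edge e, the probability gain of
    toggling it, gain[e] = sum over formulas containing e of
    P(key ^ bit_e) - P(key). Applying a move only changes the keys of
    the formulas containing the moved edge, so only their contributions
    to co-occurring edges' gains are updated.
    """

    def __init__(self, evaluators, candidates, penalty, rng):
        self.ev = evaluators
        self.candidates = candidates  # sorted tuple of edges
        self.penalty = penalty
        self.rng = rng
        self.formulas_of: dict[Edge, list[int]] = {e: [] for e in candidates}
        for fi, ev in enumerate(evaluators):
            for e in ev.edges:
                if e in self.formulas_of:
                    self.formulas_of[e].append(fi)

    def run(self, start: set[Edge], max_iter: int = 100000):
        S = set(start)
        keys = [ev.key_for(S) for ev in self.ev]
        probs = [ev.probability_for_key(k) for ev, k in zip(self.ev, keys)]
        gain = {e: 0.0 for e in self.candidates}
        for fi, ev in enumerate(self.ev):
            k, p = keys[fi], probs[fi]
            for e, bit in ev.bit_of.items():
                if e in gain:
                    gain[e] += ev.probability_for_key(k ^ bit) - p

        def apply_toggle(e: Edge) -> None:
            for fi in self.formulas_of[e]:
                ev = self.ev[fi]
                old_k, old_p = keys[fi], probs[fi]
                new_k = old_k ^ ev.bit_of[e]
                new_p = ev.probability_for_key(new_k)
                for e2, bit in ev.bit_of.items():
                    if e2 in gain:
                        gain[e2] += (
                            ev.probability_for_key(new_k ^ bit) - new_p
                            - ev.probability_for_key(old_k ^ bit) + old_p
                        )
                keys[fi], probs[fi] = new_k, new_p
            if e in S:
                S.discard(e)
            else:
                S.add(e)

        for _ in range(max_iter):
            best_d = 1e-12
            best_edges: list[Edge] = []
            for e in self.candidates:
                d = gain[e] + (self.penalty if e in S else -self.penalty)
                if d > best_d + 1e-12:
                    best_d, best_edges = d, [e]
                elif best_edges and abs(d - best_d) <= 1e-12:
                    best_edges.append(e)
            if best_edges:
                e = (best_edges[0] if len(best_edges) == 1
                     else self.rng.choice(best_edges))
                apply_toggle(e)
                continue
            # No single-edge move improves. Multi-edge clauses create
            # coupled local optima (one edge alone never pays its
            # penalty), so try completing a whole missing clause.
            move = self._best_clause_completion(keys, probs)
            if move is None:
                break
            for e in move:
                apply_toggle(e)
        return S, sum(probs) - self.penalty * len(S)

    def _best_clause_completion(self, keys, probs):
        """Most-improving 'add all missing edges of one clause' move, or
        None when no such move strictly improves the score."""
        best_d = 1e-12
        best: list[Edge] | None = None
        seen: set[frozenset[Edge]] = set()
        for fi, ev in enumerate(self.ev):
            for full, _unc, _tw in ev._clauses:
                missing = full & ~keys[fi]
                if missing == 0:
                    continue
                add = []
                m = missing
                while m:
                    b = m & -m
                    add.append(ev.edges[b.bit_length() - 1])
                    m ^= b
                key_set = frozenset(add)
                if key_set in seen:
                    continue
                seen.add(key_set)
                d = -self.penalty * len(add)
                affected: set[int] = set()
                for e in add:
                    affected.update(self.formulas_of[e])
                for fj in affected:
                    evj = self.ev[fj]
                    addmask = 0
                    for e in add:
                        bit = evj.bit_of.get(e)
                        if bit:
                            addmask |= bit
                    d += (evj.probability_for_key(keys[fj] | addmask)
                          - probs[fj])
                if d > best_d + 1e-12:
                    best_d, best = d, add
        return best


def optimize_subnetwork(
    formulas: list[PathFormula],
    penalty: float,
    net: WeightedNetwork,
    seed: int,
    evaluators: list[FormulaEvaluator] | None = None,
    restarts: int = 3,
    mutated_genes: set[str] | None = None,
) -> Subnetwork:
    """Heuristically maximize the penalized subnetwork score.

    Candidate edges are the union of all clause edges (no other edge can
    raise the probability term). Greedy steepest ascent over single-edge
    removals and re-additions runs from several start points — the full
    candidate set, the empty set, then random subsets — with seeded
    random tie-breaking; the best-scoring local optimum wins (ties go to
    the earlier start).
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    candidates = tuple(sorted(frozenset().union(
        *(f.relevant_edges for f in formulas)) if formulas else frozenset()))
    for e in candidates:
        if e not in net.edges:
            raise KeyError(f"clause edge {e} missing from the network")
    if evaluators is None:
        evaluators = [FormulaEvaluator(f, net.edges) for f in formulas]
    rng = np.random.default_rng(seed)
    rng_choice = _RngChoice(rng)
    search = _LocalSearch(evaluators, candidates, penalty, rng_choice)
    starts: list[set[Edge]] = [set(candidates)]
    if restarts > 1:
        starts.append(set())
    for _ in range(max(0, restarts - 2)):
        starts.append({e for e in candidates if rng.random() < 0.5})
    best_S: set[Edge] = set()
    best_score = -math.inf
    for start in starts:
        S, score = search.run(start)
        if score > best_score + 1e-12:
            best_S, best_score = S, score
    if best_score < 0.0 and not best_S:
        best_score = 0.0
    mutated_genes = mutated_genes if mutated_genes is not None else {
        f.source for f in formulas
    }
    nodes = {u for (u, _v) in best_S} | {v for (_u, v) in best_S}
    return Subnetwork(
        edges={e: net.edges[e] for e in sorted(best_S)},
        score=best_score,
        mutated_nodes=nodes & mutated_genes,
        connector_nodes=nodes - mutated_genes,
    )


class _RngChoice:
    """Deterministic choice among tied edges, sorted for stability."""

    def __init__(self, rng):
        self.rng = rng

    def choice(self, edges):
        edges = sorted(edges)
        return edges[int(self.rng.integers(len(edges)))]


# ---------------------------------------------------------------------------
# Penalty scan


@dataclass
class PenaltyResult:
    runs: list[Subnetwork]
    best: Subnetwork
    mean_jaccard: float
    accepted: bool
    rejection_reason: str | None


@dataclass
class PenaltyScanResult:
    per_penalty: dict[float, PenaltyResult]
    final_network: Subnetwork
    gene_ranks: dict[str, float]

    @property
    def accepted_penalties(self) -> list[float]:
        return sorted(p for p, r in self.per_penalty.items() if r.accepted)

    def ranked_genes(self) -> list[tuple[str, float]]:
        """Mutated genes sorted by descending rank penalty, then name."""
        mutated = self.final_network.mutated_nodes
        return sorted(
            ((g, r) for g, r in self.gene_ranks.items() if g in mutated),
            key=lambda kv: (-kv[1], kv[0]),
        )


def default_penalty_grid(n: int = 10, lo: float = 0.001, hi: float = 0.5):
    """Logarithmic edge-penalty grid (defaults: 10 points, 0.001-0.5)."""
    return [float(p) for p in np.logspace(np.log10(lo), np.log10(hi), n)]


def _run_seed(seed: int, penalty: float, run: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(round(penalty * 1e9)), run])
    return int(ss.generate_state(1)[0] % (2**31))


def scan_penalties(
    formulas: list[PathFormula],
    net: WeightedNetwork,
    penalties,
    runs_per_penalty: int = 3,
    seed: int = 0,
    mutated_genes: set[str] | None = None,
    max_interactions: int = MAX_INTERACTIONS,
    min_jaccard: float = MIN_JACCARD,
    restarts: int = 3,
) -> PenaltyScanResult:
    """Optimize per penalty with replicate runs and stability acceptance.

    Run seeds derive from (seed, penalty value, replicate index), so the
    result is invariant to the order of the penalty list. A penalty is
    accepted iff best score > 0, mean pairwise Jaccard >= ``min_jaccard``
    and the best subnetwork has <= ``max_interactions`` edges. The final
    network is the union of accepted best subnetworks; gene ranks are the
    highest accepted penalty at which each gene appears.
    """
    if not penalties:
        raise ValueError("penalty list must be non-empty")
    if runs_per_penalty < 2:
        raise ValueError("runs_per_penalty must be >= 2")
    mutated_genes = mutated_genes if mutated_genes is not None else {
        f.source for f in formulas
    }
    evaluators = [FormulaEvaluator(f, net.edges) for f in formulas]
    per_penalty: dict[float, PenaltyResult] = {}
    for penalty in sorted(set(float(p) for p in penalties)):
        runs = [
            optimize_subnetwork(
                formulas, penalty, net,
                seed=_run_seed(seed, penalty, r),
                evaluators=evaluators, restarts=restarts,
                mutated_genes=mutated_genes,
            )
            for r in range(runs_per_penalty)
        ]
        best = runs[0]
        for r in runs[1:]:
            if r.score > best.score + 1e-12:
                best = r
        pairs = [
            jaccard(runs[i].edge_set, runs[j].edge_set)
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        mean_j = float(np.mean(pairs)) if pairs else 1.0
        reason = None
        if not best.score > 0.0:
            reason = "score"
        elif mean_j < min_jaccard:
            reason = "jaccard"
        elif len(best.edges) > max_interactions:
            reason = "size"
        per_penalty[penalty] = PenaltyResult(
            runs=runs, best=best, mean_jaccard=mean_j,
            accepted=reason is None, rejection_reason=reason,
        )

    union_edges: dict[Edge, float] = {}
    gene_ranks: dict[str, float] = {}
    for penalty, res in per_penalty.items():
        if not res.accepted:
            continue
        union_edges.update(res.best.edges)
        for g in res.best.nodes:
            if gene_ranks.get(g, -1.0) < penalty:
                gene_ranks[g] = penalty
    union_nodes = {u for (u, _v) in union_edges} | {v for (_u, v) in union_edges}
    union_score = float(
        sum(ev.probability(frozenset(union_edges)) for ev in evaluators)
    )
    final = Subnetwork(
        edges=dict(sorted(union_edges.items())),
        score=union_score,
        mutated_nodes=union_nodes & mutated_genes,
        connector_nodes=union_nodes - mutated_genes,
    )
    return PenaltyScanResult(
        per_penalty=per_penalty, final_network=final, gene_ranks=gene_ranks
    )


def label_components(
    final: Subnetwork,
    gene_samples: dict[str, set[str]] | None = None,
) -> list[Subnetwork]:
    """Split the final network into connected components, ranked by the
    number of cohort samples with >= 1 mutation in the component.

    Connectivity ignores edge direction. ``gene_samples`` maps each
    mutated gene to the samples carrying it; without it components are
    ranked by size only. Ties break by node count, then by the
    lexicographically smallest node.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(final.edges)
    comps = []
    for nodes in nx.connected_components(g):
        edges = {e: w for e, w in final.edges.items()
                 if e[0] in nodes and e[1] in nodes}
        mutated = nodes & final.mutated_nodes
        covered: set[str] = set()
        if gene_samples:
            for gene in mutated:
                covered |= gene_samples.get(gene, set())
        comps.append((
            Subnetwork(
                edges=dict(sorted(edges.items())),
                score=float(len(covered)),
                mutated_nodes=mutated,
                connector_nodes=nodes - final.mutated_nodes,
            ),
            len(covered), len(nodes), min(nodes),
        ))
    comps.sort(key=lambda t: (-t[1], -t[2], t[3]))
    return [c[0] for c in comps]
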