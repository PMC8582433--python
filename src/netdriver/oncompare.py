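"""Exact Poisson-binomial comparison of mutation rates between groups.

Fisher's exact test assumes every sample is equally likely to carry a
mutation, which breaks down when groups differ in a confounder such as
tumor mutational burden (TMB): high-TMB samples are more likely to carry
a mutation in any gene for purely background reasons. Here each sample
gets its own null mutation probability — either the pooled frequency
(m1 + m2)/(n1 + n2) when no confounders are modeled, or a fitted
logistic regression of the mutation indicator on the confounders, fit on
all samples from both groups. Under the null that group membership adds
nothing beyond the confounders, each group's mutated-sample count then
follows a Poisson binomial distribution, and p-values are exact sums of
the joint pmf over outcome pairs whose group-1:group-2 ratio is at least
(right-sided) or at most (left-sided) as extreme as observed. Ratio
comparisons are done by cross-multiplication (v1*m2 >= v2*m1) so that
zero counts need no special casing; ties count toward both sides.

Gene sets are handled by combining per-gene probabilities into a
per-sample probability of at least one hit, 1 - prod(1 - p_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "GroupedCohort",
    "ComparisonResult",
    "uniform_null_prob",
    "fit_gene_model",
    "pb_pmf",
    "right_pvalue",
    "left_pvalue",
    "geneset_prob",
    "compare",
    "compare_all",
]

RIDGE_LAMBDA = 1e-4  # slope stabilizer for the logistic fits


@dataclass
class GroupedCohort:
    """Two disjoint sample groups with mutation indicators and optional
    per-sample confounder values.

    indicators: DataFrame genes x samples with 0/1 entries.
    confounders: DataFrame samples x features (e.g., a 'tmb' column), or
    None when only the uniform null is wanted.
    """

    group1: list[str]
    group2: list[str]
    indicators: pd.DataFrame
    confounders: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValueError(f"groups overlap: {sorted(overlap)[:3]}...")
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        for s in list(self.group1) + list(self.group2):
            if s not in self.indicators.columns:
                raise KeyError(f"sample {s!r} missing from indicators")

    @property
    def samples(self) -> list[str]:
        return list(self.group1) + list(self.group2)


@dataclass(frozen=True)
class ComparisonResult:
    target: str
    m1: int
    m2: int
    n1: int
    n2: int
    p_right: float
    p_left: float
    corrected: bool


def uniform_null_prob(m1: int, m2: int, n1: int, n2: int) -> float:
    """Pooled null mutation probability (m1 + m2) / (n1 + n2)."""
    if n1 + n2 <= 0:
        raise ValueError("empty cohort")
    if m1 > n1 or m2 > n2 or min(m1, m2) < 0:
        raise ValueError("mutated counts must satisfy 0 <= m_i <= n_i")
    return (m1 + m2) / (n1 + n2)


def fit_gene_model(indicator, confounders, ridge: float = RIDGE_LAMBDA):
    """Per-sample null probabilities from a logistic model on confounders.

    Fit pooled over all samples (both groups). Constant confounder
    columns are dropped; with no informative column left, a constant
    indicator, or a failed fit, falls back to the pooled frequency.
    Returns an array aligned with the input samples.
    """
    y = np.asarray(indicator, dtype=float)
    X = np.asarray(confounders, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mean_y = float(y.mean())
    fallback = np.full(len(y), mean_y)
    if mean_y in (0.0, 1.0):
        return fallback
    keep = X.std(axis=0) > 0
    if not keep.any():
        return fallback
    X = X[:, keep]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            model.fit(Xs, y)
        probs = model.predict_proba(Xs)[:, 1]
    except Exception:
        return fallback
    if not np.all(np.isfinite(probs)):
        return fallback
    return probs


def pb_pmf(probs) -> np.ndarray:
    """Exact Poisson binomial pmf by iterative convolution.

    ``probs`` are the per-trial success probabilities; the result has
    length n + 1 and sums to 1 up to float round-off.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0,1]")
    pmf = np.ones(1)
    for p in probs:
        pmf = np.convolve(pmf, np.array([1.0 - p, p]))
    return pmf


def _ratio_mask(n1: int, n2: int, m1: int, m2: int, side: str) -> np.ndarray:
    v1 = np.arange(n1 + 1)[:, None]
    v2 = np.arange(n2 + 1)[None, :]
    if side == "right":
        return v1 * m2 >= v2 * m1
    return v1 * m2 <= v2 * m1


def right_pvalue(pmf1, pmf2, m1: int, m2: int) -> float:
    """P(v1:v2 ratio at least as extreme toward group 1 as m1:m2).

    Sums the product pmf over all (v1, v2) with v1*m2 >= v2*m1 — the
    cross-multiplied form of v1/v2 >= m1/m2 — so ties, including the
    observed state, are always counted.
    """
    pmf1, pmf2 = np.asarray(pmf1), np.asarray(pmf2)
    n1, n2 = len(pmf1) - 1, len(pmf2) - 1
    if not (0 <= m1 <= n1 and 0 <= m2 <= n2):
        raise ValueError("observed counts exceed group sizes")
    mask = _ratio_mask(n1, n2, m1, m2, "right")
    return min(1.0, max(0.0, float(pmf1 @ mask @ pmf2)))


def left_pvalue(pmf1, pmf2, m1: int, m2: int) -> float:
    """P(v1:v2 ratio at most as extreme toward group 1 as m1:m2)."""
    pmf1, pmf2 = np.asarray(pmf1), np.asarray(pmf2)
    n1, n2 = len(pmf1) - 1, len(pmf2) - 1
    if not (0 <= m1 <= n1 and 0 <= m2 <= n2):
        raise ValueError("observed counts exceed group sizes")
    mask = _ratio_mask(n1, n2, m1, m2, "left")
    return min(1.0, max(0.0, float(pmf1 @ mask @ pmf2)))


def geneset_prob(per_gene_probs) -> float:
    """Probability of at least one mutated gene: 1 - prod(1 - p_i)."""
    p = np.asarray(per_gene_probs, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0,1]")
    return float(1.0 - np.prod(1.0 - p))


def compare(
    cohort: GroupedCohort,
    target,
    use_confounders: bool = True,
    target_id: str | None = None,
) -> ComparisonResult:
    """Test one gene or gene set for differential mutation rate.

    ``target`` is a gene symbol or an iterable of symbols (a set). For a
    set, the observed count in each group is the number of samples with
    at least one mutated member and the per-sample null probability
    combines the per-gene models via :func:`geneset_prob`.
    """
    genes = [target] if isinstance(target, str) else list(target)
    if not genes:
        raise ValueError("empty target")
    for g in genes:
        if g not in cohort.indicators.index:
            raise KeyError(f"gene {g!r} missing from indicators")
    samples = cohort.samples
    n1, n2 = len(cohort.group1), len(cohort.group2)
    ind = cohort.indicators.loc[genes, samples].to_numpy(dtype=float)
    hit = ind.max(axis=0)  # >=1 mutated member
    m1 = int(hit[:n1].sum())
    m2 = int(hit[n1:].sum())

    corrected = bool(use_confounders and cohort.confounders is not None)
    if corrected:
        X = cohort.confounders.loc[samples].to_numpy(dtype=float)
        per_gene = np.vstack([fit_gene_model(row, X) for row in ind])
    else:
        p0 = uniform_null_prob(m1, m2, n1, n2)
        per_gene = np.full_like(ind, p0)
        if len(genes) > 1:
            # with >1 gene the pooled frequency is per gene, not per set
            for i, row in enumerate(ind):
                g1 = int(row[:n1].sum())
                g2 = int(row[n1:].sum())
                per_gene[i, :] = uniform_null_prob(g1, g2, n1, n2)
    sample_probs = 1.0 - np.prod(1.0 - per_gene, axis=0)
    pmf1 = pb_pmf(sample_probs[:n1])
    pmf2 = pb_pmf(sample_probs[n1:])
    return ComparisonResult(
        target=target_id or (genes[0] if len(genes) == 1 else "+".join(genes)),
        m1=m1, m2=m2, n1=n1, n2=n2,
        p_right=right_pvalue(pmf1, pmf2, m1, m2),
        p_left=left_pvalue(pmf1, pmf2, m1, m2),
        corrected=corrected,
    )


def compare_all(
    cohort: GroupedCohort,
    genes=None,
    use_confounders: bool = True,
    gene_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Run :func:`compare` for every gene (and optional named set) and
    return a tidy results table."""
    genes = list(genes) if genes is not None else list(cohort.indicators.index)
    rows = []
    for g in genes:
        rows.append(compare(cohort, g, use_confounders))
    for set_id, members in (gene_sets or {}).items():
        rows.append(compare(cohort, members, use_confounders, target_id=set_id))
    return pd.DataFrame(
        {
            "target": [r.target for r in rows],
            "m1": [r.m1 for r in rows],
            "m2": [r.m2 for r in rows],
            "n1": [r.n1 for r in rows],
            "n2": [r.n2 for r in rows],
            "p_right": [r.p_right for r in rows],
            "p_left": [r.p_left for r in rows],
            "corrected": [r.corrected for r in rows],
        }
    )
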