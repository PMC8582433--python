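"""Driver categorization and benchmark metrics.

Candidate drivers are classified along two axes. The *enrichment* axis
summarizes, across two independent metastatic-vs-primary comparisons,
whether a gene's metastatic mutation excess survives correction for
tumor mutational burden. The *evolution* axis uses patients with
multiple sequenced lesions to place a gene's mutations early (present in
the primary and all metastases), at the primary-to-metastasis transition
(absent from the primary but truncal — shared by most metastatic
lesions), or late (subclonal in the metastases). Finally, a ranked gene
list can be benchmarked against a curated gold-standard set via the
true-positive ratio among the top predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EnrichmentFlags",
    "PatientLesionProfile",
    "enrichment_category",
    "evolution_class",
    "tp_ratio",
    "ENRICHMENT_CATEGORIES",
    "EVOLUTION_CLASSES",
]

ENRICHMENT_CATEGORIES = (
    "strong", "intermediate", "weak", "no_sign_with_tmb", "no_enrichment",
)
EVOLUTION_CLASSES = ("primary_early", "transitional", "late", "not_observed")


@dataclass(frozen=True)
class EnrichmentFlags:
    """Significance flags for one gene in two metastatic cohorts.

    ``raw`` flags come from the uncorrected right-sided test at level
    ``alpha``; ``corrected`` flags from the confounder-corrected test.
    """

    raw_cohort1: bool
    corrected_cohort1: bool
    raw_cohort2: bool
    corrected_cohort2: bool
    alpha: float = 0.05


def enrichment_category(flags: EnrichmentFlags) -> str:
    """Map the four significance flags to an enrichment-signal class.

    strong: corrected-significant in both cohorts. intermediate:
    raw-significant in both, corrected-significant in exactly one.
    weak: raw-and-corrected significant in exactly one cohort (not
    qualifying above). no_sign_with_tmb: raw-significant in both but
    corrected in neither. no_enrichment: anything else.
    """
    r1, c1 = flags.raw_cohort1, flags.corrected_cohort1
    r2, c2 = flags.raw_cohort2, flags.corrected_cohort2
    if c1 and c2:
        return "strong"
    if r1 and r2 and (c1 != c2):
        return "intermediate"
    if (r1 and c1) != (r2 and c2):
        return "weak"
    if r1 and r2 and not c1 and not c2:
        return "no_sign_with_tmb"
    return "no_enrichment"


def flags_from_pvalues(
    p_raw_1: float, p_corr_1: float, p_raw_2: float, p_corr_2: float,
    alpha: float = 0.05,
) -> EnrichmentFlags:
    return EnrichmentFlags(
        raw_cohort1=p_raw_1 < alpha,
        corrected_cohort1=p_corr_1 < alpha,
        raw_cohort2=p_raw_2 < alpha,
        corrected_cohort2=p_corr_2 < alpha,
        alpha=alpha,
    )


@dataclass(frozen=True)
class PatientLesionProfile:
    """Mutation status of one gene (or variant) across a patient's
    lesions. Patients need >= 2 metastatic lesions to be informative."""

    patient: str
    primary_available: bool
    primary_mutated: bool
    metastases: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.metastases) < 2:
            raise ValueError(
                f"patient {self.patient}: >= 2 metastatic lesions required"
            )
        if self.primary_mutated and not self.primary_available:
            raise ValueError("primary_mutated set without a primary sample")

    @property
    def mutated(self) -> bool:
        return self.primary_mutated or any(self.metastases)

    @property
    def truncal(self) -> bool:
        """Mutation in > 50% of this patient's metastatic lesions."""
        return sum(self.metastases) / len(self.metastases) > 0.5

    @property
    def all_lesions(self) -> bool:
        return all(self.metastases)


def evolution_class(profiles) -> str:
    """Tumor-evolution class of a gene from multi-lesion patients.

    primary_early: > 50% of the patients carrying the mutation have it in
    the primary (when one is available) and in all their metastatic
    lesions. transitional: not qualifying above, but > 50% of mutated
    patients lack the mutation in the matched primary while carrying it
    truncally (> 50% of lesions). late: everything else mutated — the
    mutation is typically subclonal within the metastases.
    """
    profiles = list(profiles)
    mutated = [p for p in profiles if p.mutated]
    if not mutated:
        return "not_observed"
    n = len(mutated)
    early = sum(
        1 for p in mutated
        if (p.primary_mutated or not p.primary_available) and p.all_lesions
    )
    if early / n > 0.5:
        return "primary_early"
    transitional = sum(
        1 for p in mutated
        if not p.primary_mutated and p.truncal
    )
    if transitional / n > 0.5:
        return "transitional"
    return "late"


def tp_ratio(ranked, gold, top_k: int | None = None) -> float:
    """Fraction of gold-standard genes among the top-k predictions.

    ``ranked`` is either a list of genes (best first) or a list of
    (gene, rank_score) pairs with higher scores better. With scored
    input, a tie block straddling the k boundary is included whole, so
    the effective k may exceed ``top_k``.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked list must be non-empty")
    if ranked and isinstance(ranked[0], (tuple, list)):
        genes = [g for g, _s in ranked]
        scores = [s for _g, s in ranked]
    else:
        genes = list(ranked)
        scores = None
    k = len(genes) if top_k is None else min(top_k, len(genes))
    if scores is not None and k < len(genes):
        boundary = scores[k - 1]
        while k < len(genes) and scores[k] == boundary:
            k += 1
    top = genes[:k]
    gold = set(gold)
    return sum(1 for g in top if g in gold) / len(top)
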