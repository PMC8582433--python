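"""Cohort mutation table: loading, variant filters, sample QC, relevance.

Somatic mutation records arrive as a MAF-like TSV with one row per variant
call. Records carry a variant allele frequency (VAF), read coverage, a
functional impact score in [0, 1] (FATHMM-style pathogenicity; CADD scores
can be converted with :func:`cadd_to_probability`), and a consequence
class. Low-quality and non-coding-consequence calls are removed, samples
with outlying mutation counts are discarded, and hypermutator samples
receive a multiplicative correction factor so their mutations do not
swamp the path scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "SchemaError",
    "DEFAULT_EXCLUDED_CONSEQUENCES",
    "load_mutations",
    "filter_variants",
    "cadd_to_probability",
    "flag_outlier_samples",
    "compute_sample_corrections",
    "relevance_score",
    "gene_relevance_map",
]

REQUIRED_COLUMNS = ("sample", "gene", "vaf", "coverage", "impact", "consequence")

#: Consequence classes with no expected protein-level effect.
DEFAULT_EXCLUDED_CONSEQUENCES = frozenset(
    {"silent", "intron", "intergenic", "upstream", "downstream", "3'UTR", "5'UTR"}
)

HYPERMUTATOR_ZSCORE = 3.5


class SchemaError(ValueError):
    """Raised when the mutation table is missing required columns."""


@dataclass
class CohortTable:
    """Mutation records plus per-sample statistics.

    records
        DataFrame with columns sample, gene, variant, vaf, coverage,
        impact, consequence (one row per mutation call).
    stats
        DataFrame indexed by sample id with columns tmb (pre-filter
        mutation count), log_count (log10 of current record count),
        zscore, outlier, hypermutator, correction.
    """

    records: pd.DataFrame
    stats: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stats is None:
            self.stats = _init_stats(self.records)

    @property
    def samples(self) -> list[str]:
        return list(self.stats.index)

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"].unique())

    def copy(self) -> "CohortTable":
        return CohortTable(self.records.copy(), self.stats.copy())


def _init_stats(records: pd.DataFrame) -> pd.DataFrame:
    counts = records.groupby("sample").size() if len(records) else pd.Series(dtype=int)
    stats = pd.DataFrame(index=counts.index.rename("sample"))
    stats["tmb"] = counts.astype(int)
    stats["log_count"] = np.log10(np.maximum(counts, 1))
    stats["zscore"] = 0.0
    stats["outlier"] = False
    stats["hypermutator"] = False
    stats["correction"] = 1.0
    return stats


def load_mutations(path) -> CohortTable:
    """Load a MAF-like TSV (columns sample, gene, vaf, coverage, impact,
    consequence; variant optional).

    Per-sample ``tmb`` is set to the raw pre-filter row count so that
    burden-based statistics remain comparable after filtering.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "variant" not in df.columns:
        df["variant"] = ""
    for col, kind in (("vaf", float), ("coverage", int), ("impact", float)):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise ValueError(f"unparseable {col!r} value at line {row}") from exc
        if kind is int:
            df[col] = df[col].astype(int)
    if len(df):
        if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
            raise ValueError("vaf outside [0,1]")
        if (df["coverage"] < 0).any():
            raise ValueError("negative coverage")
        impacts = df["impact"].dropna()
        if ((impacts < 0) | (impacts > 1)).any():
            raise ValueError("impact score outside [0,1]")
    df = df[["sample", "gene", "variant", "vaf", "coverage", "impact",
             "consequence"]].reset_index(drop=True)
    return CohortTable(records=df)


def filter_variants(
    table: CohortTable,
    min_vaf: float = 0.1,
    min_coverage: int = 5,
    excluded_consequences: frozenset[str] = DEFAULT_EXCLUDED_CONSEQUENCES,
) -> CohortTable:
    """Drop low-quality and non-impactful calls.

    A record is removed when its coverage is below ``min_coverage``, its
    VAF is below ``min_vaf`` (both thresholds strict: records exactly at
    the threshold are kept), its consequence class is excluded, or it has
    no impact score. Pre-filter ``tmb`` values are preserved; idempotent.
    """
    rec = table.records
    keep = (
        (rec["coverage"] >= min_coverage)
        & (rec["vaf"] >= min_vaf)
        & ~rec["consequence"].isin(excluded_consequences)
        & rec["impact"].notna()
    )
    rec = rec[keep].reset_index(drop=True)
    stats = table.stats.copy()
    counts = rec.groupby("sample").size().reindex(stats.index).fillna(0)
    stats["log_count"] = np.log10(np.maximum(counts, 1))
    return CohortTable(records=rec, stats=stats)


def cadd_to_probability(x, scale: float = 1.04, midpoint: float = 10.0):
    """Convert CADD-scale deleteriousness scores to probabilities.

    p = 1 / (1 + scale^(-x + midpoint)). Strictly increasing with range
    (0, 1); underflows gracefully toward 0/1 for extreme scores. Accepts
    scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + scale ** (-x + midpoint))
    return float(p) if p.ndim == 0 else p


def flag_outlier_samples(table: CohortTable) -> CohortTable:
    """Remove samples whose log10 mutation burden falls outside the
    Tukey boxplot whiskers [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    The burden is the pre-filter ``tmb`` count (like TMB, it is
    evaluated before any variant filtering), so flagging commutes with
    :func:`filter_variants`. Quartiles use linear interpolation.
    Requires >= 4 samples. Records of flagged samples are removed; their
    stats rows remain with ``outlier=True`` for reporting. Idempotent.
    """
    stats = table.stats.copy()
    active = stats.index[~stats["outlier"]]
    if len(active) < 4:
        raise ValueError("outlier flagging needs >= 4 samples")
    logc = np.log10(np.maximum(stats.loc[active, "tmb"], 1))
    q1, q3 = np.quantile(logc, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = logc.index[(logc < lo) | (logc > hi)]
    stats.loc[flagged, "outlier"] = True
    rec = table.records[
        ~table.records["sample"].isin(stats.index[stats["outlier"]])
    ].reset_index(drop=True)
    return CohortTable(records=rec, stats=stats)


def compute_sample_corrections(table: CohortTable) -> CohortTable:
    """Z-score the log10 mutation counts and damp hypermutators.

    Samples with z > 3.5 are flagged hypermutators and get
    correction = median(count) / count clamped to (0, 1]; all others get
    correction 1. A zero standard deviation yields all-zero z-scores.
    Outlier samples are excluded from the mean/sd and keep correction 1.
    """
    stats = table.stats.copy()
    active = stats.index[~stats["outlier"]]
    counts = table.records.groupby("sample").size().reindex(active).fillna(0)
    logc = np.log10(np.maximum(counts, 1))
    sd = float(logc.std(ddof=0))
    z = (logc - logc.mean()) / sd if sd > 0 else logc * 0.0
    stats.loc[active, "zscore"] = z
    hyper = z.index[z > HYPERMUTATOR_ZSCORE]
    stats["hypermutator"] = False
    stats.loc[hyper, "hypermutator"] = True
    stats["correction"] = 1.0
    if len(hyper):
        med = float(counts.median())
        corr = (med / counts.loc[hyper]).clip(upper=1.0)
        corr[corr <= 0] = 1.0
        stats.loc[hyper, "correction"] = corr
    return CohortTable(records=table.records.copy(), stats=stats)


def relevance_score(impact: float, vaf: float, correction: float = 1.0) -> float:
    """Per-mutation relevance: impact * VAF * sample correction, in [0,1].

    Each factor is already a probability-like weight, so their product is
    used; the combination is deliberately simple and can be swapped out by
    callers that precompute relevances themselves.
    """
    return float(impact) * float(vaf) * float(correction)


def gene_relevance_map(table: CohortTable) -> dict[str, dict[str, float]]:
    """Best per-(gene, sample) relevance: gene -> {sample: max relevance}."""
    corr = table.stats["correction"]
    rec = table.records
    rel = rec["impact"].to_numpy() * rec["vaf"].to_numpy() * corr.reindex(
        rec["sample"]).to_numpy()
    out: dict[str, dict[str, float]] = {}
    for gene, sample, r in zip(rec["gene"], rec["sample"], rel):
        d = out.setdefault(gene, {})
        if r > d.get(sample, 0.0):
            d[sample] = r
    return out


def save_cohort(table: CohortTable, records_path, stats_path=None) -> None:
    """Write the filtered records TSV and, optionally, the per-sample
    statistics TSV."""
    table.records.to_csv(records_path, sep="\t", index=False)
    if stats_path is not None:
        table.stats.to_csv(stats_path, sep="\t")
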