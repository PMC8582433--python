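"""End-to-end orchestration of the driver-discovery workflow.

The file-level entry points (`run_gonetic`, `run_oncompare`) read the
standard TSV inputs, execute the library modules in order, and write the
output tables; the object-level `driver_pipeline` is the same workflow
for callers that already hold a network and cohort in memory (tests,
simulations). Every stage failure is wrapped in a :class:`StageError`
naming the stage so command-line users can see where a run died.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from netdriver import cohort as cohort_mod
from netdriver import network_prior, oncompare, pathfinding, subnetwork_selection
from netdriver.cohort import CohortTable
from netdriver.network_prior import WeightedNetwork

logger = logging.getLogger("netdriver")

__all__ = ["RunConfig", "StageError", "driver_pipeline", "run_gonetic",
           "run_oncompare"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat configuration for the driver pipeline.

    Defaults follow the method's published settings: paths capped at 25
    per source and 4 edges with score threshold 0.2; penalties rejected
    on negative score, mean Jaccard < 0.5 or > 80 edges; variant filters
    at VAF 0.1 / coverage 5 with non-coding consequences excluded.
    """

    # network prior
    default_weight: float = 1.0
    undirected: bool = False
    # cohort
    min_vaf: float = 0.1
    min_coverage: int = 5
    excluded_consequences: tuple[str, ...] = tuple(
        sorted(cohort_mod.DEFAULT_EXCLUDED_CONSEQUENCES)
    )
    score_scale: str = "probability"  # or "cadd"
    remove_outliers: bool = True
    # pathfinding
    max_paths: int = 25
    min_path_prob: float = 0.2
    max_path_edges: int = 4
    # penalty scan
    penalties: tuple[float, ...] = tuple(
        subnetwork_selection.default_penalty_grid()
    )
    runs_per_penalty: int = 3
    max_interactions: int = 80
    min_jaccard: float = 0.5
    restarts: int = 3
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        for key in ("excluded_consequences", "penalties"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_consequences"] = list(d["excluded_consequences"])
        d["penalties"] = list(d["penalties"])
        return d


def prepare_cohort(table: CohortTable, config: RunConfig) -> CohortTable:
    """Filter variants, optionally convert CADD scores, drop outlier
    samples, and compute hypermutator corrections."""
    if config.score_scale == "cadd":
        table = table.copy()
        table.records["impact"] = cohort_mod.cadd_to_probability(
            table.records["impact"].to_numpy()
        )
    elif config.score_scale != "probability":
        raise ValueError(f"unknown score_scale {config.score_scale!r}")
    table = cohort_mod.filter_variants(
        table,
        min_vaf=config.min_vaf,
        min_coverage=config.min_coverage,
        excluded_consequences=frozenset(config.excluded_consequences),
    )
    if config.remove_outliers:
        table = cohort_mod.flag_outlier_samples(table)
    return cohort_mod.compute_sample_corrections(table)


def driver_pipeline(
    net: WeightedNetwork,
    table: CohortTable,
    config: RunConfig | None = None,
    prepared: bool = False,
) -> dict:
    """Run reweighting, pathfinding and the penalty scan; return all
    intermediate and final artifacts in a dict."""
    config = config or RunConfig()
    if not prepared:
        table = prepare_cohort(table, config)
    model = network_prior.fit_degree_model(net)
    reweighted = network_prior.reweight_edges(net, model)
    cfg = pathfinding.PathfindingConfig(
        max_paths_per_source=config.max_paths,
        min_path_prob=config.min_path_prob,
        max_edges=config.max_path_edges,
    )
    index = pathfinding.enumerate_paths(reweighted, table, cfg)
    if index.skipped_genes:
        logger.info("%d mutated genes absent from the network",
                    index.skipped_genes)
    formulas = subnetwork_selection.build_formulas(index)
    scan = subnetwork_selection.scan_penalties(
        formulas,
        reweighted,
        penalties=list(config.penalties),
        runs_per_penalty=config.runs_per_penalty,
        seed=config.seed,
        mutated_genes=table.genes,
        max_interactions=config.max_interactions,
        min_jaccard=config.min_jaccard,
        restarts=config.restarts,
    )
    if not scan.accepted_penalties:
        logger.warning("no edge penalty accepted; final network is empty")
    gene_samples = {
        g: set(grp["sample"]) for g, grp in table.records.groupby("gene")
    }
    components = subnetwork_selection.label_components(
        scan.final_network, gene_samples
    )
    return dict(
        cohort=table,
        degree_model=model,
        network=reweighted,
        path_index=index,
        formulas=formulas,
        scan=scan,
        components=components,
        gene_samples=gene_samples,
        config=config,
    )


def _write_outputs(result: dict, outdir: str) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    scan = result["scan"]
    written = []

    path = os.path.join(outdir, "final_network.tsv")
    if scan.final_network.edges:
        network_prior.save_network(
            WeightedNetwork(edges=dict(scan.final_network.edges)), path)
    else:
        open(path, "w").close()
    written.append(path)

    path = os.path.join(outdir, "components.tsv")
    with open(path, "w") as fh:
        fh.write("component\trank\tgenes\tconnectors\tsamples_covered\n")
        for rank, comp in enumerate(result["components"], start=1):
            genes = ",".join(sorted(comp.mutated_nodes))
            conns = ",".join(sorted(comp.connector_nodes))
            fh.write(f"C{rank}\t{rank}\t{genes}\t{conns}\t{int(comp.score)}\n")
    written.append(path)

    path = os.path.join(outdir, "gene_ranking.tsv")
    gene_samples = result["gene_samples"]
    n_samples = len(result["cohort"].stats.index[
        ~result["cohort"].stats["outlier"]])
    with open(path, "w") as fh:
        fh.write("gene\trank_penalty\trole\tmutation_frequency\n")
        for g in sorted(scan.gene_ranks,
                        key=lambda g: (-scan.gene_ranks[g], g)):
            role = ("mutated" if g in scan.final_network.mutated_nodes
                    else "connector")
            freq = len(gene_samples.get(g, ())) / max(n_samples, 1)
            fh.write(f"{g}\t{scan.gene_ranks[g]:.6g}\t{role}\t{freq:.4f}\n")
    written.append(path)

    path = os.path.join(outdir, "scan_report.json")
    report = {
        "config": result["config"].resolved(),
        "penalties": {
            f"{p:.6g}": {
                "score": res.best.score,
                "mean_jaccard": res.mean_jaccard,
                "size": len(res.best.edges),
                "accepted": res.accepted,
                "reason": res.rejection_reason,
            }
            for p, res in scan.per_penalty.items()
        },
        "final_edges": len(scan.final_network.edges),
        "mutated_genes": sorted(scan.final_network.mutated_nodes),
        "connector_genes": sorted(scan.final_network.connector_nodes),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    written.append(path)
    return written


def run_gonetic(network_path, mutations_path, outdir,
                config: RunConfig | None = None) -> list[str]:
    """File-level driver pipeline; returns the list of written files."""
    config = config or RunConfig()
    logger.info("resolved config: %s", json.dumps(config.resolved(),
                                                  sort_keys=True))
    try:
        net = network_prior.load_network(
            network_path, default_weight=config.default_weight,
            undirected=config.undirected,
        )
    except (OSError, ValueError) as exc:
        raise StageError("network_prior", str(exc)) from exc
    try:
        table = cohort_mod.load_mutations(mutations_path)
        table = prepare_cohort(table, config)
    except (OSError, ValueError) as exc:
        raise StageError("cohort", str(exc)) from exc
    try:
        result = driver_pipeline(net, table, config, prepared=True)
    except Exception as exc:
        raise StageError("subnetwork_selection", str(exc)) from exc
    return _write_outputs(result, outdir)


def run_oncompare(indicators_path, annotations_path, out_path,
                  sets_path=None, confounder_cols=("tmb",),
                  alpha: float = 0.05) -> pd.DataFrame:
    """File-level group comparison; writes and returns the results table.

    The indicator matrix is genes x samples (0/1); the annotation TSV
    needs columns ``sample`` and ``group`` (two distinct labels) plus
    the confounder columns. Both raw and confounder-corrected p-values
    are reported per gene (and per gene set when ``sets_path`` names
    one: lines of ``set_id<TAB>gene1,gene2,...``).
    """
    try:
        ind = pd.read_csv(indicators_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotations_path, sep="\t")
        if "sample" not in ann.columns or "group" not in ann.columns:
            raise ValueError("annotation file needs 'sample' and 'group'")
        missing = [c for c in confounder_cols if c not in ann.columns]
        if missing:
            raise ValueError(f"missing confounder column(s): {missing}")
    except (OSError, ValueError) as exc:
        raise StageError("oncompare", str(exc)) from exc
    groups = sorted(ann["group"].unique())
    if len(groups) != 2:
        raise StageError("oncompare", f"need exactly 2 groups, got {groups}")
    ann = ann.set_index("sample")
    g1 = list(ann.index[ann["group"] == groups[0]])
    g2 = list(ann.index[ann["group"] == groups[1]])
    cohort = oncompare.GroupedCohort(
        group1=g1, group2=g2, indicators=ind,
        confounders=ann[list(confounder_cols)] if confounder_cols else None,
    )
    gene_sets = None
    if sets_path:
        gene_sets = {}
        with open(sets_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                set_id, members = line.split("\t")
                gene_sets[set_id] = members.split(",")
    raw = oncompare.compare_all(cohort, use_confounders=False,
                                gene_sets=gene_sets)
    corr = oncompare.compare_all(cohort, use_confounders=True,
                                 gene_sets=gene_sets)
    out = raw.drop(columns=["corrected"]).rename(
        columns={"p_right": "p_right_raw", "p_left": "p_left_raw"})
    out["p_right_corrected"] = corr["p_right"]
    out["p_left_corrected"] = corr["p_left"]
    out.to_csv(out_path, sep="\t", index=False)
    return out
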