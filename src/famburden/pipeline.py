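"""End-to-end orchestration: filter -> genes -> clusters -> terms ->
burden -> segregation, with per-stage TSV reports and a summary JSON.

All ordering is deterministic, so a rerun with the same inputs and
configuration reproduces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as fio
from .enrichment import (
    GeneCluster,
    GoTerm,
    TermAssignment,
    TermBurdenResult,
    assign_term,
    build_network,
    find_clusters,
    term_burden_test,
    terms_from_gmt,
)
from .genes import (
    GeneVariantTable,
    Segregation,
    aggregate_by_gene,
    exclude_hypervariable,
    family_dedup_counts,
    segregation_check,
    select_lof_genes,
)
from .meta import ReferencePanel, run_meta_analysis
from .variants import (
    AnnotatedVariant,
    CohortDesign,
    FilterConfig,
    FilterLog,
    filter_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run."""

    vcf: str | Path | None = None
    ped: str | Path | None = None
    edges: str | Path | None = None
    gmt: str | Path | None = None
    control: str | Path | None = None
    study_records: str | Path | None = None
    meta_config: str | Path | None = None
    csq_format: str = fio.DEFAULT_CSQ_FORMAT
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_cluster_size: int = 5
    term_min_genes: int = 10
    term_max_genes: int = 200
    alpha: float = 0.05
    hypervariable_fraction: float = 0.01
    exclusion_order: str = "lof_first"  # lof_first | exclude_first
    burden_mode: str = "proportion_of_burden"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.exclusion_order not in ("lof_first", "exclude_first"):
            raise ValueError("exclusion_order must be lof_first or exclude_first")
        if not (self.min_cluster_size >= 1):
            raise ValueError("min_cluster_size must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")


@dataclass
class ClusterReport:
    cluster: GeneCluster
    assignment: TermAssignment | None
    burden: TermBurdenResult | None


@dataclass
class AnalysisResult:
    """Everything the cohort analysis produces, in memory."""

    filter_log: FilterLog
    filtered: list[AnnotatedVariant]
    table: GeneVariantTable
    lof_genes: list[str]
    excluded_genes: list[str]
    candidates: list[str]
    gene_universe: frozenset[str]
    clusters: list[ClusterReport]
    dedup: dict[tuple[str, int, str, str], int]
    segregation: list[dict]

    @property
    def selected_terms(self) -> list[GoTerm]:
        return [c.assignment.term for c in self.clusters if c.assignment]


def analyse_cohort(
    variants: list[AnnotatedVariant],
    design: CohortDesign,
    edges: list[tuple[str, str]],
    terms: list[GoTerm],
    control_counts: dict[str, int],
    control_size: int,
    cfg: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the in-memory analysis chain on an already-parsed cohort."""
    cfg = cfg or PipelineConfig()
    log = FilterLog()
    filtered = filter_cohort(variants, design, cfg.filter, log)
    table = aggregate_by_gene(filtered)

    if cfg.exclusion_order == "lof_first":
        lof_genes = select_lof_genes(table)
        if lof_genes:
            sub = GeneVariantTable(
                entries={g: table.entries[g] for g in lof_genes}
            )
            candidates, excluded = exclude_hypervariable(
                sub, cfg.hypervariable_fraction
            )
        else:
            candidates, excluded = [], []
    else:
        if table.genes:
            kept, excluded = exclude_hypervariable(table, cfg.hypervariable_fraction)
        else:
            kept, excluded = [], []
        lof_genes = select_lof_genes(table)
        candidates = select_lof_genes(table, within=kept)

    gene_universe = frozenset(g for g in table.genes if g not in set(excluded))

    clusters: list[ClusterReport] = []
    if candidates:
        net = build_network(edges)
        background = frozenset(
            {g for t in terms for g in t.genes} | set(net.nodes) | set(candidates)
        )
        for cl in find_clusters(net, candidates, cfg.min_cluster_size):
            assignment = assign_term(
                cl, terms, background,
                alpha=cfg.alpha,
                min_genes=cfg.term_min_genes,
                max_genes=cfg.term_max_genes,
            )
            burden = None
            if assignment is not None:
                burden = term_burden_test(
                    assignment.term, filtered, design,
                    control_counts, control_size,
                    mode=cfg.burden_mode, gene_universe=gene_universe,
                )
            clusters.append(ClusterReport(cl, assignment, burden))

    dedup = family_dedup_counts(filtered, design)

    # segregation of candidate-cluster variants, family by family
    seg_rows: list[dict] = []
    cluster_genes = {g for c in clusters for g in c.cluster.members}
    fams = design.families
    for v in filtered:
        if v.gene not in cluster_genes:
            continue
        carriers = set(v.carriers())
        for fam, members in sorted(fams.items()):
            if not carriers & set(members):
                continue
            status = segregation_check(v, members, design)
            seg_rows.append(
                {
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "gene": v.gene, "family": fam, "status": status.value,
                }
            )

    return AnalysisResult(
        filter_log=log,
        filtered=filtered,
        table=table,
        lof_genes=lof_genes,
        excluded_genes=list(excluded),
        candidates=list(candidates),
        gene_universe=gene_universe,
        clusters=clusters,
        dedup=dedup,
        segregation=seg_rows,
    )


def _summary_dict(res: AnalysisResult, cfg: PipelineConfig) -> dict:
    return {
        "counts": {
            "input_variants": res.filter_log.n_input,
            "filtered_variants": len(res.filtered),
            "genes": len(res.table.genes),
            "lof_genes": len(res.lof_genes),
            "hypervariable_excluded": len(res.excluded_genes),
            "candidate_genes": len(res.candidates),
            "clusters": len(res.clusters),
        },
        "filter_log": res.filter_log.as_dict(),
        "excluded_genes": res.excluded_genes,
        "clusters": [
            {
                "size": c.cluster.size,
                "members": c.cluster.sorted_members(),
                "term": None if c.assignment is None else {
                    "id": c.assignment.term.id,
                    "name": c.assignment.term.name,
                    "size": c.assignment.term.size,
                    "raw_p": c.assignment.raw_p,
                    "adjusted_p": c.assignment.adjusted_p,
                },
                "burden": None if c.burden is None else {
                    "term_id": c.burden.term.id,
                    "mode": c.burden.mode,
                    "table": [
                        c.burden.table.a, c.burden.table.b,
                        c.burden.table.c, c.burden.table.d,
                    ],
                    "case_count": c.burden.case_count,
                    "control_count": c.burden.control_count,
                    "p": c.burden.p,
                },
            }
            for c in res.clusters
        ],
        "selected_terms": [t.id for t in res.selected_terms],
        "config": {
            "exclusion_order": cfg.exclusion_order,
            "burden_mode": cfg.burden_mode,
            "hypervariable_fraction": cfg.hypervariable_fraction,
            "min_cluster_size": cfg.min_cluster_size,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
        },
    }


def run_all(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage from files and write all reports.

    Returns the run directory. Raises on missing inputs (fail fast with
    the offending path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("vcf", "ped", "edges", "gmt", "control"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name!r} missing: {p}")

    variants, vcf_samples = fio.read_annotated_vcf(cfg.vcf, cfg.csq_format)
    design = fio.cohort_from_ped(cfg.ped, vcf_samples)
    edges = fio.read_edge_list(cfg.edges)
    terms = terms_from_gmt(fio.read_gmt(cfg.gmt))
    control_counts, control_size = fio.read_control_counts(cfg.control)

    res = analyse_cohort(
        variants, design, edges, terms, control_counts, control_size, cfg
    )

    fio.write_variant_table(res.filtered, design, outdir / "filtered_variants.tsv")
    _write_gene_report(res, outdir / "genes.tsv")
    _write_cluster_reports(res, outdir)
    pd.DataFrame(
        res.segregation,
        columns=["chrom", "pos", "ref", "alt", "gene", "family", "status"],
    ).to_csv(outdir / "segregation.tsv", sep="\t", index=False)

    summary = _summary_dict(res, cfg)

    if cfg.study_records is not None and cfg.meta_config is not None:
        meta_df, meta_notes = run_meta_from_files(
            cfg.study_records, cfg.meta_config
        )
        meta_df.to_csv(outdir / "meta_analysis.tsv", sep="\t", index=False)
        summary["meta_notes"] = meta_notes

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return outdir


def run_meta_from_files(
    records_path: str | Path, config_path: str | Path
) -> tuple[pd.DataFrame, list[str]]:
    """Run the carrier meta-analysis from a records TSV and config JSON."""
    records = fio.read_study_records(records_path)
    with open(config_path) as fh:
        mc = json.load(fh)
    panels = [
        ReferencePanel(p["name"], int(p["carriers"]), int(p["size"]))
        for p in mc["panels"]
    ]
    report = run_meta_analysis(
        records,
        gene=mc["gene"],
        total_probands=int(mc["total_probands"]),
        panels=panels,
        exclusions=mc.get("exclusions"),
        published_carriers=mc.get("published_carriers"),
        unit=mc.get("unit", "allele"),
    )
    df = report.to_frame()
    df.insert(1, "carriers_aggregated", report.carriers_aggregated)
    return df, report.notes


def _write_gene_report(res: AnalysisResult, path: Path) -> None:
    from .variants import ConsequenceClass

    excluded = set(res.excluded_genes)
    rows = []
    for g in sorted(res.table.genes):
        vs = res.table.entries[g]
        rows.append(
            {
                "gene": g,
                "n_variants": len(vs),
                "n_lof": sum(
                    1 for v in vs if v.consequence is ConsequenceClass.LOF
                ),
                "hypervariable": g in excluded,
                "candidate": g in set(res.candidates),
                "dedup_family_counts": ";".join(
                    str(res.dedup[v.key]) for v in vs
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene", "n_variants", "n_lof", "hypervariable", "candidate",
                 "dedup_family_counts"],
    ).to_csv(path, sep="\t", index=False)


def _write_cluster_reports(res: AnalysisResult, outdir: Path) -> None:
    cl_rows, term_rows, burden_rows = [], [], []
    for i, c in enumerate(res.clusters, start=1):
        cl_rows.append(
            {
                "cluster": i,
                "size": c.cluster.size,
                "members": ";".join(c.cluster.sorted_members()),
            }
        )
        if c.assignment:
            term_rows.append(
                {
                    "cluster": i,
                    "term_id": c.assignment.term.id,
                    "term_name": c.assignment.term.name,
                    "term_size": c.assignment.term.size,
                    "raw_p": c.assignment.raw_p,
                    "adjusted_p": c.assignment.adjusted_p,
                }
            )
        if c.burden:
            t = c.burden.table
            burden_rows.append(
                {
                    "cluster": i,
                    "term_id": c.burden.term.id,
                    "mode": c.burden.mode,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "case_count": c.burden.case_count,
                    "control_count": c.burden.control_count,
                    "p": c.burden.p,
                }
            )
    pd.DataFrame(cl_rows, columns=["cluster", "size", "members"]).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        term_rows,
        columns=["cluster", "term_id", "term_name", "term_size", "raw_p",
                 "adjusted_p"],
    ).to_csv(outdir / "term_assignment.tsv", sep="\t", index=False)
    pd.DataFrame(
        burden_rows,
        columns=["cluster", "term_id", "mode", "a", "b", "c", "d",
                 "case_count", "control_count", "p"],
    ).to_csv(outdir / "burden.tsv", sep="\t", index=False)
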