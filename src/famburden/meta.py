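"""Cross-study carrier meta-analysis for a target gene.

Published proband-level variant reports are harmonised to consequence
classes, loss-of-function carriers are counted once per proband, and
carrier enrichment against a reference panel (e.g. 1000 Genomes
Europeans, or ExAC non-Finnish Europeans) is tested with a one-tailed
Fisher exact test. Counting defaults to allele-level denominators
(2N chromosomes per cohort), matching aggregation of allele counts
across studies; a per-individual carrier mode is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .stats import ContingencyTable2x2, fisher_one_tailed_greater
from .variants import ConsequenceClass

logger = logging.getLogger(__name__)

#: Free-text consequence labels, as printed in published reports,
#: normalised to consequence classes before LoF filtering.
_LABEL_CLASS = {
    "fs deletion": ConsequenceClass.LOF,
    "fs insertion": ConsequenceClass.LOF,
    "frameshift deletion": ConsequenceClass.LOF,
    "frameshift insertion": ConsequenceClass.LOF,
    "frameshift variant": ConsequenceClass.LOF,
    "stop-site gain": ConsequenceClass.LOF,
    "stop site gain": ConsequenceClass.LOF,
    "stop site gained": ConsequenceClass.LOF,
    "stop gained": ConsequenceClass.LOF,
    "stop-site loss": ConsequenceClass.LOF,
    "stop site lost": ConsequenceClass.LOF,
    "start-site loss": ConsequenceClass.LOF,
    "start site loss": ConsequenceClass.LOF,
    "start site lost": ConsequenceClass.LOF,
    "splice-site variant": ConsequenceClass.LOF,
    "splice-acceptor variant": ConsequenceClass.LOF,
    "splice-donor variant": ConsequenceClass.LOF,
    "in-frame deletion": ConsequenceClass.INFRAME_INDEL,
    "in-frame insertion": ConsequenceClass.INFRAME_INDEL,
    "missense": ConsequenceClass.MISSENSE,
    "missense variant": ConsequenceClass.MISSENSE,
}


def harmonise_consequence(label: str) -> ConsequenceClass:
    """Map a published free-text consequence label to a class."""
    cls = _LABEL_CLASS.get(label.strip().lower())
    if cls is None:
        logger.warning("unrecognised consequence label %r treated as OTHER", label)
        return ConsequenceClass.OTHER
    return cls


@dataclass(frozen=True)
class ReferencePanel:
    """LoF carrier count for the target gene in a reference population."""

    name: str
    carriers: int
    size: int

    def __post_init__(self) -> None:
        if not (0 <= self.carriers <= self.size):
            raise ValueError(
                f"panel {self.name}: carriers {self.carriers} outside [0, {self.size}]"
            )


def aggregate_carriers(
    records: pd.DataFrame,
    gene: str,
    total_probands: int,
    exclusions: list[str] | None = None,
) -> tuple[int, int]:
    """Count distinct probands carrying a LoF variant of ``gene``.

    ``records`` is the study-records table (columns study, patient_id,
    gene, variant, consequence, optionally excluded/exclusion_reason).
    Variants listed in ``exclusions``, or rows flagged excluded in the
    table, do not count. Duplicate (study, patient, variant) rows
    collapse with a warning; a proband with several qualifying variants
    counts once. Returns (carriers, total_probands).
    """
    exclusions = set(exclusions or [])
    df = records[records["gene"] == gene].copy()
    dup = df.duplicated(subset=["study", "patient_id", "variant"])
    if dup.any():
        logger.warning("%d duplicate study/patient/variant rows collapsed", dup.sum())
        df = df[~dup]
    if total_probands < df["patient_id"].nunique():
        raise ValueError(
            f"total_probands={total_probands} smaller than the "
            f"{df['patient_id'].nunique()} distinct probands on record"
        )
    carriers: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        if row["variant"] in exclusions:
            continue
        if str(row.get("excluded", "")).strip().lower() in ("1", "true", "yes"):
            continue
        if harmonise_consequence(row["consequence"]) is not ConsequenceClass.LOF:
            continue
        carriers.add((row["study"], row["patient_id"]))
    return len(carriers), total_probands


def carrier_enrichment(
    case_carriers: int,
    case_n: int,
    panel: ReferencePanel,
    unit: str = "allele",
) -> float:
    """One-tailed Fisher p for LoF enrichment against a reference panel.

    ``unit='allele'`` draws denominators from chromosomes (2N per
    cohort, one counted allele per carrier); ``unit='carrier'`` uses
    individuals. Carriers are assumed heterozygous for the rare LoF
    alleles considered here.
    """
    if case_carriers > case_n:
        raise ValueError("case carriers exceed cohort size")
    if unit == "allele":
        table = ContingencyTable2x2(
            a=case_carriers, b=2 * case_n - case_carriers,
            c=panel.carriers, d=2 * panel.size - panel.carriers,
        )
    elif unit == "carrier":
        table = ContingencyTable2x2(
            a=case_carriers, b=case_n - case_carriers,
            c=panel.carriers, d=panel.size - panel.carriers,
        )
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return fisher_one_tailed_greater(table)


@dataclass
class MetaReport:
    gene: str
    carriers_aggregated: int
    carriers_published: int | None
    total_probands: int
    rows: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def run_meta_analysis(
    records: pd.DataFrame,
    gene: str,
    total_probands: int,
    panels: list[ReferencePanel],
    exclusions: list[str] | None = None,
    published_carriers: int | None = None,
    unit: str = "allele",
) -> MetaReport:
    """Aggregate carriers and test enrichment against each panel.

    When the published carrier count differs from the aggregate over the
    records table, both are reported, the discrepancy is flagged, and
    the published count drives the headline p-values (printed counts
    are treated as the study's bookkeeping of record).
    """
    agg, n = aggregate_carriers(records, gene, total_probands, exclusions)
    report = MetaReport(
        gene=gene,
        carriers_aggregated=agg,
        carriers_published=published_carriers,
        total_probands=n,
    )
    headline = agg if published_carriers is None else published_carriers
    if published_carriers is not None and published_carriers != agg:
        report.notes.append(
            f"published carrier count ({published_carriers}) differs from the "
            f"aggregate over the records table ({agg}); published count used "
            "for the headline test"
        )
    for panel in panels:
        p = carrier_enrichment(headline, n, panel, unit=unit)
        report.rows.append(
            {
                "gene": gene,
                "carriers": headline,
                "probands": n,
                "panel": panel.name,
                "panel_carriers": panel.carriers,
                "panel_size": panel.size,
                "unit": unit,
                "p_one_tailed": p,
            }
        )
    return report
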