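"""Gene-level collapsing of filtered variants.

Filtered variants are partitioned by gene symbol; genes are then
selected for containing at least one loss-of-function variant, the most
variable genes (by count of rare protein-affecting variants) are
excluded as hypervariable, variant occurrences are deduplicated to one
per affected family, and candidate variants are checked for segregation
with phenotype within each family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .variants import AnnotatedVariant, CohortDesign, ConsequenceClass

logger = logging.getLogger(__name__)

#: Bucket for variants whose annotation carries no gene symbol; excluded
#: from all downstream gene-level analyses.
UNASSIGNED = "__unassigned__"


@dataclass
class GeneVariantTable:
    """Partition of filtered variants by gene symbol."""

    entries: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [g for g in self.entries if g != UNASSIGNED]

    def lof_flag(self, gene: str) -> bool:
        return any(
            v.consequence is ConsequenceClass.LOF for v in self.entries.get(gene, [])
        )

    def variability_count(self, gene: str) -> int:
        return len(self.entries.get(gene, []))

    @property
    def n_variants(self) -> int:
        return sum(len(vs) for vs in self.entries.values())


def aggregate_by_gene(variants: Iterable[AnnotatedVariant]) -> GeneVariantTable:
    """Partition variants by gene; symbol-less variants go to a sentinel
    bucket that downstream selection ignores."""
    table = GeneVariantTable()
    for v in variants:
        gene = v.gene if v.gene else UNASSIGNED
        table.entries.setdefault(gene, []).append(v)
    return table


def exclude_hypervariable(
    table: GeneVariantTable, fraction: float = 0.01
) -> tuple[list[str], list[str]]:
    """Drop the top ``fraction`` of genes by rare protein-affecting
    variant count.

    The cut removes ceil(fraction * G) genes; genes tied with the last
    excluded rank are all excluded. Returns (kept, excluded), each
    sorted alphabetically.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    genes = table.genes
    if not genes:
        raise ValueError("empty gene table")
    n_excl = math.ceil(fraction * len(genes))
    if n_excl == 0:
        return sorted(genes), []
    ranked = sorted(genes, key=lambda g: (-table.variability_count(g), g))
    cut_count = table.variability_count(ranked[n_excl - 1])
    excluded = [g for g in genes if table.variability_count(g) >= cut_count]
    if len(excluded) == len(genes):
        logger.warning(
            "all %d genes tied at the hypervariable cut; whole tie group excluded",
            len(genes),
        )
    elif len(excluded) > n_excl:
        logger.info(
            "hypervariable tie at count %d expanded exclusion from %d to %d genes",
            cut_count, n_excl, len(excluded),
        )
    excluded_set = set(excluded)
    kept = sorted(g for g in genes if g not in excluded_set)
    return kept, sorted(excluded)


def select_lof_genes(
    table: GeneVariantTable, within: Iterable[str] | None = None
) -> list[str]:
    """Genes containing at least one loss-of-function variant, sorted;
    optionally restricted to ``within`` (e.g. post-exclusion survivors)."""
    pool = table.genes if within is None else [g for g in within if g != UNASSIGNED]
    return sorted(g for g in pool if table.lof_flag(g))


def family_dedup_counts(
    variants: Iterable[AnnotatedVariant], design: CohortDesign
) -> dict[tuple[str, int, str, str], int]:
    """Per-variant count of families with >=1 affected carrier.

    Multiple affected carriers within one family contribute a single
    occurrence, matching per-family deduplication of shared haplotypes.
    """
    fam_of = {s.sample_id: s.family_id for s in design.samples}
    affected = set(design.affected_ids)
    out: dict[tuple[str, int, str, str], int] = {}
    for v in variants:
        fams = {
            fam_of[s]
            for s, g in v.genotypes.items()
            if g is not None and g >= 1 and s in affected
        }
        out[v.key] = len(fams)
    return out


class Segregation(Enum):
    SEGREGATES = "segregates"
    FAILS = "fails"
    UNINFORMATIVE = "uninformative"


def segregation_check(
    v: AnnotatedVariant, family_members: Sequence[str], design: CohortDesign
) -> Segregation:
    """Does a candidate variant track with disease within one family?

    Segregates iff every sequenced affected member carries the variant.
    Unaffected carriers are compatible (incomplete penetrance), so they
    never cause failure. A family with a single sequenced member is
    uninformative.
    """
    members = list(family_members)
    if len(members) <= 1:
        return Segregation.UNINFORMATIVE
    affected = [m for m in members if design.status(m)]
    if not affected:
        return Segregation.UNINFORMATIVE
    for m in affected:
        g = v.genotypes.get(m)
        if g is None or g == 0:
            return Segregation.FAILS
    return Segregation.SEGREGATES
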