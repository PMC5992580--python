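"""Interaction-network clustering and gene-set burden testing.

Candidate genes are grouped into clusters of physically interacting
genes (connected components of the induced subgraph, size >= 5 by
default). Each cluster is annotated with the most significant Gene
Ontology term of 10-200 genes under a Bonferroni-corrected
hypergeometric over-representation test. Loss-of-function burden within
a selected term is then compared between the family cohort
(family-deduplicated occurrences) and an external control cohort with a
one-tailed Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genes import GeneVariantTable, family_dedup_counts
from .stats import (
    ContingencyTable2x2,
    bonferroni_adjust,
    fisher_one_tailed_greater,
    hypergeom_sf_ge,
)
from .variants import AnnotatedVariant, CohortDesign, ConsequenceClass

logger = logging.getLogger(__name__)


def build_network(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Undirected gene-interaction graph; self-loops dropped."""
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    return g


@dataclass(frozen=True)
class GeneCluster:
    """A connected set of physically interacting candidate genes."""

    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"GO term {self.id} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


def terms_from_gmt(gmt: Mapping[str, tuple[str, frozenset[str]]]) -> list[GoTerm]:
    return [GoTerm(tid, name, genes) for tid, (name, genes) in sorted(gmt.items())]


def find_clusters(
    net: nx.Graph, candidates: Sequence[str], min_size: int = 5
) -> list[GeneCluster]:
    """Connected components of the candidate-induced subgraph, filtered
    to ``min_size`` and ordered by size (desc) then first member."""
    if not candidates:
        raise ValueError("candidate gene list is empty")
    present = [g for g in candidates if g in net]
    sub = net.subgraph(present)
    clusters = [
        GeneCluster(members=frozenset(comp))
        for comp in nx.connected_components(sub)
        if len(comp) >= min_size
    ]
    clusters.sort(key=lambda c: (-c.size, c.sorted_members()[0]))
    return clusters


def over_representation_test(
    cluster: GeneCluster, term: GoTerm, background: frozenset[str] | set[str]
) -> float:
    """Upper-tail hypergeometric p for the cluster/term overlap.

    Draws of size |cluster| from the background; successes are the
    term's genes within the background.
    """
    background = frozenset(background)
    if not cluster.members <= background:
        raise ValueError("cluster genes must be a subset of the background")
    k = len(cluster.members & term.genes)
    K = len(term.genes & background)
    return hypergeom_sf_ge(k, N=len(background), K=K, n=cluster.size)


@dataclass(frozen=True)
class TermAssignment:
    term: GoTerm
    raw_p: float
    adjusted_p: float


def assign_term(
    cluster: GeneCluster,
    terms: Sequence[GoTerm],
    background: frozenset[str] | set[str],
    alpha: float = 0.05,
    min_genes: int = 10,
    max_genes: int = 200,
    bonferroni_m: int | None = None,
) -> TermAssignment | None:
    """Pick the cluster's most significant GO term within the size window.

    All supplied terms are tested and Bonferroni-adjusted together
    (``bonferroni_m`` overrides the family size, e.g. to count only
    terms with nonzero overlap); among window-sized terms with adjusted
    p < alpha the smallest adjusted p wins, ties broken by smaller term
    then lexicographic id. Returns None when nothing qualifies.
    """
    if not terms:
        raise ValueError("no terms supplied")
    raw = [over_representation_test(cluster, t, background) for t in terms]
    adjusted = bonferroni_adjust(raw, m=bonferroni_m)
    best: tuple[float, int, str] | None = None
    best_idx: int | None = None
    for i, term in enumerate(terms):
        if not (min_genes <= term.size <= max_genes):
            continue
        if adjusted[i] >= alpha:
            continue
        key = (adjusted[i], term.size, term.id)
        if best is None or key < best:
            best = key
            best_idx = i
    if best_idx is None:
        return None
    return TermAssignment(
        term=terms[best_idx], raw_p=raw[best_idx], adjusted_p=adjusted[best_idx]
    )


@dataclass(frozen=True)
class TermBurdenResult:
    term: GoTerm
    table: ContingencyTable2x2
    p: float
    case_count: int
    control_count: int
    mode: str


def _case_lof_dedup_count(
    variants: Iterable[AnnotatedVariant],
    design: CohortDesign,
    genes: frozenset[str] | None,
) -> int:
    """Family-deduplicated LoF occurrence count, optionally gene-restricted."""
    pool = [
        v
        for v in variants
        if v.consequence is ConsequenceClass.LOF
        and (genes is None or v.gene in genes)
    ]
    return sum(family_dedup_counts(pool, design).values())


def term_burden_test(
    term: GoTerm,
    case_variants: Sequence[AnnotatedVariant],
    design: CohortDesign,
    control_counts: Mapping[str, int],
    control_size: int,
    mode: str = "proportion_of_burden",
    gene_universe: frozenset[str] | None = None,
) -> TermBurdenResult:
    """One-tailed burden comparison of a GO term between cohorts.

    Case occurrences are family-deduplicated LoF counts over every
    filtered gene annotated to the term (clustered or not); control
    occurrences are aggregated control-cohort LoF allele counts over the
    same genes. In ``proportion_of_burden`` mode the 2x2 is
    [in-term, out-of-term] x [cases, controls], each cohort's total
    filtered LoF count supplying the denominator; ``carrier`` mode uses
    [count, 2 * cohort size - count] per cohort. ``gene_universe``, when
    given, restricts both cohorts' totals (e.g. to the
    post-hypervariable-exclusion gene set).
    """
    if mode not in ("proportion_of_burden", "carrier"):
        raise ValueError(f"unknown burden mode {mode!r}")
    term_genes = term.genes if gene_universe is None else term.genes & gene_universe
    case_in = _case_lof_dedup_count(case_variants, design, term_genes)
    case_total = _case_lof_dedup_count(case_variants, design, gene_universe)
    ctrl_in = sum(
        c for g, c in control_counts.items() if g in term_genes
    )
    ctrl_total = sum(
        c
        for g, c in control_counts.items()
        if gene_universe is None or g in gene_universe
    )
    if mode == "proportion_of_burden":
        if case_total == 0 or ctrl_total == 0:
            raise ValueError(
                "burden test needs nonzero total filtered LoF counts in both "
                f"cohorts (cases={case_total}, controls={ctrl_total})"
            )
        table = ContingencyTable2x2(
            a=case_in, b=case_total - case_in, c=ctrl_in, d=ctrl_total - ctrl_in
        )
    else:
        n_case_chrom = 2 * len(design.samples)
        n_ctrl_chrom = 2 * control_size
        if case_in > n_case_chrom or ctrl_in > n_ctrl_chrom:
            raise ValueError("counts exceed chromosome totals in carrier mode")
        table = ContingencyTable2x2(
            a=case_in, b=n_case_chrom - case_in,
            c=ctrl_in, d=n_ctrl_chrom - ctrl_in,
        )
    return TermBurdenResult(
        term=term,
        table=table,
        p=fisher_one_tailed_greater(table),
        case_count=case_in,
        control_count=ctrl_in,
        mode=mode,
    )
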