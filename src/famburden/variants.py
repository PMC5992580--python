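"""Variant-level domain model and the candidate-variant filters.

A variant enters the pipeline as one alt allele at one site, annotated
with a gene symbol, a Sequence Ontology consequence, SIFT/PolyPhen
classes and a European reference allele frequency, plus per-sample
genotype allele counts. Filtering keeps variants that are rare in the
reference panel (AF < 0.05 by default), protein-affecting
(loss-of-function, qualifying missense, or in-frame indel), and carried
by at least one affected cohort member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "ConsequenceClass",
    "AnnotatedVariant",
    "CohortDesign",
    "FilterConfig",
    "FilterLog",
    "classify_consequence",
    "is_protein_affecting",
    "filter_cohort",
]


class ConsequenceClass(Enum):
    """Functional class of a variant, ordered by decreasing severity."""

    LOF = "LOF"
    MISSENSE = "MISSENSE"
    INFRAME_INDEL = "INFRAME_INDEL"
    OTHER = "OTHER"


# Severity rank for multi-term annotations: the worst class wins.
_SEVERITY = {
    ConsequenceClass.LOF: 0,
    ConsequenceClass.MISSENSE: 1,
    ConsequenceClass.INFRAME_INDEL: 2,
    ConsequenceClass.OTHER: 3,
}

# Sequence Ontology terms mapped to classes. LoF is exactly the six
# protein-truncating categories: stop gained/lost, start lost, splice
# acceptor/donor, frameshift.
_SO_CLASS = {
    "stop_gained": ConsequenceClass.LOF,
    "stop_lost": ConsequenceClass.LOF,
    "start_lost": ConsequenceClass.LOF,
    "splice_acceptor_variant": ConsequenceClass.LOF,
    "splice_donor_variant": ConsequenceClass.LOF,
    "frameshift_variant": ConsequenceClass.LOF,
    "missense_variant": ConsequenceClass.MISSENSE,
    "inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "inframe_deletion": ConsequenceClass.INFRAME_INDEL,
}

_unknown_terms_seen: set[str] = set()


def classify_consequence(raw_term: str) -> ConsequenceClass:
    """Map a Sequence-Ontology-style consequence string to a class.

    Multi-term annotations (``&``- or ``,``-separated, VEP style) take
    the most severe class. Unknown terms map to OTHER and are logged
    once each.
    """
    if not raw_term:
        raise ValueError("empty consequence term")
    terms = [t for part in raw_term.split("&") for t in part.split(",") if t]
    best = ConsequenceClass.OTHER
    for term in terms:
        cls = _SO_CLASS.get(term.strip())
        if cls is None:
            cls = ConsequenceClass.OTHER
            if term not in _unknown_terms_seen:
                _unknown_terms_seen.add(term)
                logger.debug("unknown consequence term %r mapped to OTHER", term)
        if _SEVERITY[cls] < _SEVERITY[best]:
            best = cls
    return best


@dataclass
class AnnotatedVariant:
    """One alt allele at a site with annotations and genotypes.

    ``genotypes`` maps sample id -> alt allele count in {0, 1, 2}; a
    value of ``None`` marks a missing call. Samples absent from the
    mapping are treated as homozygous reference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    raw_consequence: str
    consequence: ConsequenceClass
    sift: str = "unknown"  # deleterious | tolerated | unknown
    polyphen: str = "unknown"  # probably_damaging | possibly_damaging | benign | unknown
    control_af: float | None = None
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.control_af is not None and not (0.0 <= self.control_af <= 1.0):
            raise ValueError(f"control_af out of [0,1]: {self.control_af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        """Sample ids with at least one alt allele (observed calls only)."""
        return [s for s, g in self.genotypes.items() if g is not None and g >= 1]

    def allele_count(self, samples: Iterable[str] | None = None) -> int:
        if samples is None:
            return sum(g for g in self.genotypes.values() if g)
        return sum(
            g for s in samples if (g := self.genotypes.get(s)) is not None and g
        )


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: str
    affected: bool


@dataclass
class CohortDesign:
    """Sequenced samples grouped into families with affection status."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in cohort design")
        if not any(s.affected for s in self.samples):
            raise ValueError("cohort must contain at least one affected sample")

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for s in self.samples:
            fams.setdefault(s.family_id, []).append(s.sample_id)
        return fams

    @property
    def affected_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.affected]

    @property
    def unaffected_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.affected]

    def status(self, sample_id: str) -> bool:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.affected
        raise KeyError(sample_id)

    def affected_in_family(self, family_id: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.family_id == family_id and s.affected
        ]


@dataclass
class FilterConfig:
    """Knobs for the variant-level filters.

    max_control_af: rarity threshold on the reference-panel allele
        frequency (strict ``<``).
    missense_rule: "both" requires SIFT deleterious AND PolyPhen
        damaging; "either" accepts one of the two.
    possibly_damaging_counts: whether PolyPhen "possibly_damaging"
        qualifies as damaging.
    keep_inframe: retain in-frame indels as protein-affecting.
    unknown_af_passes: variants absent from the reference panel pass the
        rarity filter (absence implies rarity).
    missing_prediction_fails: missense with an unknown SIFT/PolyPhen
        prediction fails that predictor (conservative default).
    """

    max_control_af: float = 0.05
    missense_rule: str = "both"  # both | either
    possibly_damaging_counts: bool = True
    keep_inframe: bool = True
    unknown_af_passes: bool = True
    missing_prediction_fails: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.max_control_af <= 1.0):
            raise ValueError("max_control_af must be in (0, 1]")
        if self.missense_rule not in ("both", "either"):
            raise ValueError("missense_rule must be 'both' or 'either'")


@dataclass
class FilterLog:
    """Per-rule removal accounting for one filter_cohort run."""

    n_input: int = 0
    n_all_missing: int = 0
    n_common: int = 0
    n_not_protein_affecting: int = 0
    n_no_affected_carrier: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _sift_deleterious(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.sift == "deleterious":
        return True
    if v.sift == "unknown" and not cfg.missing_prediction_fails:
        return True
    return False


def _polyphen_damaging(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.polyphen == "probably_damaging":
        return True
    if v.polyphen == "possibly_damaging" and cfg.possibly_damaging_counts:
        return True
    if v.polyphen == "unknown" and not cfg.missing_prediction_fails:
        return True
    return False


def is_protein_affecting(v: AnnotatedVariant, cfg: FilterConfig | None = None) -> bool:
    """True for LoF, qualifying missense, or (optionally) in-frame indels."""
    cfg = cfg or FilterConfig()
    if v.consequence is ConsequenceClass.LOF:
        return True
    if v.consequence is ConsequenceClass.INFRAME_INDEL:
        return cfg.keep_inframe
    if v.consequence is ConsequenceClass.MISSENSE:
        sift_ok = _sift_deleterious(v, cfg)
        poly_ok = _polyphen_damaging(v, cfg)
        return (sift_ok and poly_ok) if cfg.missense_rule == "both" else (sift_ok or poly_ok)
    return False


def _is_rare(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.control_af is None:
        return cfg.unknown_af_passes
    return v.control_af < cfg.max_control_af


def filter_cohort(
    variants: Iterable[AnnotatedVariant],
    design: CohortDesign,
    cfg: FilterConfig | None = None,
    log: FilterLog | None = None,
) -> list[AnnotatedVariant]:
    """Apply the three variant-level filters, preserving input order.

    A variant is kept iff it is (i) rare in the reference panel,
    (ii) protein-affecting, and (iii) carried by at least one affected
    sample. Variants with all genotypes missing are dropped with a
    warning. ``log``, when given, accumulates per-rule removal counts.
    """
    cfg = cfg or FilterConfig()
    log = log if log is not None else FilterLog()
    affected = set(design.affected_ids)
    kept: list[AnnotatedVariant] = []
    for v in variants:
        log.n_input += 1
        observed = [g for g in v.genotypes.values() if g is not None]
        if v.genotypes and not observed:
            logger.warning(
                "variant %s:%d %s>%s has no observed genotypes; dropped",
                v.chrom, v.pos, v.ref, v.alt,
            )
            log.n_all_missing += 1
            continue
        if not _is_rare(v, cfg):
            log.n_common += 1
            continue
        if not is_protein_affecting(v, cfg):
            log.n_not_protein_affecting += 1
            continue
        if not any(
            (g := v.genotypes.get(s)) is not None and g >= 1 for s in affected
        ):
            log.n_no_affected_carrier += 1
            continue
        kept.append(v)
    log.n_retained += len(kept)
    return kept
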