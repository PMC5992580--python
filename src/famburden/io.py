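"""Readers and writers for the pipeline's file formats.

VCF parsing goes through pysam; everything else is plain TSV/GMT text.
Multi-allelic VCF records are decomposed into one AnnotatedVariant per
alt allele, with per-allele annotation matching.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .variants import (
    AnnotatedVariant,
    CohortDesign,
    Sample,
    classify_consequence,
)

logger = logging.getLogger(__name__)

DEFAULT_CSQ_FORMAT = "SYMBOL|Consequence|SIFT|PolyPhen|EUR_AF"

_SIFT_LABELS = {"deleterious", "tolerated"}
_POLYPHEN_LABELS = {"probably_damaging", "possibly_damaging", "benign"}


def _strip_score(label: str) -> str:
    """VEP writes e.g. 'deleterious(0.01)'; keep the categorical part."""
    return label.split("(")[0].strip()


def _parse_sift(raw: str) -> str:
    lab = _strip_score(raw).lower()
    return lab if lab in _SIFT_LABELS else "unknown"


def _parse_polyphen(raw: str) -> str:
    lab = _strip_score(raw).lower()
    return lab if lab in _POLYPHEN_LABELS else "unknown"


def _parse_af(raw: str) -> float | None:
    raw = raw.strip()
    if raw in ("", ".", "NA"):
        return None
    return float(raw)


def read_pedigree(path: str | Path) -> list[tuple[str, str, str, str, str, str]]:
    """Read a 6-column PED file; returns raw rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line has <6 columns: {line!r}")
            rows.append(tuple(parts[:6]))
    return rows


def cohort_from_ped(
    path: str | Path, vcf_samples: Iterable[str] | None = None
) -> CohortDesign:
    """Build a CohortDesign from a PED file.

    Phenotype 2 = affected, 1 = unaffected; rows with phenotype 0/-9
    (e.g. unsequenced founders) are skipped. When ``vcf_samples`` is
    given, only individuals present in the VCF are kept.
    """
    keep = set(vcf_samples) if vcf_samples is not None else None
    samples = []
    for fam, ind, _father, _mother, _sex, pheno in read_pedigree(path):
        if pheno not in ("1", "2"):
            continue
        if keep is not None and ind not in keep:
            continue
        samples.append(Sample(sample_id=ind, family_id=fam, affected=pheno == "2"))
    return CohortDesign(samples=samples)


@dataclass
class CsqSpec:
    """Declared sub-field order of the CSQ annotation string."""

    fields: list[str]

    @classmethod
    def from_format(cls, fmt: str = DEFAULT_CSQ_FORMAT) -> "CsqSpec":
        return cls(fields=[f.strip() for f in fmt.split("|")])

    def index(self, name: str) -> int | None:
        try:
            return self.fields.index(name)
        except ValueError:
            return None


def _match_csq_entries(
    entries: list[list[str]], alts: tuple[str, ...], spec: CsqSpec
) -> dict[int, list[str]]:
    """Assign one CSQ entry per alt-allele index.

    With a declared Allele field, match on it; otherwise entries are
    taken in alt order when the counts agree, and a single entry is
    applied to every alt.
    """
    out: dict[int, list[str]] = {}
    ai = spec.index("Allele")
    if ai is not None:
        for i, alt in enumerate(alts):
            for e in entries:
                if len(e) > ai and e[ai] == alt:
                    out[i] = e
                    break
        if out:
            return out
    if len(entries) == len(alts):
        return {i: e for i, e in enumerate(entries)}
    if len(entries) == 1:
        if len(alts) > 1:
            logger.warning("single CSQ entry applied to %d alt alleles", len(alts))
        return {i: entries[0] for i in range(len(alts))}
    return {i: entries[min(i, len(entries) - 1)] for i in range(len(alts))}


def read_annotated_vcf(
    path: str | Path, csq_format: str = DEFAULT_CSQ_FORMAT
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Parse an annotated VCF into AnnotatedVariants plus the sample list.

    Each alt allele of a multi-allelic record becomes its own variant;
    genotype allele counts are taken per alt allele, counting observed
    alleles only for half-missing calls.
    """
    spec = CsqSpec.from_format(csq_format)
    idx = {name: spec.index(name) for name in
           ("SYMBOL", "Consequence", "SIFT", "PolyPhen", "EUR_AF")}
    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if not alts:
                continue
            raw_csq = rec.info.get("CSQ")
            if raw_csq is None:
                entries: list[list[str]] = []
            elif isinstance(raw_csq, tuple):
                entries = [e.split("|") for e in raw_csq]
            else:
                entries = [raw_csq.split("|")]
            matched = _match_csq_entries(entries, alts, spec) if entries else {}
            for ai, alt in enumerate(alts):
                entry = matched.get(ai, [])

                def fld(name: str) -> str:
                    j = idx[name]
                    return entry[j] if j is not None and j < len(entry) else ""

                genotypes: dict[str, int | None] = {}
                alt_code = ai + 1
                for sid in sample_ids:
                    gt = rec.samples[sid].get("GT")
                    if gt is None or all(a is None for a in gt):
                        genotypes[sid] = None
                        continue
                    genotypes[sid] = sum(1 for a in gt if a == alt_code)
                raw_cons = fld("Consequence") or "unknown"
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=fld("SYMBOL"),
                        raw_consequence=raw_cons,
                        consequence=classify_consequence(raw_cons),
                        sift=_parse_sift(fld("SIFT")),
                        polyphen=_parse_polyphen(fld("PolyPhen")),
                        control_af=_parse_af(fld("EUR_AF")),
                        genotypes=genotypes,
                    )
                )
    return variants, sample_ids


def write_variant_table(
    variants: Iterable[AnnotatedVariant], design: CohortDesign, path: str | Path
) -> pd.DataFrame:
    """Write the filtered-variant TSV report and return it as a frame."""
    affected = set(design.affected_ids)
    unaffected = set(design.unaffected_ids)
    rows = []
    for v in variants:
        carriers = set(v.carriers())
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "class": v.consequence.value,
                "sift": v.sift,
                "polyphen": v.polyphen,
                "control_af": "" if v.control_af is None else v.control_af,
                "affected_carriers": len(carriers & affected),
                "unaffected_carriers": len(carriers & unaffected),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "class", "sift",
            "polyphen", "control_af", "affected_carriers", "unaffected_carriers",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-symbol-column TSV edge list; extra columns (weights) ignored."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"edge line has <2 columns: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if a and b and a != b:
                edges.append((a, b))
    return edges


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT gene-set file: term id -> (name, gene set)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs id, name, >=1 gene: {line!r}")
            tid, name = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"GMT term {tid} has no genes")
            terms[tid] = (name, genes)
    return terms


def read_control_counts(path: str | Path) -> tuple[dict[str, int], int]:
    """Control-cohort aggregated LoF table: gene, allele_count, cohort_size.

    Returns (per-gene allele counts, cohort size). The cohort size must
    be constant across rows.
    """
    counts: dict[str, int] = {}
    sizes: set[int] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            counts[row["gene"]] = counts.get(row["gene"], 0) + int(row["allele_count"])
            sizes.add(int(row["cohort_size"]))
    if len(sizes) != 1:
        raise ValueError(f"control table must declare one cohort size, got {sizes}")
    return counts, sizes.pop()


def read_study_records(path: str | Path) -> pd.DataFrame:
    """Published proband-level carrier records (one row per report)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"study", "patient_id", "gene", "variant", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study records missing columns: {sorted(missing)}")
    return df
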