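"""Synthetic family-cohort generator with known planted structure.

Everything the pipeline consumes can be simulated: an annotated
multi-sample VCF plus pedigree for a 22-family cohort (28 affected, 11
unaffected by default), an aggregated control-panel LoF table standing
in for a 503-individual European reference sample, a sparse physical
interaction network with a planted clique, and GO-style gene-set
annotations containing a planted term plus decoys.

Each family consists of two unsequenced founders and their sequenced
children. Rare variants arise on founder haplotypes (one new private
variant per draw) and drop through the pedigree by fair Mendelian
transmission, so within-family sharing, segregation successes and
failures, and unaffected-only carriers all occur naturally. The planted
effect multiplies the founder loss-of-function rate in the planted term
genes; at multiplier 1 the planted genes are statistically identical to
background, giving an exact null for calibration runs.

A TruthLedger records the planted structure and, independently of the
analysis code, the per-variant family-deduplicated affected-carrier
counts implied by the emitted genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .variants import (
    AnnotatedVariant,
    CohortDesign,
    Sample,
    classify_consequence,
)

#: Sequenced (affected, unaffected) members per family, mirroring a
#: 22-family gastric-cancer cohort with 28 affected and 11 unaffected.
DEFAULT_FAMILY_STRUCTURE: tuple[tuple[int, int], ...] = (
    (2, 0), (2, 4), (1, 0), (1, 2), (1, 0), (1, 0), (2, 0), (1, 0),
    (1, 0), (1, 2), (4, 1), (1, 0), (1, 0), (1, 0), (1, 0), (1, 0),
    (1, 0), (1, 0), (1, 1), (1, 0), (1, 1), (1, 0),
)

_LOF_TERMS = (
    "stop_gained", "frameshift_variant", "splice_acceptor_variant",
    "splice_donor_variant", "stop_lost", "start_lost",
)
_REF_ALT = {
    "stop_gained": ("C", "T"),
    "frameshift_variant": ("CA", "C"),
    "splice_acceptor_variant": ("A", "G"),
    "splice_donor_variant": ("G", "T"),
    "stop_lost": ("T", "C"),
    "start_lost": ("A", "C"),
    "missense_variant": ("G", "A"),
    "synonymous_variant": ("T", "C"),
    "inframe_deletion": ("CTTT", "C"),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Rates are per-haplotype per-gene probabilities of a new rare variant
    arising on a founder chromosome; an individual's carrier probability
    is roughly twice the haplotype rate.
    """

    family_structure: tuple[tuple[int, int], ...] = DEFAULT_FAMILY_STRUCTURE
    n_control: int = 503
    n_genes: int = 1000
    background_lof_rate: float = 0.01
    missense_damaging_rate: float = 0.01
    missense_benign_rate: float = 0.01
    synonymous_rate: float = 0.005
    n_common_variants: int = 30
    n_hypervariable_genes: int = 10
    hypervariable_multiplier: float = 15.0
    planted_term_genes: int = 20
    planted_clique: int = 8
    planted_rate_multiplier: float = 8.0
    n_random_edges: int = 800
    n_decoy_terms: int = 40
    missing_call_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_lof_rate", "missense_damaging_rate",
                     "missense_benign_rate", "synonymous_rate",
                     "missing_call_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {r}")
        if self.background_lof_rate * self.planted_rate_multiplier > 1.0:
            raise ValueError("planted LoF rate exceeds 1")
        if self.planted_clique > self.planted_term_genes:
            raise ValueError("clique larger than the planted term")
        if self.planted_term_genes + self.n_hypervariable_genes > self.n_genes:
            raise ValueError("planted and hypervariable genes exceed the universe")
        if not self.family_structure:
            raise ValueError("family structure is empty")
        if not any(a > 0 for a, _u in self.family_structure):
            raise ValueError("cohort needs at least one affected individual")

    @property
    def n_families(self) -> int:
        return len(self.family_structure)

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def planted_genes(self) -> list[str]:
        return self.genes[: self.planted_term_genes]

    @property
    def clique_genes(self) -> list[str]:
        return self.genes[: self.planted_clique]

    @property
    def hypervariable_genes(self) -> list[str]:
        return self.genes[self.n_genes - self.n_hypervariable_genes:]

    @property
    def planted_term_id(self) -> str:
        return "GO:9990001"


@dataclass
class TruthLedger:
    """Generator-side record of the planted structure."""

    planted_term_id: str
    planted_genes: list[str]
    clique_genes: list[str]
    hypervariable_genes: list[str]
    provenance: dict[str, str] = field(default_factory=dict)
    expected_family_dedup: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _gene_site(gene_index: int, counter: int) -> tuple[str, int]:
    chrom = str((gene_index % 22) + 1)
    base = 1_000_000 + (gene_index // 22) * 200_000
    return chrom, base + counter * 10


def _variant_key_str(v: AnnotatedVariant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


class _CohortBuilder:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.gene_names = cfg.genes
        self.site_counter = np.zeros(cfg.n_genes, dtype=int)
        self.variants: list[AnnotatedVariant] = []
        self.provenance: dict[str, str] = {}
        self.samples: list[Sample] = []
        self.family_children: dict[str, list[str]] = {}

    def build_design(self) -> CohortDesign:
        for fi, (n_aff, n_un) in enumerate(self.cfg.family_structure):
            fam = f"F{fi + 1:02d}"
            children = [f"{fam}_A{j + 1}" for j in range(n_aff)]
            children += [f"{fam}_U{j + 1}" for j in range(n_un)]
            self.family_children[fam] = children
            for c in children:
                self.samples.append(
                    Sample(sample_id=c, family_id=fam, affected="_A" in c)
                )
        return CohortDesign(samples=list(self.samples))

    def _new_variant(
        self, gene_index: int, so_term: str, sift: str, polyphen: str,
        control_af: float | None, genotypes: dict[str, int | None],
        provenance: str,
    ) -> AnnotatedVariant:
        chrom, pos = _gene_site(gene_index, int(self.site_counter[gene_index]))
        self.site_counter[gene_index] += 1
        ref, alt = _REF_ALT[so_term]
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=self.gene_names[gene_index],
            raw_consequence=so_term,
            consequence=classify_consequence(so_term),
            sift=sift, polyphen=polyphen,
            control_af=control_af, genotypes=genotypes,
        )
        self.variants.append(v)
        self.provenance[_variant_key_str(v)] = provenance
        return v

    def _background_af(self, u: float, x: float) -> float | None:
        """Mixture straddling the rarity threshold: mostly rare, some
        common (caught by the AF filter), some absent from the panel."""
        if u < 0.6:
            return round(0.05 * x, 6)
        if u < 0.8:
            return round(0.05 + 0.25 * x, 6)
        return None

    def _per_gene_rates(self, base: float, planted_boost: bool,
                        hyper_boost: bool) -> np.ndarray:
        cfg = self.cfg
        rates = np.full(cfg.n_genes, base)
        if planted_boost:
            rates[: cfg.planted_term_genes] *= cfg.planted_rate_multiplier
        if hyper_boost:
            rates[cfg.n_genes - cfg.n_hypervariable_genes:] *= (
                cfg.hypervariable_multiplier
            )
        return np.clip(rates, 0.0, 1.0)

    def add_rare_class(self, so_pool: tuple[str, ...] | str, rates: np.ndarray,
                       sift: str, polyphen: str, provenance: str,
                       af_near_zero_for_planted: bool = False) -> None:
        cfg = self.cfg
        for fam, children in self.family_children.items():
            hits = self.rng.random((4, cfg.n_genes)) < rates[None, :]
            gene_idx = np.nonzero(hits)[1]
            m = len(gene_idx)
            if m == 0:
                continue
            # fair Mendelian drop of each founder allele to the children
            transmitted = self.rng.random((m, len(children))) < 0.5
            so_idx = (np.zeros(m, dtype=int) if isinstance(so_pool, str)
                      else self.rng.integers(len(so_pool), size=m))
            af_u = self.rng.random((m, 2))
            for i in range(m):
                row = transmitted[i]
                if not row.any():
                    continue  # allele not inherited by any sequenced child
                genotypes = {c: 1 for c, hit in zip(children, row) if hit}
                gi = int(gene_idx[i])
                so = so_pool if isinstance(so_pool, str) else so_pool[int(so_idx[i])]
                planted = gi < cfg.planted_term_genes
                af = (None if (planted and af_near_zero_for_planted)
                      else self._background_af(af_u[i, 0], af_u[i, 1]))
                if provenance == "lof":
                    prov = "planted" if planted else "background"
                else:
                    prov = provenance
                self._new_variant(gi, so, sift, polyphen, af, genotypes, prov)

    def add_common_variants(self) -> None:
        cfg = self.cfg
        all_children = [c for cs in self.family_children.values() for c in cs]
        for _ in range(cfg.n_common_variants):
            gi = int(self.rng.integers(cfg.n_genes))
            af = round(float(self.rng.uniform(0.05, 0.5)), 6)
            so = ("missense_variant", "synonymous_variant", "stop_gained")[
                int(self.rng.integers(3))
            ]
            genotypes: dict[str, int | None] = {}
            for c in all_children:
                g = int(self.rng.binomial(2, af))
                if g:
                    genotypes[c] = g
            if not genotypes:
                continue
            sift = "tolerated" if so == "missense_variant" else ""
            poly = "benign" if so == "missense_variant" else ""
            self._new_variant(gi, so, sift, poly, af, genotypes, "common")

    def mask_missing(self) -> None:
        rate = self.cfg.missing_call_rate
        if rate <= 0 or not self.variants:
            return
        ids = [s.sample_id for s in self.samples]
        mask = self.rng.random((len(self.variants), len(ids))) < rate
        for vi, si in zip(*np.nonzero(mask)):
            self.variants[int(vi)].genotypes[ids[int(si)]] = None


def simulate_cohort_data(
    cfg: SimulationConfig,
) -> tuple[list[AnnotatedVariant], CohortDesign, TruthLedger]:
    """Generate the cohort in memory: variants, design, truth ledger."""
    rng = np.random.default_rng([cfg.seed, 1])
    b = _CohortBuilder(cfg, rng)
    design = b.build_design()
    # Background LoF process over every gene (planted genes included, at
    # the base rate, so multiplier 1 is an exact null) ...
    b.add_rare_class(
        _LOF_TERMS,
        b._per_gene_rates(cfg.background_lof_rate, planted_boost=False,
                          hyper_boost=True),
        sift="", polyphen="", provenance="background",
    )
    # ... plus the planted excess: novel LoF variants absent from the
    # reference panel, arising only in the planted term genes.
    if cfg.planted_rate_multiplier > 1.0:
        excess = np.zeros(cfg.n_genes)
        excess[: cfg.planted_term_genes] = (
            cfg.background_lof_rate * (cfg.planted_rate_multiplier - 1.0)
        )
        b.add_rare_class(
            _LOF_TERMS, np.clip(excess, 0.0, 1.0),
            sift="", polyphen="", provenance="lof",
            af_near_zero_for_planted=True,
        )
    b.add_rare_class(
        "missense_variant",
        b._per_gene_rates(cfg.missense_damaging_rate, planted_boost=False,
                          hyper_boost=True),
        sift="deleterious", polyphen="probably_damaging", provenance="missense",
    )
    b.add_rare_class(
        "missense_variant",
        b._per_gene_rates(cfg.missense_benign_rate, planted_boost=False,
                          hyper_boost=True),
        sift="tolerated", polyphen="benign", provenance="benign_missense",
    )
    b.add_rare_class(
        "synonymous_variant",
        b._per_gene_rates(cfg.synonymous_rate, planted_boost=False,
                          hyper_boost=False),
        sift="", polyphen="", provenance="synonymous",
    )
    b.add_common_variants()
    b.mask_missing()
    variants = sorted(b.variants, key=lambda v: (int(v.chrom), v.pos, v.alt))

    # Generator-side dedup bookkeeping, independent of the analysis code:
    # count, per variant, families with >=1 affected carrier call.
    fam_of = {s.sample_id: s.family_id for s in design.samples}
    affected = {s.sample_id for s in design.samples if s.affected}
    expected: dict[str, int] = {}
    for v in variants:
        fams = {
            fam_of[sid]
            for sid, g in v.genotypes.items()
            if g is not None and g >= 1 and sid in affected
        }
        expected[_variant_key_str(v)] = len(fams)

    ledger = TruthLedger(
        planted_term_id=cfg.planted_term_id,
        planted_genes=cfg.planted_genes,
        clique_genes=cfg.clique_genes,
        hypervariable_genes=cfg.hypervariable_genes,
        provenance=b.provenance,
        expected_family_dedup=expected,
        seed=cfg.seed,
    )
    return variants, design, ledger


def simulate_control_counts(cfg: SimulationConfig) -> tuple[dict[str, int], int]:
    """Aggregated per-gene control LoF allele counts (no planted effect)."""
    rng = np.random.default_rng([cfg.seed, 2])
    rates = np.full(cfg.n_genes, cfg.background_lof_rate)
    rates[cfg.n_genes - cfg.n_hypervariable_genes:] *= cfg.hypervariable_multiplier
    rates = np.clip(rates, 0.0, 1.0)
    counts = rng.binomial(2 * cfg.n_control, rates)
    return {g: int(c) for g, c in zip(cfg.genes, counts)}, cfg.n_control


def simulate_network_and_terms(
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, frozenset[str]]]]:
    """Sparse random interaction network with a planted clique, plus a
    GMT-style term map containing the planted term and decoys."""
    rng = np.random.default_rng([cfg.seed, 3])
    genes = cfg.genes
    edges: set[tuple[str, str]] = set()
    clique = cfg.clique_genes
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            edges.add((clique[i], clique[j]))
    while len(edges) < cfg.n_random_edges + len(clique) * (len(clique) - 1) // 2:
        a, bdx = rng.integers(cfg.n_genes, size=2)
        if a == bdx:
            continue
        pair = tuple(sorted((genes[int(a)], genes[int(bdx)])))
        edges.add(pair)  # type: ignore[arg-type]

    terms: dict[str, tuple[str, frozenset[str]]] = {
        cfg.planted_term_id: (
            "planted biological process", frozenset(cfg.planted_genes)
        )
    }
    # decoys of mixed sizes, some outside the 10-200 selection window
    sizes = [5, 300] + [
        int(s) for s in rng.integers(10, 150, size=max(cfg.n_decoy_terms - 2, 0))
    ]
    for i, size in enumerate(sizes):
        size = min(size, cfg.n_genes)
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        terms[f"GO:{8000000 + i}"] = (
            f"decoy process {i + 1}",
            frozenset(genes[int(m)] for m in members),
        )
    return sorted(edges), terms


# ---------------------------------------------------------------------------
# file emission

VCF_CSQ_FORMAT = "SYMBOL|Consequence|SIFT|PolyPhen|EUR_AF"


def write_vcf(
    variants: list[AnnotatedVariant], design: CohortDesign, path: str | Path
) -> None:
    """Emit a VCF 4.2 with per-allele CSQ annotations and GT calls."""
    sample_ids = [s.sample_id for s in design.samples]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        f'annotations. Format: {VCF_CSQ_FORMAT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c in sorted({v.chrom for v in variants}, key=lambda x: (len(x), x)):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for v in variants:
        af = "" if v.control_af is None else f"{v.control_af:g}"
        csq = f"{v.gene}|{v.raw_consequence}|{v.sift or ''}|{v.polyphen or ''}|{af}"
        csq = csq.replace("|unknown", "|")  # unannotated predictors stay blank
        gts = []
        for sid in sample_ids:
            g = v.genotypes.get(sid, 0)
            if g is None:
                gts.append("./.")
            elif g == 0:
                gts.append("0/0")
            elif g == 1:
                gts.append("0/1")
            else:
                gts.append("1/1")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\tCSQ={csq}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ped(design: CohortDesign, path: str | Path) -> None:
    """Six-column pedigree; two unsequenced founders head each family."""
    lines = []
    for fam, members in sorted(design.families.items()):
        father, mother = f"{fam}_P1", f"{fam}_P2"
        lines.append(f"{fam}\t{father}\t0\t0\t1\t0")
        lines.append(f"{fam}\t{mother}\t0\t0\t2\t0")
        for m in members:
            pheno = "2" if design.status(m) else "1"
            lines.append(f"{fam}\t{m}\t{father}\t{mother}\t0\t{pheno}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_control_counts(
    counts: dict[str, int], cohort_size: int, path: str | Path
) -> None:
    lines = ["gene\tallele_count\tcohort_size"]
    for g in sorted(counts):
        lines.append(f"{g}\t{counts[g]}\t{cohort_size}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{a}\t{b}" for a, b in edges) + "\n"
    )


def write_gmt(
    terms: dict[str, tuple[str, frozenset[str]]], path: str | Path
) -> None:
    lines = []
    for tid in sorted(terms):
        name, genes = terms[tid]
        lines.append("\t".join([tid, name] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_cohort(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[Path, Path, TruthLedger]:
    """Simulate and write the cohort VCF + PED; returns paths and ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, design, ledger = simulate_cohort_data(cfg)
    vcf = outdir / "cohort.vcf"
    ped = outdir / "cohort.ped"
    write_vcf(variants, design, vcf)
    write_ped(design, ped)
    ledger.to_json(outdir / "truth.json")
    return vcf, ped, ledger


def simulate_all_inputs(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input file the pipeline needs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf, ped, _ledger = simulate_cohort(cfg, outdir)
    counts, size = simulate_control_counts(cfg)
    control = outdir / "control_lof_counts.tsv"
    write_control_counts(counts, size, control)
    edges, terms = simulate_network_and_terms(cfg)
    edge_path = outdir / "network_edges.tsv"
    gmt_path = outdir / "terms.gmt"
    write_edge_list(edges, edge_path)
    write_gmt(terms, gmt_path)
    return {
        "vcf": vcf, "ped": ped, "control": control,
        "edges": edge_path, "gmt": gmt_path, "truth": outdir / "truth.json",
    }
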