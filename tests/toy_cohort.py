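"""Hand-built toy cohort: 40 alt-allele variants with hand-traced
expected filter outcomes.

Three families: FA (A1, A2 affected; U1 unaffected), FB (B1 affected;
B2 unaffected), FC (C1 affected, singleton). Every filter rule is
exercised: the rarity threshold (including the strict < 0.05 boundary
and missing AF), the loss-of-function term list, the SIFT/PolyPhen
missense conjunction, in-frame indels, multi-term and multi-allelic
annotations, half-missing and all-missing genotype records, and the
affected-carrier requirement. ``expect_keep`` was assigned by tracing
the three rules by hand for each variant.
"""

from pathlib import Path

SAMPLES = ["A1", "A2", "U1", "B1", "B2", "C1"]

PED_TEXT = """\
FA\tA1\t0\t0\t1\t2
FA\tA2\t0\t0\t2\t2
FA\tU1\t0\t0\t1\t1
FB\tB1\t0\t0\t1\t2
FB\tB2\t0\t0\t2\t1
FC\tC1\t0\t0\t1\t2
"""


def _gts(**kw: str) -> list[str]:
    return [kw.get(s, "0/0") for s in SAMPLES]


# (gene, consequence, sift, polyphen, af, genotypes, expect_keep)
# af "" means absent from the reference panel.
SPECS = [
    ("G1", "stop_gained", "", "", "0.001", _gts(A1="0/1"), True),
    ("G1", "frameshift_variant", "", "", "", _gts(A2="0/1"), True),
    ("G1", "stop_lost", "", "", "0.2", _gts(A1="0/1"), False),  # common
    ("G2", "splice_acceptor_variant", "", "", "0.001", _gts(U1="0/1"), False),
    ("G2", "splice_donor_variant", "", "", "0.001", _gts(B2="0/1"), False),
    ("G2", "start_lost", "", "", "0.0499", _gts(C1="0/1"), True),
    ("G3", "stop_gained", "", "", "0.05", _gts(A1="0/1"), False),  # strict <
    ("G3", "missense_variant", "deleterious(0.01)", "probably_damaging(0.99)",
     "0.001", _gts(A1="0/1"), True),
    ("G3", "missense_variant", "deleterious", "possibly_damaging",
     "0.001", _gts(B1="0/1"), True),
    ("G3", "missense_variant", "deleterious", "benign", "0.001",
     _gts(A1="0/1"), False),
    ("G3", "missense_variant", "tolerated", "probably_damaging", "0.001",
     _gts(A1="0/1"), False),
    ("G3", "missense_variant", "tolerated(0.4)", "benign(0.01)", "0.001",
     _gts(A2="0/1"), False),
    ("G4", "missense_variant", "", "probably_damaging", "0.001",
     _gts(A1="0/1"), False),  # missing SIFT fails
    ("G4", "missense_variant", "deleterious", "", "0.001",
     _gts(A1="0/1"), False),  # missing PolyPhen fails
    ("G4", "missense_variant", "deleterious", "probably_damaging", "",
     _gts(A1="0/1"), True),
    ("G4", "missense_variant", "deleterious", "probably_damaging", "0.1",
     _gts(A1="0/1"), False),
    ("G5", "inframe_deletion", "", "", "0.001", _gts(A1="0/1"), True),
    ("G5", "inframe_insertion", "", "", "0.001", _gts(C1="0/1"), True),
    ("G5", "inframe_deletion", "", "", "0.001", _gts(U1="0/1"), False),
    ("G5", "synonymous_variant", "", "", "0.001", _gts(A1="0/1"), False),
    ("G6", "intron_variant", "", "", "", _gts(A1="0/1"), False),
    ("G6", "missense_variant&splice_region_variant", "deleterious",
     "probably_damaging", "0.001", _gts(A1="0/1"), True),
    ("G6", "stop_gained&missense_variant", "tolerated", "benign", "0.001",
     _gts(A1="0/1"), True),  # most severe class wins
    ("G6", "splice_region_variant&synonymous_variant", "", "", "0.001",
     _gts(A1="0/1"), False),
    ("G7", "stop_gained", "", "", "0.001",
     _gts(A1="./.", A2="./.", U1="./.", B1="./.", B2="./.", C1="./."),
     False),  # all genotypes missing
    ("G7", "stop_gained", "", "", "0.001", _gts(A1="./1"), True),  # half call
    ("G7", "frameshift_variant", "", "", "0.001", _gts(A1="1/1"), True),
    ("G8", "stop_gained", "", "", "0.001",
     _gts(A1="0/1", A2="0/1", U1="0/1", B1="0/1"), True),
    # multi-allelic record below contributes two variants (29, 30)
    ("G9", "stop_gained", "", "", "", _gts(C1="0/1"), True),
    ("G9", "frameshift_variant", "", "", "0.3", _gts(B1="0/1"), False),
    ("G9", "missense_variant", "deleterious", "probably_damaging", "0.04",
     _gts(B1="0/1"), True),
    ("G10", "stop_gained", "", "", "0.001", _gts(), False),  # nobody carries
    ("G10", "splice_acceptor_variant", "", "", "0.001",
     _gts(A2="0/1", U1="0/1"), True),
    ("G10", "stop_lost", "", "", "", _gts(A1="0/1"), True),
    ("G11", "missense_variant", "deleterious", "probably_damaging", "0.001",
     _gts(B2="0/1", U1="0/1"), False),  # unaffected carriers only
    ("G11", "stop_gained", "", "", "0.0499", _gts(B1="0/1"), True),
    ("G11", "protein_altering_variant", "", "", "0.001", _gts(A1="0/1"), False),
    ("G12", "frameshift_variant", "", "", "0.001",
     _gts(A1="0/1", A2="0/1", B1="0/1"), True),
]

# multi-allelic site: alt 1 qualifying missense carried by A1, alt 2
# synonymous carried by B1; CSQ entries in alt order
MULTIALLELIC = (
    "G8",
    ["missense_variant|deleterious|probably_damaging|0.001",
     "synonymous_variant|||0.001"],
    {"A1": "0/1", "B1": "0/2"},
    [True, False],
)


def _record_lines() -> tuple[list[str], set[tuple[str, int, str, str]], int]:
    lines = []
    expected: set[tuple[str, int, str, str]] = set()
    pos = 1000
    n_variants = 0
    for gene, cons, sift, poly, af, gts, keep in SPECS:
        ref, alt = ("AT", "A") if "frameshift" in cons or "inframe" in cons else ("A", "T")
        csq = f"{gene}|{cons}|{sift}|{poly}|{af}"
        lines.append(
            f"1\t{pos}\t.\t{ref}\t{alt}\t.\t.\tCSQ={csq}\tGT\t" + "\t".join(gts)
        )
        if keep:
            expected.add(("1", pos, ref, alt))
        n_variants += 1
        pos += 10
    gene, entries, carriers, keeps = MULTIALLELIC
    gts = [carriers.get(s, "0/0") for s in SAMPLES]
    csq = ",".join(f"{gene}|{e}" for e in entries)
    lines.append(
        f"1\t{pos}\t.\tA\tT,G\t.\t.\tCSQ={csq}\tGT\t" + "\t".join(gts)
    )
    for alt, keep in zip(("T", "G"), keeps):
        if keep:
            expected.add(("1", pos, "A", alt))
        n_variants += 1
    return lines, expected, n_variants


RECORD_LINES, EXPECTED_KEPT, N_VARIANTS = _record_lines()

VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations.'
    ' Format: SYMBOL|Consequence|SIFT|PolyPhen|EUR_AF">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "##contig=<ID=1>",
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLES),
]


def write_toy_cohort(tmpdir) -> tuple[Path, Path]:
    vcf = Path(tmpdir) / "toy.vcf"
    ped = Path(tmpdir) / "toy.ped"
    vcf.write_text("\n".join(VCF_HEADER + RECORD_LINES) + "\n")
    ped.write_text(PED_TEXT)
    return vcf, ped
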