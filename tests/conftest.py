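import pytest

from famburden.variants import (
    AnnotatedVariant,
    CohortDesign,
    Sample,
    classify_consequence,
)


def make_variant(
    gene="GENE1",
    consequence="stop_gained",
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    sift="unknown",
    polyphen="unknown",
    control_af=None,
    genotypes=None,
):
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        raw_consequence=consequence,
        consequence=classify_consequence(consequence),
        sift=sift,
        polyphen=polyphen,
        control_af=control_af,
        genotypes=dict(genotypes or {}),
    )


@pytest.fixture
def small_design():
    """Two families: FA with two affected + one unaffected, FB with one
    affected + one unaffected."""
    return CohortDesign(
        samples=[
            Sample("A1", "FA", True),
            Sample("A2", "FA", True),
            Sample("U1", "FA", False),
            Sample("B1", "FB", True),
            Sample("B2", "FB", False),
        ]
    )
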