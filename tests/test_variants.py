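"""Consequence classification, variant filters, and VCF/PED parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famburden.io import cohort_from_ped, read_annotated_vcf
from famburden.variants import (
    ConsequenceClass,
    FilterConfig,
    FilterLog,
    classify_consequence,
    filter_cohort,
    is_protein_affecting,
)

from .conftest import make_variant
from .toy_cohort import EXPECTED_KEPT, N_VARIANTS, SAMPLES, write_toy_cohort


class TestClassify:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", ConsequenceClass.LOF),
            ("stop_lost", ConsequenceClass.LOF),
            ("start_lost", ConsequenceClass.LOF),
            ("splice_acceptor_variant", ConsequenceClass.LOF),
            ("splice_donor_variant", ConsequenceClass.LOF),
            ("frameshift_variant", ConsequenceClass.LOF),
            ("missense_variant", ConsequenceClass.MISSENSE),
            ("inframe_insertion", ConsequenceClass.INFRAME_INDEL),
            ("inframe_deletion", ConsequenceClass.INFRAME_INDEL),
            ("synonymous_variant", ConsequenceClass.OTHER),
            ("intron_variant", ConsequenceClass.OTHER),
            ("totally_made_up_term", ConsequenceClass.OTHER),
        ],
    )
    def test_term_lookup(self, term, expected):
        assert classify_consequence(term) is expected

    def test_most_severe_class_wins(self):
        assert classify_consequence(
            "missense_variant&stop_gained"
        ) is ConsequenceClass.LOF
        assert classify_consequence(
            "splice_region_variant&missense_variant"
        ) is ConsequenceClass.MISSENSE

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            classify_consequence("")


class TestProteinAffecting:
    def test_lof_kept_unconditionally(self):
        v = make_variant(consequence="stop_gained", sift="tolerated",
                         polyphen="benign")
        assert is_protein_affecting(v)

    @pytest.mark.parametrize(
        "sift,polyphen,rule,expected",
        [
            ("deleterious", "probably_damaging", "both", True),
            ("deleterious", "possibly_damaging", "both", True),
            ("deleterious", "benign", "both", False),
            ("deleterious", "benign", "either", True),
            ("tolerated", "probably_damaging", "both", False),
            ("tolerated", "benign", "both", False),
            ("tolerated", "benign", "either", False),
            ("unknown", "probably_damaging", "both", False),
        ],
    )
    def test_missense_rule(self, sift, polyphen, rule, expected):
        v = make_variant(consequence="missense_variant", sift=sift,
                         polyphen=polyphen)
        assert is_protein_affecting(v, FilterConfig(missense_rule=rule)) == expected

    def test_possibly_damaging_configurable(self):
        v = make_variant(consequence="missense_variant", sift="deleterious",
                         polyphen="possibly_damaging")
        assert not is_protein_affecting(
            v, FilterConfig(possibly_damaging_counts=False)
        )

    def test_inframe_configurable(self):
        v = make_variant(consequence="inframe_deletion")
        assert is_protein_affecting(v)
        assert not is_protein_affecting(v, FilterConfig(keep_inframe=False))


class TestFilterCohort:
    def test_three_rules(self, small_design):
        keep = make_variant(pos=1, control_af=0.001, genotypes={"A1": 1})
        common = make_variant(pos=2, control_af=0.20, genotypes={"A1": 1})
        unaffected_only = make_variant(
            pos=3, consequence="missense_variant", sift="deleterious",
            polyphen="probably_damaging", control_af=0.001,
            genotypes={"U1": 1, "B2": 1},
        )
        log = FilterLog()
        out = filter_cohort(
            [keep, common, unaffected_only], small_design, log=log
        )
        assert [v.pos for v in out] == [1]
        assert log.n_common == 1 and log.n_no_affected_carrier == 1
        assert log.n_retained == 1

    def test_idempotent(self, small_design):
        vs = [
            make_variant(pos=i, control_af=af, genotypes=g)
            for i, (af, g) in enumerate(
                [(0.001, {"A1": 1}), (0.2, {"A1": 1}), (None, {"B1": 1}),
                 (0.04, {"U1": 1})],
                start=1,
            )
        ]
        once = filter_cohort(vs, small_design)
        twice = filter_cohort(once, small_design)
        assert [v.key for v in once] == [v.key for v in twice]

    @given(thresholds=st.tuples(st.floats(0.01, 1.0), st.floats(0.01, 1.0)))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_af_threshold(self, thresholds):
        from famburden.variants import CohortDesign, Sample

        small_design = CohortDesign(
            samples=[Sample("A1", "FA", True), Sample("U1", "FA", False)]
        )
        lo, hi = sorted(thresholds)
        vs = [
            make_variant(pos=10 + i, control_af=af, genotypes={"A1": 1})
            for i, af in enumerate(
                [0.0, 0.005, 0.02, 0.049, 0.05, 0.1, 0.5, None]
            )
        ]
        small = {v.key for v in filter_cohort(
            vs, small_design, FilterConfig(max_control_af=lo))}
        big = {v.key for v in filter_cohort(
            vs, small_design, FilterConfig(max_control_af=hi))}
        assert small <= big

    def test_every_retained_variant_has_affected_carrier(self, small_design):
        vs = [
            make_variant(pos=i, control_af=0.001, genotypes=g)
            for i, g in enumerate(
                [{"A1": 1}, {"U1": 1}, {"B1": 2}, {"B2": 1}, {}], start=1
            )
        ]
        affected = set(small_design.affected_ids)
        for v in filter_cohort(vs, small_design):
            assert any(v.genotypes.get(s) for s in affected)


class TestToyCohortParsing:
    def test_hand_traced_filter_outcome(self, tmp_path):
        vcf, ped = write_toy_cohort(tmp_path)
        variants, vcf_samples = read_annotated_vcf(vcf)
        assert vcf_samples == SAMPLES
        assert len(variants) == N_VARIANTS == 40
        design = cohort_from_ped(ped, vcf_samples)
        kept = filter_cohort(variants, design)
        assert {v.key for v in kept} == EXPECTED_KEPT

    def test_multiallelic_decomposition_and_half_calls(self, tmp_path):
        vcf, _ped = write_toy_cohort(tmp_path)
        variants, _ = read_annotated_vcf(vcf)
        by_key = {v.key: v for v in variants}
        multi = [v for v in variants if v.pos == max(x.pos for x in variants)]
        assert len(multi) == 2
        assert {v.alt for v in multi} == {"T", "G"}
        assert {v.consequence for v in multi} == {
            ConsequenceClass.MISSENSE, ConsequenceClass.OTHER
        }
        # the 0/2 genotype counts for alt G only
        v_t = next(v for v in multi if v.alt == "T")
        v_g = next(v for v in multi if v.alt == "G")
        assert v_t.genotypes["A1"] == 1 and v_t.genotypes["B1"] == 0
        assert v_g.genotypes["B1"] == 1 and v_g.genotypes["A1"] == 0
        # half-missing "./1" counts the observed allele
        half = next(
            v for v in variants
            if v.gene == "G7" and v.raw_consequence == "stop_gained"
            and v.genotypes["A1"] == 1
        )
        assert half.genotypes["A2"] == 0
        assert by_key[half.key] is half

    def test_ped_statuses(self, tmp_path):
        _vcf, ped = write_toy_cohort(tmp_path)
        design = cohort_from_ped(ped, SAMPLES)
        assert sorted(design.affected_ids) == ["A1", "A2", "B1", "C1"]
        assert sorted(design.unaffected_ids) == ["B2", "U1"]
        assert design.families["FA"] == ["A1", "A2", "U1"]
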