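import random

import pytest
from hypothesis import given, strategies as st

from conftest import random_template
from spddpcr.assay_design import (
    AmpliconTemplate,
    Direction,
    SuperSelectivePrimer,
    VariantSpec,
    design_standard_assay,
    design_superselective,
    enumerate_designs,
    intervening_segment,
    validate_assay,
)
from spddpcr.errors import DesignError, GeometryError, InputError
from spddpcr.seq import reverse_complement
from spddpcr.strategy import StrategySpec, parse_strategy


def test_forward_design_reconstructs_published_primer(apc_4128):
    primer = design_superselective(
        apc_4128.template(), parse_strategy("21–7/8–5:1:1"), "forward",
        bridge_override="ATATATA",
    )
    assert primer.anchor == "GTGCTCAGACACCCAAAAGTC"
    assert primer.bridge == "ATATATA"
    assert primer.foot == "CACTAAG"
    assert primer.full_sequence == "GTGCTCAGACACCCAAAAGTC" + "ATATATA" + "CACTAAG"


def test_reverse_design_reconstructs_published_primer(lamc3):
    primer = design_superselective(
        lamc3.template(), parse_strategy("19–8/6–4:1:1"), "reverse",
        bridge_override="ATATATAT",
    )
    assert primer.full_sequence == "CACTGAGCGAGTGGAACCC" + "ATATATAT" + "ACAGTG"


def test_default_bridge_is_at_alternation(apc_4128):
    primer = design_superselective(
        apc_4128.template(), apc_4128.strategy, apc_4128.direction
    )
    assert primer.bridge == "ATATATA"  # matches the published bridge


def test_foot_carries_alt_allele_not_reference(apc_4128):
    primer = design_superselective(
        apc_4128.template(), apc_4128.strategy, "forward"
    )
    # template has T at the interrogated position; primer foot has the A
    assert primer.interrogated_base == "A"


def test_variant_too_close_to_template_end_is_geometry_error():
    t = random_template(random.Random(0), 40, 2)
    with pytest.raises(GeometryError):
        design_superselective(t, StrategySpec(21, 7, 8, 5, 1), "forward")


def test_template_rejects_wrong_reference_base():
    with pytest.raises(InputError, match="reference allele"):
        AmpliconTemplate("ACGTACGT", 0, VariantSpec("G", "c.1A>T", "C", "T"))


@given(
    seed=st.integers(0, 10_000),
    anchor_len=st.integers(10, 24),
    bridge_len=st.integers(1, 8),
    intervening_len=st.integers(1, 8),
    foot=st.sampled_from([(4, 1), (5, 1), (6, 0), (3, 0)]),
    direction=st.sampled_from(["forward", "reverse"]),
)
def test_designed_primers_always_validate(
    seed, anchor_len, bridge_len, intervening_len, foot, direction
):
    """Any design produced on a random template passes the structural
    audit against that template."""
    rng = random.Random(seed)
    f5, f3 = foot
    upstream = anchor_len + intervening_len + f5
    length = upstream + 1 + f3 + rng.randint(0, 20)
    offset = upstream if direction == "forward" else length - 1 - upstream - f3
    template = random_template(rng, length, offset)
    strategy = StrategySpec(anchor_len, bridge_len, intervening_len, f5, f3)
    primer = design_superselective(template, strategy, direction)
    report = validate_assay(primer, None, template)
    assert report.structural_ok, report.failures()


@given(seed=st.integers(0, 10_000))
def test_forward_reverse_mirror_symmetry(seed):
    """Forward design on a template equals reverse design on its reverse
    complement (mirrored variant coordinate)."""
    rng = random.Random(seed)
    length = rng.randint(45, 90)
    offset = rng.randint(34, length - 2)
    template = random_template(rng, length, offset)
    mirrored = AmpliconTemplate(
        reverse_complement(template.sequence),
        length - 1 - offset,
        VariantSpec(
            "TEST", "c.?",
            reverse_complement(template.variant.ref_allele),
            reverse_complement(template.variant.alt_allele),
        ),
    )
    strategy = StrategySpec(18, 6, 8, 5, 1)
    fwd = design_superselective(template, strategy, "forward")
    rev = design_superselective(mirrored, strategy, "reverse")
    assert fwd.anchor == rev.anchor
    assert fwd.foot == rev.foot


class TestValidateAssay:
    def test_ref_allele_foot_fails_wildtype_mismatch_check(self, apc_4128):
        template = apc_4128.template()
        good = design_superselective(template, apc_4128.strategy, "forward")
        bad = SuperSelectivePrimer(
            good.anchor, good.bridge,
            good.foot[:5] + template.variant.ref_allele + good.foot[6:],
            good.direction, good.strategy,
        )
        report = validate_assay(bad, None, template)
        assert not report["foot_single_mismatch_wildtype"].passed
        assert not report["foot_matches_mutant"].passed

    def test_complementary_bridge_fails_asymmetry_check(self, apc_4128):
        template = apc_4128.template()
        intervening = intervening_segment(template, apc_4128.strategy, "forward")
        good = design_superselective(template, apc_4128.strategy, "forward")
        bad = SuperSelectivePrimer(
            good.anchor, reverse_complement(intervening), good.foot,
            good.direction,
            StrategySpec(21, len(intervening), 8, 5, 1),
        )
        report = validate_assay(bad, None, template)
        assert not report["bridge_asymmetry"].passed

    def test_overall_is_conjunction_of_checks(self, apc_4128):
        report = validate_assay(apc_4128.ssp(), None, apc_4128.template())
        assert report.overall == all(c.passed for c in report.checks)


class TestStandardAssay:
    def test_pair_from_published_anchor_satisfies_constraints(self, apc_4128):
        pair = design_standard_assay(apc_4128.template(), apc_4128.anchor)
        assert pair.amplicon_len <= 100
        assert abs(pair.tm_anchor - pair.tm_complementary) <= 2.0
        assert pair.anchor_primer == apc_4128.anchor

    def test_published_pair_validates(self, apc_4128):
        from spddpcr.assay_design import StandardPrimerPair
        from spddpcr.thermo import compute_tm

        template = apc_4128.template()
        comp = apc_4128.complementary_primer
        # published complementary primer binds the bottom strand at the
        # amplicon end
        assert reverse_complement(comp) in template.sequence
        pair = StandardPrimerPair(
            apc_4128.anchor, comp, len(template.sequence),
            compute_tm(apc_4128.anchor), compute_tm(comp),
        )
        report = validate_assay(apc_4128.ssp(), pair, template)
        assert report.overall

    def test_absent_anchor_is_design_failure(self, apc_4128):
        with pytest.raises(DesignError, match="does not occur"):
            design_standard_assay(apc_4128.template(), "A" * 18)

    def test_symmetric_toy_template_tm_agreement(self):
        """Tm-matched pair on a toy template agrees with the NN oracle."""
        from test_thermo import oracle_tm

        seq = "GCGTACGTTAGCATCGATGCACGGTACCTAGGATCGTAGCTAGGCATGCATCGTACGATC"
        template = AmpliconTemplate(
            seq, 30, VariantSpec("TOY", "c.1G>T", seq[30], "T" if seq[30] != "T" else "A")
        )
        anchor = seq[:20]
        pair = design_standard_assay(template, anchor, tm_tolerance=2.0)
        assert abs(oracle_tm(pair.anchor_primer) - oracle_tm(pair.complementary_primer)) < 2.5


class TestEnumerateDesigns:
    def test_contains_published_design(self, apc_4128):
        candidates = enumerate_designs(
            apc_4128.template(),
            anchor_len_range=(18, 24),
            bridge_len_range=(6, 9),
            intervening_len_range=(4, 8),
        )
        full = {c.full_sequence for c in candidates}
        assert apc_4128.anchor + apc_4128.bridge + apc_4128.foot in full

    def test_edge_variant_yields_only_one_direction(self):
        rng = random.Random(3)
        template = random_template(rng, 60, 3)  # 3 bp from the 5' end
        candidates = enumerate_designs(template, anchor_len_range=(18, 22))
        assert candidates
        assert {c.direction for c in candidates} == {Direction.REVERSE}

    def test_all_candidates_validate_and_rank_deterministically(self):
        rng = random.Random(11)
        template = random_template(rng, 80, 45)
        a = enumerate_designs(template, anchor_len_range=(16, 20),
                              bridge_len_range=(6, 8))
        b = enumerate_designs(template, anchor_len_range=(16, 20),
                              bridge_len_range=(6, 8))
        assert [c.full_sequence for c in a] == [c.full_sequence for c in b]
        for candidate in a[:20]:
            assert validate_assay(candidate, None, template).structural_ok
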