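import itertools

import numpy as np
import pytest

from nhejseq.joints import (
    JointDescriptor,
    JointError,
    JointLimits,
    MicrohomologyMismatch,
    UnexplainableProduct,
    WindowError,
    alias_moore_haber,
    canonical_descriptor,
    decode_joint_id,
    encode_joint_id,
    enumerate_joints,
    joint_table,
    precise_descriptor,
    product_sequence,
)
from nhejseq.locus import DsbLocus

from conftest import random_sequence


def brute_force_products(locus, limits):
    """Independent oracle: all strings left-prefix + insertion + right-suffix
    over every (L, R, M, I) in the limits whose microhomology bases agree,
    deduplicated by string."""
    s, t, v = locus.top_strand, locus.cut_pos, locus.overhang_len
    out = set()
    inserts = [""]
    for length in range(1, limits.insertion_max + 1):
        inserts += ["".join(c) for c in itertools.product("ACGT", repeat=length)]
    for l in range(limits.left_max + 1):
        for r in range(limits.right_max + 1):
            for m in range(limits.mh_max + 1):
                if t - l - m < 0 or t - v + r + m > len(s):
                    continue
                if s[t - l - m : t - l] != s[t - v + r : t - v + r + m]:
                    continue
                for ins in inserts:
                    if ins and m:
                        continue
                    out.add(s[: t - l] + ins + s[t - v + r + m :])
    return out


class TestProductSequence:
    def test_precise_joint_is_identity(self, tiny_locus):
        assert product_sequence(precise_descriptor(tiny_locus), tiny_locus) == tiny_locus.top_strand

    def test_fill_in_after_one_base_resection(self, tiny_locus):
        # chew one overhang base on the left, fill in, blunt-join: +3 bp overall
        desc = JointDescriptor.build(4, microhomology=0, left_deleted=1)
        assert desc.net_change == 3
        product = product_sequence(desc, tiny_locus)
        assert product == "AAAACGT" + "CGTACGTTTT"
        assert len(product) == tiny_locus.n + desc.net_change

    def test_two_base_slipped_annealing_duplicates_overhang_bases(self, ca_locus):
        # overhang CACA: terminal CA anneals to initial CA, fill-in duplicates CA
        desc = JointDescriptor.build(4, microhomology=2)
        assert desc.net_change == 2
        product = product_sequence(desc, ca_locus)
        assert product == "AAAACACA" + "CAGTTTTT"

    def test_microhomology_requires_identical_junction_bases(self, tiny_locus):
        # overhang CGTA: last two bases TA != first two CG, so M=2 cannot anneal
        desc = JointDescriptor.build(4, microhomology=2)
        with pytest.raises(MicrohomologyMismatch):
            product_sequence(desc, tiny_locus)

    def test_descriptor_algebra_enforced(self, tiny_locus):
        bad = JointDescriptor(net_change=0, microhomology=0, left_deleted=1, right_deleted=0)
        with pytest.raises(JointError, match="algebra"):
            product_sequence(bad, tiny_locus)

    def test_insertion_with_microhomology_rejected(self):
        with pytest.raises(JointError, match="M=0"):
            JointDescriptor.build(4, microhomology=1, insertion="A")

    def test_three_base_insertion_rejected(self):
        with pytest.raises(JointError, match="2 inserted"):
            JointDescriptor.build(4, insertion="ACG")


@pytest.mark.parametrize("v", [0, 2, 4])
@pytest.mark.parametrize("with_insertions", [False, True])
def test_enumeration_matches_brute_force_oracle(medium_locus, medium_layout, v, with_insertions):
    """The enumerated product set equals exhaustive string construction."""
    locus = DsbLocus(
        medium_locus.name,
        medium_locus.top_strand,
        medium_locus.cut_pos,
        v,
        medium_locus.amplicon_window,
    )
    limits = JointLimits(
        left_max=3, right_max=3, mh_max=4, insertion_max=2 if with_insertions else 0
    )
    templates = enumerate_joints(locus, medium_layout, limits)
    products = {tm.product for tm in templates}
    assert products == brute_force_products(locus, limits)
    # no two templates share a product, and the precise joint is always present
    assert len(products) == len(templates)
    assert any(tm.joint_id == "precise" for tm in templates)
    # descriptor algebra holds exhaustively
    for tm in templates:
        d = tm.descriptor
        assert len(tm.product) - locus.n == d.net_change
        assert d.net_change == v - d.left_deleted - d.right_deleted - d.microhomology + len(
            d.insertion
        )


def test_enumeration_is_deterministic_and_sorted(medium_locus, medium_layout):
    limits = JointLimits(left_max=3, right_max=3, mh_max=4)
    a = enumerate_joints(medium_locus, medium_layout, limits)
    b = enumerate_joints(medium_locus, medium_layout, limits)
    assert [tm.joint_id for tm in a] == [tm.joint_id for tm in b]
    assert [tm.joint_id for tm in a] == sorted(tm.joint_id for tm in a)


def test_zero_deletion_space_is_religation_variants(medium_locus, medium_layout):
    """With no resection and no insertions only overhang-annealing variants remain."""
    limits = JointLimits(left_max=0, right_max=0, mh_max=4, insertion_max=0)
    templates = enumerate_joints(medium_locus, medium_layout, limits)
    ids = {tm.joint_id for tm in templates}
    # M=4 precise, M=2 slipped annealing of CACA, M=0 full fill-in; M=1,3 fail identity
    assert ids == {"precise", "D+2_M2_L0_R0", "D+4_M0_L0_R0"}
    assert {tm.product for tm in templates} == brute_force_products(medium_locus, limits)


def test_equivalent_descriptors_collapse_to_canonical(medium_locus, medium_layout):
    """(L=0, M=2) and (L=2, R=... ) style duplicates keep the max-M descriptor."""
    limits = JointLimits(left_max=3, right_max=3, mh_max=4)
    templates = enumerate_joints(medium_locus, medium_layout, limits)
    by_product = {}
    for tm in templates:
        assert tm.product not in by_product
        by_product[tm.product] = tm
    slipped = product_sequence(JointDescriptor.build(4, microhomology=2), medium_locus)
    # that product is also reachable as (L=0, R=2, M=0); the M=2 descriptor wins
    assert by_product[slipped].descriptor.microhomology == 2


def test_limits_pushing_junction_outside_read_raise(sim_locus):
    from nhejseq.locus import ReadLayout

    tight = ReadLayout(index_len=6, primer_len=0, read_len=30)
    with pytest.raises(WindowError, match="junction"):
        enumerate_joints(sim_locus, tight, JointLimits(left_max=40, right_max=0, mh_max=0, insertion_max=0))


class TestCanonicalDescriptor:
    def test_top_strand_is_precise(self, tiny_locus):
        assert canonical_descriptor(tiny_locus.top_strand, tiny_locus).is_precise

    def test_round_trip_reproduces_product(self, tiny_locus):
        product = product_sequence(JointDescriptor.build(4, left_deleted=1), tiny_locus)
        desc = canonical_descriptor(product, tiny_locus)
        assert product_sequence(desc, tiny_locus) == product

    def test_unexplainable_product_raises(self, tiny_locus):
        with pytest.raises(UnexplainableProduct):
            canonical_descriptor("GGGGGGGGGGGGGG", tiny_locus)

    def test_random_descriptor_round_trip_and_idempotence(self):
        """canonical(product(d)) reproduces the product and is a fixed point."""
        rng = np.random.default_rng(12345)
        limits = JointLimits(left_max=6, right_max=6, mh_max=6)
        checked = 0
        attempts = 0
        while checked < 1000 and attempts < 20000:
            attempts += 1
            seq = random_sequence(40, seed=int(rng.integers(1 << 30)))
            v = int(rng.integers(0, 5))
            t = 20
            locus = DsbLocus("r", seq, t, v, (1, 40))
            m = int(rng.integers(0, 5))
            l = int(rng.integers(0, 5))
            r = int(rng.integers(0, 5))
            ins = ""
            if m == 0 and rng.random() < 0.3:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
            desc = JointDescriptor.build(v, m, l, r, ins)
            try:
                product = product_sequence(desc, locus)
            except JointError:
                continue
            canon = canonical_descriptor(product, locus, limits)
            assert product_sequence(canon, locus) == product
            recanon = canonical_descriptor(product_sequence(canon, locus), locus, limits)
            assert recanon == canon
            assert decode_joint_id(encode_joint_id(canon), v) == canon
            checked += 1
        assert checked == 1000


class TestJointIds:
    def test_precise_encodes_specially(self, tiny_locus):
        assert encode_joint_id(precise_descriptor(tiny_locus)) == "precise"
        assert decode_joint_id("precise", overhang_len=4) == precise_descriptor(tiny_locus)

    def test_deletion_identifier_rendering(self):
        desc = JointDescriptor(-3, 4, 3, 0)
        assert encode_joint_id(desc) == "D-3_M4_L3_R0"

    def test_insertion_identifier_rendering(self):
        desc = JointDescriptor.build(4, insertion="CA", left_deleted=1, right_deleted=0)
        assert encode_joint_id(desc) == "D+5_M0_L1_R0_ICA"

    @pytest.mark.parametrize(
        "bad", ["", "precise_extra", "D3_M0_L0_R0", "D+1_M0_L0", "D+1_M0_L0_R0_INN"]
    )
    def test_malformed_identifiers_rejected(self, bad):
        with pytest.raises(JointError):
            decode_joint_id(bad, overhang_len=4)

    def test_precise_decode_requires_overhang_length(self):
        with pytest.raises(JointError, match="overhang"):
            decode_joint_id("precise")

    def test_random_round_trip(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            v = int(rng.integers(0, 7))
            m = int(rng.integers(0, 7))
            ins = ""
            if m == 0 and rng.random() < 0.4:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
            desc = JointDescriptor.build(
                v, m, int(rng.integers(0, 20)), int(rng.integers(0, 20)), ins
            )
            assert decode_joint_id(encode_joint_id(desc), v) == desc


class TestMooreHaberAlias:
    def test_fill_in_duplication_alias(self, ca_locus):
        desc = JointDescriptor.build(4, microhomology=2)
        assert alias_moore_haber(desc, ca_locus) == "+CA"

    def test_precise_and_insertion_have_no_alias(self, ca_locus):
        assert alias_moore_haber(precise_descriptor(ca_locus), ca_locus) is None
        ins = JointDescriptor.build(4, insertion="T")
        assert alias_moore_haber(ins, ca_locus) is None

    def test_blunt_fill_in_has_no_alias(self, ca_locus):
        blunt = JointDescriptor.build(4)  # M=0, D=+4 duplication of the whole overhang
        assert alias_moore_haber(blunt, ca_locus) is None

    def test_unambiguous_deletion_alias(self, tiny_locus):
        desc = JointDescriptor.build(4, left_deleted=5)  # removes one A of the AAAA run
        assert desc.net_change == -1
        assert alias_moore_haber(desc, tiny_locus) == "-A"


def test_joint_table_columns(medium_locus, medium_layout):
    templates = enumerate_joints(medium_locus, medium_layout, JointLimits(2, 2, 4))
    table = joint_table(templates)
    assert list(table.columns) == ["D", "M", "L", "R", "I", "product_length", "read_template"]
    assert table.loc["precise", "D"] == 0
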