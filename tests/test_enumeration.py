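"""Rotation classes, the bottom-up construction, and the exact counters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from sympy import divisors

from ccdecomp import (
    CountTable,
    Decomposition,
    DistanceAlphabet,
    canonical,
    count_linear,
    count_primitive_necklaces,
    enumerate_brute_force,
    enumerate_decompositions,
    frobenius_two,
    primitive_root,
    rotations,
)

parts_strategy = st.lists(
    st.sampled_from([3, 4, 7]), min_size=1, max_size=12
).map(tuple)


class TestRotationClasses:
    @pytest.mark.parametrize(
        "parts, expected",
        [
            ((3, 3, 4), {(3, 3, 4), (3, 4, 3), (4, 3, 3)}),
            ((7,), {(7,)}),
            ((3, 4, 3, 4), {(3, 4, 3, 4), (4, 3, 4, 3)}),
        ],
    )
    def test_rotations(self, parts, expected):
        assert rotations(parts) == expected

    @pytest.mark.parametrize(
        "parts, expected",
        [((4, 3, 3), (3, 3, 4)), ((7,), (7,)), ((7, 3, 4), (3, 4, 7))],
    )
    def test_canonical(self, parts, expected):
        assert canonical(parts) == expected

    @pytest.mark.parametrize(
        "parts, root, mult",
        [
            ((3, 4, 3, 4), (3, 4), 2),
            ((3, 3, 4), (3, 3, 4), 1),
            ((4, 4, 4), (4,), 3),
        ],
    )
    def test_primitive_root(self, parts, root, mult):
        assert primitive_root(parts) == (root, mult)

    @pytest.mark.parametrize("func", [rotations, canonical, primitive_root])
    def test_empty_input_rejected(self, func):
        with pytest.raises(ValueError):
            func(())

    @given(parts_strategy)
    def test_canonical_is_rotation_invariant_and_idempotent(self, parts):
        reps = {canonical(r) for r in rotations(parts)}
        assert len(reps) == 1
        (rep,) = reps
        assert canonical(rep) == rep

    @given(parts_strategy)
    def test_primitive_root_reconstructs(self, parts):
        root, mult = primitive_root(parts)
        assert root * mult == parts
        assert primitive_root(root)[1] == 1
        # distinct rotations of the whole = part count of the root
        assert len(rotations(parts)) == len(root)


class TestEnumeration:
    @pytest.mark.parametrize(
        "period, members",
        [
            (16, {(3, 3, 3, 3, 4), (3, 3, 3, 7)}),
            (7, {(7,), (3, 4)}),
            (5, set()),
            (6, set()),
            (8, set()),
            (9, set()),
            (12, set()),
        ],
    )
    def test_printed_member_sets(self, enum40, period, members):
        assert {d.parts for d in enum40[period]} == members

    @pytest.mark.parametrize("period, count", [(22, 9), (23, 12)])
    def test_printed_counts(self, enum40, period, count):
        assert len(enum40[period]) == count

    def test_members_are_canonical_and_primitive(self, enum40):
        for dset in enum40.values():
            for d in dset:
                assert d.is_canonical
                assert d.is_primitive
                assert d.period == dset.period

    def test_registry_closed_under_rotation(self, enum40):
        dset = enum40[22]
        reg = dset.rotational_registry
        assert all(rotations(t) <= reg for t in reg)
        assert len(reg) == sum(len(rotations(d.parts)) for d in dset)

    def test_rejects_period_below_minimum(self):
        with pytest.raises(ValueError, match="below the smallest"):
            enumerate_decompositions(2)

    def test_rejects_non_integer(self):
        with pytest.raises(TypeError):
            enumerate_decompositions(10.5)

    def test_cap_refusal_and_override(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_decompositions(81)
        sets = enumerate_decompositions(25, cap=20, force=True)
        assert 25 in sets

    def test_custom_alphabet(self):
        sets = enumerate_decompositions(10, DistanceAlphabet((2, 5)))
        assert {d.parts for d in sets[7]} == {(2, 5)}
        assert {d.parts for d in sets[9]} == {(2, 2, 5)}


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "period, members",
        [
            (10, {(3, 3, 4), (3, 7)}),
            (2, set()),
        ],
    )
    def test_examples(self, period, members):
        assert {d.parts for d in enumerate_brute_force(period)} == members

    def test_period_22_count(self):
        assert len(enumerate_brute_force(22)) == 9

    def test_three_way_agreement_small(self, enum40):
        """Construction, brute force and Moebius counting coincide."""
        for n in range(3, 31):
            bf = enumerate_brute_force(n)
            assert bf == set(enum40[n].members), n
            assert len(bf) == count_primitive_necklaces(n), n


class TestCounting:
    @pytest.mark.parametrize("m, expected", [(0, 1), (5, 0), (7, 3), (10, 5)])
    def test_count_linear_examples(self, m, expected):
        assert count_linear(m) == expected

    def test_count_linear_negative_rejected(self):
        with pytest.raises(ValueError):
            count_linear(-1)

    def test_recursion_holds(self):
        table = CountTable()
        table.count(60)
        for m in range(8, 61):
            assert table.values[m] == sum(table.values[m - a] for a in (3, 4, 7))

    @pytest.mark.parametrize("n, expected", [(22, 9), (12, 0), (10, 2)])
    def test_necklace_count_examples(self, n, expected):
        assert count_primitive_necklaces(n) == expected

    def test_linear_cyclic_conservation(self, enum40):
        """Every ordered sequence is a rotation of a unique primitive
        class of some divisor period: x[n] = sum over d|n of the part
        counts of the primitive classes of period d."""
        for n in range(1, 41):
            rhs = sum(
                len(d.parts)
                for dd in divisors(n)
                if dd in enum40
                for d in enum40[dd]
            )
            assert count_linear(n) == rhs, n

    def test_large_period_count_is_fast_and_exact(self):
        # far beyond enumeration range; exact big-integer result
        assert count_primitive_necklaces(140) == 18342442737398

    def test_frobenius_gap(self, enum40):
        zeros = [n for n in range(1, 41) if count_linear(n) == 0]
        assert zeros == [1, 2, 5]
        empty = [n for n in range(3, 41) if not enum40[n].members]
        assert empty == [5, 6, 8, 9, 12]

    def test_nonempty_above_twelve(self, enum40):
        assert all(enum40[n].members for n in range(13, 41))


class TestFrobenius:
    @pytest.mark.parametrize("pair, expected", [((3, 4), 5), ((2, 3), 1), ((3, 7), 11)])
    def test_values(self, pair, expected):
        assert frobenius_two(*pair) == expected

    def test_non_coprime_rejected(self):
        with pytest.raises(ValueError, match="coprime"):
            frobenius_two(4, 6)

    def test_consistent_with_counting(self):
        alpha = DistanceAlphabet((3, 7))
        g = frobenius_two(3, 7)
        assert count_linear(g, alpha) == 0
        assert all(count_linear(n, alpha) > 0 for n in range(g + 1, 41))


class TestDecompositionType:
    def test_string_round_trip(self):
        d = Decomposition.from_string("3+4+7")
        assert d.parts == (3, 4, 7) and str(d) == "3+4+7" and d.period == 14

    def test_equality_via_canonical_form(self):
        assert Decomposition((4, 3, 3)).canonicalized() == Decomposition((3, 3, 4))

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            DistanceAlphabet(())
        with pytest.raises(ValueError):
            DistanceAlphabet((1, 3))
        with pytest.raises(ValueError):
            DistanceAlphabet((4, 3))
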