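"""Hyperoctahedral isometries: enumeration, stabilizers, colorings, swaps."""

import itertools

import numpy as np
import pytest

from aars_symmetry.aars_annotation import Coloring, color_codons
from aars_symmetry.code_models import build_stage, pattern_set
from aars_symmetry.codon_algebra import (
    DEFAULT_SCHEME,
    all_codons,
    codon_to_index,
    encode_codon,
    hamming_bit,
    index_to_codon,
)
from aars_symmetry.symmetry_analysis import (
    IsometryElement,
    class_swap_isometries,
    color_preserving_group,
    identity_element,
    isometry_group,
    mirror_symmetry_report,
    partition_correspondence,
    stabilizer_of_set,
    wc_complement_element,
)


def naive_apply(sigma, flip, x, n=6):
    """Independent re-implementation of the isometry action on indices."""
    bits = [(x >> (n - 1 - j)) & 1 for j in range(n)]
    out = [bits[sigma[j]] ^ ((flip >> (n - 1 - j)) & 1) for j in range(n)]
    return sum(b << (n - 1 - j) for j, b in enumerate(out))


def naive_stabilizer_orders(codon_set, n=6):
    """Brute-force oracle: loop over all 2^n * n! signed permutations."""
    idx = frozenset(codon_to_index(c) for c in codon_set)
    count = 0
    for sigma in itertools.permutations(range(n)):
        for flip in range(1 << n):
            if frozenset(naive_apply(sigma, flip, x, n) for x in idx) == idx:
                count += 1
    return count


class TestGroupEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 8), (3, 48), (6, 46080)])
    def test_full_order(self, n, expected):
        assert isometry_group(n, "full").order == expected

    def test_codon_structured_order(self, structured_group):
        assert structured_group.order == 3072

    def test_structured_is_subgroup_of_full(self, full_group, structured_group):
        full = {(e.sigma, e.flip) for e in full_group}
        assert all((e.sigma, e.flip) in full for e in structured_group)

    def test_refuses_oversized_enumeration(self):
        with pytest.raises(ValueError, match="n <= 6"):
            isometry_group(7, "full")

    def test_closure_exhaustive_small(self):
        assert isometry_group(3, "full").is_closed()

    def test_closure_sampled_at_n6(self, full_group):
        assert full_group.is_closed(sample=300, seed=0)

    def test_structured_closure_sampled(self, structured_group):
        assert structured_group.is_closed(sample=300, seed=1)

    def test_inverses_and_identity(self):
        g3 = isometry_group(3, "full")
        assert sum(e.is_identity for e in g3) == 1
        for e in g3:
            assert e.compose(e.inverse()).is_identity
            assert e.inverse().compose(e).is_identity

    def test_associativity_spot_check(self, full_group):
        rng = np.random.default_rng(0)
        elems = full_group.elements
        for _ in range(50):
            a, b, c = (elems[i] for i in rng.integers(0, len(elems), 3))
            assert a.compose(b).compose(c) == a.compose(b.compose(c))

    def test_perm_table_matches_elementwise_action(self, full_group):
        rng = np.random.default_rng(2)
        for g in rng.integers(0, full_group.order, 40):
            e = full_group.elements[g]
            x = int(rng.integers(0, 64))
            assert full_group.perm_table[g, x] == e.apply_index(x) == naive_apply(e.sigma, e.flip, x)


class TestIsometryProperties:
    def test_distance_preservation(self, full_group):
        """d(g(x), g(y)) = d(x, y) for random elements and codon pairs."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            e = full_group.elements[rng.integers(0, full_group.order)]
            x, y = rng.integers(0, 64, 2)
            c1, c2 = index_to_codon(int(x)), index_to_codon(int(y))
            d_before = hamming_bit(encode_codon(c1), encode_codon(c2))
            d_after = hamming_bit(
                encode_codon(e.apply_codon(c1)), encode_codon(e.apply_codon(c2))
            )
            assert d_before == d_after

    def test_wc_complement_is_an_element_mapping_rny_to_ynr(self, full_group):
        wc = wc_complement_element()
        assert any(e == wc for e in full_group)
        rny = pattern_set("RNY").members
        assert {wc.apply_codon(c) for c in rny} == pattern_set("YNR").members
        assert wc.compose(wc).is_identity

    def test_element_order(self):
        assert identity_element().order() == 1
        assert wc_complement_element().order() == 2


class TestStabilizers:
    def test_whole_space_stabilizer_is_everything(self, full_group):
        stab = stabilizer_of_set(all_codons(), full_group)
        assert stab.order == full_group.order

    @pytest.mark.parametrize("pattern", ["RRR", "RRY", "RYR", "RYY", "YRR", "YRY", "YYR", "YYY"])
    def test_cube_stabilizers_match_naive_oracle(self, full_group, pattern):
        stab = stabilizer_of_set(pattern_set(pattern).members, full_group)
        assert stab.order == naive_stabilizer_orders(pattern_set(pattern).members)
        assert full_group.order % stab.order == 0  # Lagrange

    def test_rny_stabilizer(self, full_group):
        """A 4-face's stabilizer: free 4-cube symmetries times the two
        value-respecting moves of the fixed coordinate pair."""
        stab = stabilizer_of_set(pattern_set("RNY").members, full_group)
        assert stab.order == 768 == 2 * (2**4 * 24)
        assert stab.is_closed(sample=200, seed=4)

    def test_stabilizer_orders_divide_group_order(self, full_group, table):
        for name in ("RNY", "EXT1", "EXT2", "SGC"):
            stab = stabilizer_of_set(build_stage(name, table).codons, full_group)
            assert full_group.order % stab.order == 0


class TestColorPreservation:
    def test_constant_coloring_equals_set_stabilizer(self, full_group):
        codons = sorted(pattern_set("RNY").members)
        coloring = Coloring(colors={c: "I" for c in codons})
        pres = color_preserving_group(coloring, full_group)
        stab = stabilizer_of_set(codons, full_group)
        assert pres.order == stab.order

    def test_bit_coloring_contains_constructed_elements(self, full_group):
        """Coloring by the value of bit 0 is preserved by any element that
        keeps coordinate 0 in place without flipping it."""
        coloring = Coloring(
            colors={c: ("I" if encode_codon(c).bits[0] else "II") for c in all_codons()}
        )
        pres = color_preserving_group(coloring, full_group)
        keep = {(e.sigma, e.flip) for e in pres}
        for e in full_group.elements[:2000]:
            if e.sigma[0] == 0 and not (e.flip >> 5) & 1:
                assert (e.sigma, e.flip) in keep

    def test_cube_color_groups_match_naive_oracle(self, full_group, table, classification):
        """Loop-based oracle over all 46,080 elements for two cubes."""
        for pattern in ("RYR", "YRR"):
            codons = pattern_set(pattern).members
            coloring = color_codons(codons, table, classification, "class_II")
            pres = color_preserving_group(coloring, full_group)
            color_map = {codon_to_index(c): col for c, col in coloring.colors.items()}
            count = 0
            for e in full_group:
                ok = True
                for x, col in color_map.items():
                    y = naive_apply(e.sigma, e.flip, x)
                    if color_map.get(y) != col:
                        ok = False
                        break
                if ok:
                    count += 1
            assert pres.order == count

    def test_sgc_coloring_subgroup_reported(self, full_group, table, classification):
        coloring = color_codons(all_codons(), table, classification, "class_II")
        pres = color_preserving_group(coloring, full_group)
        assert pres.order >= 1
        orders = pres.element_order_multiset()
        assert sum(orders.values()) == pres.order


class TestClassSwap:
    def test_constructed_swap_is_found(self, full_group):
        """Splitting codons by the value of bit 0 makes the bit-0 flip an
        exact Class I <-> Class II swap."""
        coloring = Coloring(
            colors={c: ("I" if encode_codon(c).bits[0] else "II") for c in all_codons()}
        )
        result = class_swap_isometries(coloring, full_group)
        flip_bit0 = IsometryElement(tuple(range(6)), 0b100000)
        assert result.count > 0
        assert flip_bit0 in result.elements

    def test_swap_coset_size_equals_preserving_order(self, full_group):
        coloring = Coloring(
            colors={c: ("I" if encode_codon(c).bits[0] else "II") for c in all_codons()}
        )
        pres = color_preserving_group(coloring, full_group)
        swaps = class_swap_isometries(coloring, full_group)
        assert swaps.count == pres.order

    def test_cardinality_mismatch_short_circuits(self, full_group):
        coloring = Coloring(colors={"AAA": "I", "AAC": "II", "AAG": "II"})
        result = class_swap_isometries(coloring, full_group)
        assert result.count == 0
        assert "cardinality mismatch" in result.reason

    def test_sgc_exhaustive_outcome(self, full_group, table, classification):
        """The SGC codon-level classes have 29 and 32 codons, so no
        isometry can exchange them; the search reports that honestly."""
        coloring = color_codons(all_codons(), table, classification, "class_II")
        result = class_swap_isometries(coloring, full_group)
        assert result.count == 0
        assert "cardinality mismatch" in result.reason

    def test_swap_results_empty_or_coset_on_null_colorings(self, full_group):
        """Property: across random two-colorings of the 6-cube the swap set
        is empty or exactly a coset of the color-preserving subgroup."""
        rng = np.random.default_rng(5)
        codons = all_codons()
        for _ in range(10):
            labels = rng.permutation([("I" if i < 32 else "II") for i in range(64)])
            coloring = Coloring(colors=dict(zip(codons, labels)))
            swaps = class_swap_isometries(coloring, full_group)
            pres = color_preserving_group(coloring, full_group)
            assert swaps.count in (0, pres.order)


class TestPartitionCorrespondence:
    def test_identity_partition_contains_identity(self, full_group):
        ro = [pattern_set(p).members for p in ("NAN", "NGN", "NUN", "NCN")]
        result = partition_correspondence(ro, ro, full_group)
        assert any(m.element.is_identity for m in result.matches)

    def test_ro_to_ry_partition_is_realized(self, full_group):
        """The middle-base partition maps onto the R/Y pattern partition
        within the isometry group (the piecewise automorphism is an
        isometry)."""
        ro = [pattern_set(p).members for p in ("NAN", "NGN", "NUN", "NCN")]
        ry = [pattern_set(p).members for p in ("RNR", "YNR", "RNY", "YNY")]
        result = partition_correspondence(ro, ry, full_group)
        assert len(result.matches) > 0
        # every match induces a bijection of the four blocks
        for m in result.matches[:20]:
            assert sorted(m.block_map) == [0, 1, 2, 3]

    def test_block_size_mismatch_reported(self, full_group):
        a = [pattern_set("RNY").members, frozenset(all_codons()) - pattern_set("RNY").members]
        b = [pattern_set("NNY").members, pattern_set("NNR").members]
        result = partition_correspondence(a, b, full_group)
        assert not result.matches
        assert "block-size" in result.reason


class TestMirrorReport:
    def test_rny_report_conservation(self, table, classification):
        stage = build_stage("RNY", table)
        rep = mirror_symmetry_report(stage, table, classification)
        assert rep.n_codons == 16
        assert sum(rep.color_counts.values()) == 16

    def test_swap_field_present_for_ext2_and_sgc(self, table, classification):
        for name in ("EXT2", "SGC"):
            rep = mirror_symmetry_report(build_stage(name, table), table, classification)
            assert rep.class_swap_count >= 0
            assert rep.color_preserving_order >= 1

    def test_report_is_deterministic(self, table, classification):
        stage = build_stage("EXT2", table)
        a = mirror_symmetry_report(stage, table, classification)
        b = mirror_symmetry_report(stage, table, classification)
        assert a.to_json() == b.to_json()

    def test_structured_universe_flag(self, table, classification):
        rep = mirror_symmetry_report(
            build_stage("RNY", table), table, classification, universe="codon-structured"
        )
        assert rep.universe_order == 3072
        assert rep.stabilizer_order <= 3072
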