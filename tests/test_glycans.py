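"""Glycan compositions, Y ladders, coverage normalizer, decoys."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycosearch.chem import residue_mass
from glycosearch.glycans import (
    DECOY_SHIFT_HIGH,
    DECOY_SHIFT_LOW,
    GlycanComposition,
    GlycanParseError,
    approx_size,
    coverage_normalizer,
    generate_y_ladder,
    glycan_coverage,
    make_decoy_ladder,
    parse_composition,
)

from oracle_trees import (
    distinct_y_fragment_masses,
    fixture_topologies,
    tree_composition,
)


class TestParsing:
    def test_braced_dialect(self):
        g = parse_composition("{Hex:5; HexNAc:2}")
        assert g.as_dict() == {"Hex": 5, "HexNAc": 2}
        assert g.cardinality == 7

    def test_concatenated_dialect(self):
        g = parse_composition("HexNAc(2)Hex(5)")
        assert g.as_dict() == {"Hex": 5, "HexNAc": 2}

    def test_single_hexnac_mass_matches_reference(self):
        assert parse_composition("{HexNAc:1}").mass == pytest.approx(203.0794, abs=1e-4)

    def test_mixed_composition_mass(self):
        # sum of Hex and dHex residue masses from elemental compositions
        assert parse_composition("{Hex:1; dHex:1}").mass == pytest.approx(308.1107, abs=1e-4)

    @pytest.mark.parametrize("bad", ["{Foo:1}", "{Hex:-2}", "Hex(1]x", "{Hex 3}"])
    def test_malformed_text_raises_with_token(self, bad):
        with pytest.raises(GlycanParseError):
            parse_composition(bad)


class TestResidueMasses:
    @pytest.mark.parametrize(
        "name,expected",
        [("HexNAc", 203.0794), ("Hex", 162.0528), ("dHex", 146.0579)],
    )
    def test_printed_reference_values(self, name, expected):
        assert residue_mass(name) == pytest.approx(expected, abs=1e-4)

    def test_unknown_symbol(self):
        with pytest.raises(KeyError):
            residue_mass("Xyzzy")


class TestApproxSize:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"Hex": 5, "HexNAc": 2}, 7),
            ({"Hex": 5, "HexNAc": 4, "dHex": 1, "NeuAc": 2}, 10),
            ({"HexNAc": 2, "Hex": 3, "dHex": 2, "NeuAc": 1}, 6),
            ({"NeuAc": 1}, 0),  # floored at zero
        ],
    )
    def test_examples(self, counts, expected):
        assert approx_size(GlycanComposition.from_dict(counts)) == expected


class TestCoverageNormalizer:
    def test_small_nonfucosylated_equals_size(self):
        # n_g = 7, no dHex: half-n-log-n is below n, so d_g = n_g
        g = GlycanComposition.from_dict({"Hex": 5, "HexNAc": 2})
        assert coverage_normalizer(g) == pytest.approx(7.0)

    def test_fucosylated_branch(self):
        # n_g = 10 with dHex: full n ln n
        g = GlycanComposition.from_dict({"Hex": 5, "HexNAc": 3, "dHex": 3})
        assert approx_size(g) == 10
        assert coverage_normalizer(g) == pytest.approx(10 * math.log(10), abs=1e-3)

    def test_nonfucosylated_above_breakpoint(self):
        g = GlycanComposition.from_dict({"Hex": 6, "HexNAc": 2})
        assert coverage_normalizer(g) == pytest.approx(4 * math.log(8), abs=1e-3)

    def test_breakpoint_is_seven(self):
        # the largest n_g with d_g = n_g on the non-fucosylated branch
        largest = 0
        for n in range(1, 21):
            g = GlycanComposition.from_dict({"Hex": n})
            if coverage_normalizer(g) == float(n):
                largest = n
        assert largest == 7

    @given(
        hexn=st.integers(0, 8), hexose=st.integers(0, 10),
        dhex=st.integers(0, 3), neuac=st.integers(0, 4),
    )
    @settings(deadline=None, max_examples=60)
    def test_dg_at_least_ng_and_monotone(self, hexn, hexose, dhex, neuac):
        g = GlycanComposition.from_dict(
            {"HexNAc": hexn, "Hex": hexose, "dHex": dhex, "NeuAc": neuac}
        )
        n = approx_size(g)
        d = coverage_normalizer(g)
        assert d >= max(n, 1) - 1e-12
        bigger = GlycanComposition.from_dict(
            {"HexNAc": hexn, "Hex": hexose + 1, "dHex": dhex, "NeuAc": neuac}
        )
        assert coverage_normalizer(bigger) >= d - 1e-12


class TestYLadder:
    def test_core_motif_ladder(self):
        lad = generate_y_ladder(parse_composition("{Hex:3; HexNAc:2}"))
        masses = sorted(f.mass_delta for f in lad)
        expected = sorted(
            [
                0.0,
                residue_mass("HexNAc"),
                2 * residue_mass("HexNAc"),
                2 * residue_mass("HexNAc") + residue_mass("Hex"),
                2 * residue_mass("HexNAc") + 2 * residue_mass("Hex"),
                2 * residue_mass("HexNAc") + 3 * residue_mass("Hex"),
            ]
        )
        assert len(masses) == 6
        assert np.allclose(masses, expected, atol=1e-6)
        assert all(f.is_core for f in lad)

    def test_reducing_end_dhex_decoration(self):
        bare = generate_y_ladder(parse_composition("{Hex:3; HexNAc:2}"))
        fuc = generate_y_ladder(parse_composition("{Hex:3; HexNAc:2; dHex:1}"))
        fuc_masses = {round(f.mass_delta, 4) for f in fuc}
        for f in bare:
            if f.glycan_size == 0:
                continue
            assert round(f.mass_delta + residue_mass("dHex"), 4) in fuc_masses

    def test_sialic_acids_are_labile(self):
        lad = generate_y_ladder(parse_composition("{NeuAc:2; Hex:5; HexNAc:4}"))
        assert all(f.attached_composition["NeuAc"] == 0 for f in lad)

    def test_y0_always_present_and_deterministic(self):
        g = parse_composition("{Hex:6; HexNAc:5; dHex:1}")
        lad1 = generate_y_ladder(g)
        lad2 = generate_y_ladder(g)
        assert lad1 == lad2
        assert any(f.glycan_size == 0 for f in lad1)

    def test_combination_only_mode_for_small_o_glycans(self):
        g = parse_composition("{HexNAc:1; Hex:1}")
        lad = generate_y_ladder(g)
        assert {round(f.mass_delta, 4) for f in lad} == {
            0.0,
            round(residue_mass("HexNAc"), 4),
            round(residue_mass("Hex"), 4),
            round(residue_mass("HexNAc") + residue_mass("Hex"), 4),
        }


class TestDecoyLadder:
    def test_y0_y1_unshifted_others_bounded(self):
        g = parse_composition("{Hex:5; HexNAc:4; NeuAc:1}")
        decoy = make_decoy_ladder(g, seed=13)
        for frag, shift in zip(decoy.fragments, decoy.shifts):
            if frag.glycan_size <= 1:
                assert shift == 0.0
            else:
                assert DECOY_SHIFT_LOW <= shift <= DECOY_SHIFT_HIGH

    def test_reproducible_from_seed(self):
        g = parse_composition("{Hex:5; HexNAc:4}")
        assert make_decoy_ladder(g, 5).shifts == make_decoy_ladder(g, 5).shifts
        assert make_decoy_ladder(g, 5).shifts != make_decoy_ladder(g, 6).shifts

    def test_shift_distribution_moments(self):
        rng = np.random.default_rng(0)
        shifts = []
        g = parse_composition("{Hex:7; HexNAc:6; dHex:2}")
        seed = 0
        while len(shifts) < 10_000:
            d = make_decoy_ladder(g, seed)
            shifts.extend(s for f, s in zip(d.fragments, d.shifts) if f.glycan_size > 1)
            seed += 1
        shifts = np.array(shifts[:10_000])
        assert shifts.min() >= 1.0
        assert shifts.max() <= 30.0
        assert abs(shifts.mean() - 15.5) < 0.2


class TestGlycanCoverage:
    def test_partial_match_fraction(self):
        g = parse_composition("{Hex:5; HexNAc:2}")
        lad = generate_y_ladder(g)
        matched = [f.mass_delta for f in lad[:5]]
        cov, _ = glycan_coverage(matched, g, ladder=lad)
        assert cov == pytest.approx(5 / 7, abs=1e-9)

    def test_no_matches(self):
        g = parse_composition("{Hex:5; HexNAc:2}")
        assert glycan_coverage([], g) == (0.0, 0.0)

    def test_all_core_matched(self):
        g = parse_composition("{Hex:5; HexNAc:2}")
        lad = generate_y_ladder(g)
        core = [f.mass_delta for f in lad if f.is_core]
        _, cov_core = glycan_coverage(core, g, ladder=lad)
        assert cov_core == 1.0

    def test_adding_a_match_never_decreases_coverage(self):
        g = parse_composition("{Hex:6; HexNAc:4; dHex:1}")
        lad = generate_y_ladder(g)
        masses = [f.mass_delta for f in lad]
        prev = (0.0, 0.0)
        for k in range(len(masses) + 1):
            cov = glycan_coverage(masses[:k], g, ladder=lad)
            assert cov[0] >= prev[0] and cov[1] >= prev[1]
            assert 0.0 <= cov[0] <= 1.0
            prev = cov


class TestTopologyOracleEnvelope:
    """The exact fragment counts of explicit tree topologies lie within the
    approximation envelope used by the coverage normalizer."""

    @pytest.mark.parametrize("name,tree", fixture_topologies())
    def test_upper_bound_encloses_exact_count(self, name, tree):
        g = tree_composition(tree)
        n = approx_size(g)
        exact = distinct_y_fragment_masses(tree)
        assert exact <= math.ceil(n * math.log(n))

    @pytest.mark.parametrize(
        "name,tree", [(n, t) for n, t in fixture_topologies() if n.startswith("complex")]
    )
    def test_half_bound_holds_for_complex_type(self, name, tree):
        g = tree_composition(tree)
        n = approx_size(g)
        exact = distinct_y_fragment_masses(tree)
        assert exact >= 0.5 * n * math.log(n)

    def test_high_mannose_falls_below_half_bound(self):
        # homogeneous Y ladders: the known exception to the lower bound
        trees = dict(fixture_topologies())
        tree = trees["high-mannose-Man9"]
        g = tree_composition(tree)
        n = approx_size(g)
        assert distinct_y_fragment_masses(tree) < 0.5 * n * math.log(n)
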