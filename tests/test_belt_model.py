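"""Geometry of the idealized antiparallel double belt."""
import math

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beltlink as bl
from beltlink.belt_model import (
    default_site_azimuths,
    helix,
    load_helices,
    predict_spacing,
)
from beltlink.errors import InvalidGeometryError


class TestBuildDoubleBelt:
    @pytest.mark.parametrize(
        "n,circ,expected_rise",
        [(4, 40.0, 10.0), (243, 300.0, 300.0 / 243.0)],
    )
    def test_rise_and_anchor_count(self, n, circ, expected_rise):
        belt = bl.build_double_belt(n, circ, belt_separation=10.0)
        assert belt.rise_per_residue == pytest.approx(expected_rise)
        assert belt.coords_a.shape == (n, 3) and belt.coords_b.shape == (n, 3)
        # consecutive intra-chain anchors are one arc step apart
        for coords in (belt.coords_a, belt.coords_b):
            chords = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            expected_chord = 2 * belt.radius * math.sin(belt.delta_theta / 2)
            assert np.allclose(chords, expected_chord)

    def test_chains_on_parallel_circles_opposite_direction(self, wt_belt):
        ra = np.hypot(wt_belt.coords_a[:, 0], wt_belt.coords_a[:, 1])
        rb = np.hypot(wt_belt.coords_b[:, 0], wt_belt.coords_b[:, 1])
        assert np.allclose(ra, wt_belt.radius) and np.allclose(rb, wt_belt.radius)
        assert np.allclose(wt_belt.coords_a[:, 2], +wt_belt.belt_separation / 2)
        assert np.allclose(wt_belt.coords_b[:, 2], -wt_belt.belt_separation / 2)
        # azimuth increases along chain A, decreases along chain B
        da = np.diff([wt_belt.azimuth("A", r) for r in range(10, 20)])
        db = np.diff([wt_belt.azimuth("B", r) for r in range(10, 20)])
        assert np.all(da > 0) and np.all(db < 0)

    def test_registry_phasing_gives_partners_identical_azimuth(self, wt_belt):
        a121 = wt_belt.anchor("A", 121)
        b142 = wt_belt.anchor("B", 142)
        assert np.allclose(a121[:2], b142[:2])

    def test_nonpositive_circumference_rejected(self):
        with pytest.raises(InvalidGeometryError):
            bl.build_double_belt(10, 0.0)
        with pytest.raises(InvalidGeometryError):
            bl.build_double_belt(0, 100.0)


class TestContinuousIndex:
    @pytest.mark.parametrize(
        "chain,res,expected", [("A", 1, 1), ("B", 1, 244), ("B", 243, 486)]
    )
    def test_convention(self, wt_belt, chain, res, expected):
        assert wt_belt.continuous_index(chain, res) == expected

    def test_bijection_round_trip(self, wt_belt):
        seen = set()
        for chain in "AB":
            for res in range(1, 244):
                ci = wt_belt.continuous_index(chain, res)
                assert wt_belt.from_continuous(ci) == (chain, res)
                seen.add(ci)
        assert seen == set(range(1, 487))

    @pytest.mark.parametrize("chain,res", [("A", 0), ("A", 244), ("C", 5)])
    def test_out_of_range(self, wt_belt, chain, res):
        with pytest.raises(IndexError):
            wt_belt.continuous_index(chain, res)


class TestRegistryPartner:
    def test_helix5_maps_onto_itself_and_4_faces_6(self, wt_belt):
        assert wt_belt.registry_partner(121) == 142
        assert wt_belt.registry_partner(99) == 164  # helix 4 start faces helix 6 end

    @given(res=st.integers(min_value=20, max_value=243))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, wt_belt, res):
        p = wt_belt.registry_partner(res)
        if p is not None:
            assert wt_belt.registry_partner(p) == res

    def test_no_partner_beyond_belt_end(self, wt_belt):
        # partner(10) = 253 > 243: off the end of the opposite monomer
        assert wt_belt.registry_partner(10) is None
        assert wt_belt.registry_partner(243) == 20

    def test_partners_share_azimuth_for_any_registry_constant(self):
        belt = bl.build_double_belt(100, 200.0, registry_constant=77)
        for res in (10, 40, 70):
            p = belt.registry_partner(res)
            if p is None:
                continue
            assert belt.azimuth("A", res) == pytest.approx(belt.azimuth("B", p))


class TestInsertSegmentRepeat:
    def test_helix5_duplication_lengths(self, wt_belt):
        result = bl.insert_segment_repeat(wt_belt, helix("H5"))
        assert result.belt.n_residues_per_monomer == 265
        assert result.belt.rise_per_residue == pytest.approx(wt_belt.rise_per_residue)
        assert result.belt.circumference == pytest.approx(
            wt_belt.circumference + 22 * wt_belt.rise_per_residue
        )

    def test_renumbering_map(self, wt_belt):
        result = bl.insert_segment_repeat(wt_belt, helix("H5"))
        m = result.old_to_new
        assert m[120] == 120 and m[142] == 142  # up to the segment end: unchanged
        assert m[143] == 165 and m[243] == 265  # downstream shifts by 22

    def test_effective_rise_gives_measured_circumference_growth(self):
        # with the effective rise implied by the mutant measurement (~1.09 Å)
        belt = bl.build_double_belt(243, 243 * 1.09)
        result = bl.insert_segment_repeat(belt, helix("H5"))
        assert result.belt.circumference - belt.circumference == pytest.approx(
            23.98, abs=0.01
        )

    def test_single_residue_segment(self, wt_belt):
        seg = bl.HelixSegment("X", 50, 50)
        result = bl.insert_segment_repeat(wt_belt, seg)
        assert result.belt.n_residues_per_monomer == 244
        assert result.belt.circumference - wt_belt.circumference == pytest.approx(
            wt_belt.rise_per_residue
        )

    def test_out_of_range_segment_rejected(self, wt_belt):
        with pytest.raises(InvalidGeometryError):
            bl.insert_segment_repeat(wt_belt, bl.HelixSegment("X", 240, 250))


class TestPredictSpacing:
    def test_antipodal_chord_equals_diameter(self, wt_belt):
        # site centers half a belt apart, no radial offset
        q = 243 / 4
        sp = predict_spacing(wt_belt, (q, 263 - q), (q + 243 / 2, 263 - q - 243 / 2), 0.0)
        assert sp.chord == pytest.approx(300.0 / math.pi, abs=1e-6)

    def test_chord_never_exceeds_arc(self, wt_belt):
        for off in (0.0, 10.0, 40.0):
            for r2 in (120.0, 150.5, 200.0):
                sp = predict_spacing(wt_belt, (109.5, 153.5), (r2, 263 - r2), off)
                assert sp.chord <= sp.arc + 1e-12

    def test_flat_belt_limit_chord_approaches_arc(self):
        # fixed arc separation (44 residues at fixed rise), growing radius:
        # the belt flattens locally and chord/arc -> 1
        rise = 300.0 / 243.0
        ratios = []
        for n in (243, 2430, 24300):
            belt = bl.build_double_belt(n, n * rise, registry_constant=263)
            sp = predict_spacing(belt, (109.5, 153.5), (153.5, 109.5), 0.0)
            assert sp.arc == pytest.approx(44 * rise)
            ratios.append(sp.chord / sp.arc)
        assert ratios[0] < ratios[1] < ratios[2] < 1.0
        assert ratios[2] == pytest.approx(1.0, abs=1e-4)

    def test_helix5_duplication_shifts_site_spacing_by_measured_amount(self):
        """WT and mutant belts at their measured circumferences: the site
        chord grows by ~26 Å (the measured ligand-spacing shift)."""
        wt = bl.build_double_belt(243, 300.0)
        mut = bl.build_double_belt(265, 324.0, registry_constant=285)
        sp_wt = predict_spacing(wt, (109.5, 153.5), (153.5, 109.5))
        sp_mut = predict_spacing(mut, (109.5, 175.5), (175.5, 109.5))
        assert sp_mut.chord - sp_wt.chord == pytest.approx(26.0, abs=3.0)


class TestCircumferenceDiameter:
    @pytest.mark.parametrize("d,expected", [(94.0, 295.3), (300.0 / math.pi, 300.0)])
    def test_forward(self, d, expected):
        assert bl.circumference_from_diameter(d) == pytest.approx(expected, abs=0.05)

    def test_inverse_and_round_trip(self):
        assert bl.diameter_from_circumference(324.0) == pytest.approx(103.13, abs=0.01)
        for d in (10.0, 94.0, 1234.5):
            c = bl.circumference_from_diameter(d)
            assert bl.diameter_from_circumference(c) == pytest.approx(d, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(InvalidGeometryError):
            bl.circumference_from_diameter(bad)
        with pytest.raises(InvalidGeometryError):
            bl.diameter_from_circumference(bad)


class TestHelixTableAndExport:
    def test_packaged_helix_bounds(self):
        assert (helix("H4").start_residue, helix("H4").end_residue) == (99, 120)
        assert (helix("H5").start_residue, helix("H5").end_residue) == (121, 142)
        assert (helix("H6").start_residue, helix("H6").end_residue) == (143, 164)

    def test_user_override_table(self, tmp_path):
        p = tmp_path / "helices.tsv"
        p.write_text("id\tstart\tend\nHX\t5\t10\n")
        (seg,) = load_helices(p)
        assert seg.id == "HX" and len(seg) == 6

    def test_site_azimuths_are_antipodal_ish(self, wt_belt):
        az_a, az_b = default_site_azimuths(wt_belt)
        d = abs((az_b - az_a + math.pi) % (2 * math.pi) - math.pi)
        # sites flank the helix-5/5 block: 44 residues of arc apart
        assert d == pytest.approx(44 * wt_belt.delta_theta, abs=1e-9)

    def test_pdb_export_round_trip(self, wt_belt, tmp_path):
        path = tmp_path / "belt.pdb"
        wt_belt.to_pdb(path)
        st_ = gemmi.read_structure(str(path))
        chains = {c.name: len(c) for c in st_[0]}
        assert chains == {"A": 243, "B": 243}
        first = st_[0]["A"][0][0]
        assert np.allclose(
            [first.pos.x, first.pos.y, first.pos.z], wt_belt.coords_a[0], atol=1e-2
        )
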