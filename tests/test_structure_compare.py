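import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechanomem import structure_compare as sc
from mechanomem import synthetic as syn
from mechanomem.io_formats import AtomModel, EmptySelectionError, SelectionSpec

from conftest import make_atom, poly_ala_model


def two_sphere_sasa(r1, r2, d, probe):
    """Analytic SASA of two intersecting probe-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * (R1**2 + R2**2)
    # spherical cap buried on each sphere
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return (4 * math.pi * R1**2 - 2 * math.pi * R1 * h1
            + 4 * math.pi * R2**2 - 2 * math.pi * R2 * h2)


class TestSuperpose:
    def test_identity(self):
        coords = poly_ala_model(5).coords
        fit = sc.superpose(coords, coords)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert fit.angle_deg == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)

    def test_constructed_rotation_recovered(self):
        model = poly_ala_model(10)
        copy, _ = syn.make_rotated_copy(model, (0, 0, 1), 8.0)
        fit = sc.superpose(model.coords, copy.coords)
        assert fit.rmsd < 1e-9
        assert fit.angle_deg == pytest.approx(8.0, abs=1e-9)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(0, 0.5, size=(20, 3))
        assert sc.superpose(a, b).rmsd == pytest.approx(sc.superpose(b, a).rmsd)

    def test_rotation_matrix_is_proper(self):
        rng = np.random.default_rng(1)
        fit = sc.superpose(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.rotation @ fit.rotation.T, np.eye(3),
                                   atol=1e-9)

    def test_reflection_corrected_on_planar_points(self):
        # planar sets are mirror-degenerate without the determinant fix
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                        [2, 1, 0]], dtype=float)
        mirrored = pts * np.array([1, -1, 1])
        fit = sc.superpose(pts, mirrored)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(sc.DegenerateGeometryError):
            sc.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(sc.DegenerateGeometryError):
            sc.superpose(line, line)

    def test_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(0, 0.3, size=(15, 3))
        base = sc.superpose(a, b).rmsd
        model = AtomModel([make_atom(res_num=i + 1, xyz=b[i]) for i in range(15)])
        moved, _ = syn.make_rotated_copy(model, (1, 2, 3), 37.0, (5, -4, 2))
        assert sc.superpose(a, moved.coords).rmsd == pytest.approx(base, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.5, 179.0), st.integers(0, 10**6))
    def test_angle_recovery_random(self, angle, seed):
        rng = np.random.default_rng(seed)
        model = poly_ala_model(8)
        axis = rng.normal(size=3)
        copy, _ = syn.make_rotated_copy(model, axis, angle, rng.normal(size=3))
        fit = sc.superpose(model.coords, copy.coords)
        assert fit.angle_deg == pytest.approx(angle, abs=0.01)


class TestPairAtoms:
    def test_identical_models_all_paired(self):
        m = poly_ala_model(10)
        c1, c2, keys = sc.pair_atoms(m, SelectionSpec(), m, SelectionSpec())
        assert len(keys) == len(m)
        np.testing.assert_array_equal(c1, c2)

    def test_renumbered_offset(self):
        m1 = poly_ala_model(10)
        m2 = poly_ala_model(10, start=101)
        c1, c2, keys = sc.pair_atoms(m1, SelectionSpec(), m2, SelectionSpec(),
                                     residue_offset=-100)
        assert len(keys) == len(m1)

    def test_no_pairs_without_offset(self):
        m1 = poly_ala_model(10)
        m2 = poly_ala_model(10, start=101)
        with pytest.raises(EmptySelectionError):
            sc.pair_atoms(m1, SelectionSpec(), m2, SelectionSpec())

    def test_alignment_with_insertion(self):
        # chain B carries a 3-residue insertion; alignment pairs the rest
        m1 = poly_ala_model(20, atom_names=("CA",))
        m2 = poly_ala_model(23, atom_names=("CA",))
        c1, c2, keys = sc.pair_atoms(m1, SelectionSpec(), m2, SelectionSpec(),
                                     mode="by-alignment")
        assert len(keys) == 20

    def test_alignment_matches_by_key_on_identical(self):
        m = poly_ala_model(12, atom_names=("CA",))
        _, _, k_key = sc.pair_atoms(m, SelectionSpec(), m, SelectionSpec())
        _, _, k_aln = sc.pair_atoms(m, SelectionSpec(), m, SelectionSpec(),
                                    mode="by-alignment")
        assert len(k_key) == len(k_aln) == 12


class TestDomainRotation:
    @staticmethod
    def _two_domain_models(hinge_deg):
        anchor = poly_ala_model(12, chain="A")
        moving = poly_ala_model(12, chain="B", atom_names=("N", "CA", "CB"))
        shifted = moving.with_coords(moving.coords + np.array([0.0, 30.0, 0.0]))
        model_c = AtomModel(anchor.atoms + shifted.atoms)
        rotated, _ = syn.make_rotated_copy(shifted, (1, 1, 0), hinge_deg)
        model_e = AtomModel(anchor.atoms + rotated.atoms)
        return model_e, model_c

    def test_self_rotation_zero(self):
        m = poly_ala_model(12, chain="A")
        sel = SelectionSpec(chains=frozenset("A"))
        assert sc.domain_rotation(m, m, sel, sel) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_hinge(self):
        model_e, model_c = self._two_domain_models(8.0)
        angle = sc.domain_rotation(model_e, model_c,
                                   SelectionSpec(chains=frozenset("A")),
                                   SelectionSpec(chains=frozenset("B")))
        assert angle == pytest.approx(8.0, abs=0.01)

    def test_swap_anchor_moving_symmetric(self):
        model_e, model_c = self._two_domain_models(11.0)
        a1 = sc.domain_rotation(model_e, model_c,
                                SelectionSpec(chains=frozenset("A")),
                                SelectionSpec(chains=frozenset("B")))
        a2 = sc.domain_rotation(model_e, model_c,
                                SelectionSpec(chains=frozenset("B")),
                                SelectionSpec(chains=frozenset("A")))
        assert a1 == pytest.approx(a2, abs=0.01)

    def test_direction_symmetric(self):
        model_e, model_c = self._two_domain_models(8.0)
        fwd = sc.domain_rotation(model_e, model_c,
                                 SelectionSpec(chains=frozenset("A")),
                                 SelectionSpec(chains=frozenset("B")))
        rev = sc.domain_rotation(model_c, model_e,
                                 SelectionSpec(chains=frozenset("A")),
                                 SelectionSpec(chains=frozenset("B")))
        assert fwd == pytest.approx(rev, abs=1e-6)


class TestHelixGeometry:
    def test_straight(self):
        assert sc.helix_geometry(syn.make_helix(20)).bend_deg < 0.5

    @pytest.mark.parametrize("kink", [5.0, 9.0, 20.0])
    def test_kink_recovered(self, kink):
        coords = syn.make_helix(20, kink=kink)
        assert sc.helix_geometry(coords).bend_deg == pytest.approx(kink, abs=0.5)

    def test_rotation_invariance(self):
        coords = syn.make_helix(24, kink=9.0)
        model = AtomModel([make_atom(res_num=i + 1, xyz=c)
                           for i, c in enumerate(coords)])
        rotated, _ = syn.make_rotated_copy(model, (2, -1, 1), 73.0, (4, 5, 6))
        b1 = sc.helix_geometry(coords).bend_deg
        b2 = sc.helix_geometry(rotated.coords).bend_deg
        assert b1 == pytest.approx(b2, abs=1e-6)

    def test_axial_length(self):
        geo = sc.helix_geometry(syn.make_helix(20, rise=1.5))
        assert geo.axial_length == pytest.approx(28.5, abs=0.5)

    def test_too_few(self):
        with pytest.raises(ValueError):
            sc.helix_geometry(np.zeros((7, 3)))


class TestCentroidDistance:
    def test_three_four_five(self):
        assert sc.centroid_distance(np.array([[0.0, 0, 0]]),
                                    np.array([[3.0, 4, 0]])) == pytest.approx(5.0)

    def test_identical_sets(self):
        a = np.random.default_rng(3).normal(size=(9, 3))
        assert sc.centroid_distance(a, a) == 0.0

    def test_translated_helices(self):
        h = syn.make_helix(15)
        assert sc.centroid_distance(h, h + np.array([0, 11.0, 0])) == \
            pytest.approx(11.0, abs=1e-9)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            sc.centroid_distance(np.zeros((0, 3)), np.zeros((1, 3)))


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        model = AtomModel([make_atom(element="C")])
        _, total = sc.sasa(model)
        assert total == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)
        assert total == pytest.approx(120.76, abs=0.01)

    def test_engulfed_atom_zero(self):
        big = make_atom(atom_name="X", res_num=2, element="X")
        model = AtomModel([make_atom(element="C"), big])
        radii = dict(sc.DEFAULT_RADII, X=6.0)
        areas, _ = sc.sasa(model, radii=radii)
        assert areas[0] == 0.0

    def test_two_sphere_analytic(self):
        d = 2.5
        model = AtomModel([
            make_atom(element="C"),
            make_atom(res_num=2, element="O", xyz=(d, 0, 0)),
        ])
        _, total = sc.sasa(model, points=2000)
        assert total == pytest.approx(two_sphere_sasa(1.70, 1.52, d, 1.4),
                                      rel=0.01)

    @staticmethod
    def _helix_carbons():
        coords = syn.make_helix(12, rise=1.5, radius=2.3)
        return AtomModel([make_atom(res_num=i + 1, element="C", xyz=c)
                          for i, c in enumerate(coords)])

    def test_point_convergence(self):
        model = self._helix_carbons()
        _, a1 = sc.sasa(model, points=960)
        _, a2 = sc.sasa(model, points=1920)
        assert abs(a2 - a1) / a2 < 0.005

    def test_order_independence(self):
        model = poly_ala_model(6)
        reordered = AtomModel(model.atoms[::-1])
        _, a1 = sc.sasa(model)
        _, a2 = sc.sasa(reordered)
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_unknown_element_error(self):
        model = AtomModel([make_atom(atom_name="FE", res_name="FE", element="Fe")])
        with pytest.raises(ValueError, match="Fe"):
            sc.sasa(model)


class TestBuriedInterface:
    def _contact_model(self, gap):
        a = poly_ala_model(2, chain="A")
        b_atoms = poly_ala_model(2, chain="B").atoms
        b = AtomModel(b_atoms).with_coords(
            AtomModel(b_atoms).coords + np.array([0.0, gap, 0.0]))
        return AtomModel(a.atoms + b.atoms)

    def test_distant_parts_zero(self):
        model = self._contact_model(gap=50.0)
        area = sc.buried_interface_area(model, SelectionSpec(chains=frozenset("A")),
                                        SelectionSpec(chains=frozenset("B")))
        assert area.buried == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_parts(self):
        model = self._contact_model(gap=4.0)
        a1 = sc.buried_interface_area(model, SelectionSpec(chains=frozenset("A")),
                                      SelectionSpec(chains=frozenset("B")))
        a2 = sc.buried_interface_area(model, SelectionSpec(chains=frozenset("B")),
                                      SelectionSpec(chains=frozenset("A")))
        assert a1.buried == pytest.approx(a2.buried, abs=1e-9)
        assert a1.interface == pytest.approx(a1.buried / 2)

    def test_against_high_resolution_self_oracle(self):
        model = self._contact_model(gap=4.0)
        sel_a = SelectionSpec(chains=frozenset("A"))
        sel_b = SelectionSpec(chains=frozenset("B"))
        fast = sc.buried_interface_area(model, sel_a, sel_b, points=960)
        fine = sc.buried_interface_area(model, sel_a, sel_b, points=10000)
        assert fast.buried == pytest.approx(fine.buried, rel=0.02)
        assert fast.buried > 10.0     # the fixture genuinely makes contact

    def test_overlapping_selections_error(self):
        model = poly_ala_model(10)
        with pytest.raises(ValueError):
            sc.buried_interface_area(model, SelectionSpec(res_range=(1, 6)),
                                     SelectionSpec(res_range=(5, 10)))
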