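"""Unit and property tests for the FJC conformational descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgtkit.chain import ChainTrajectory, DegenerateGeometryError
from cgtkit.descriptors import (
    DescriptorConfig,
    backbone_dihedrals,
    descriptor_series,
    radius_of_gyration,
    sasa,
    segment_chain,
    segment_contacts,
    segment_vectors,
    sphere_points,
    sum_of_segment_angles,
)

from conftest import random_rotation


def straight_chain(n_beads=20, spacing=1.0):
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = np.arange(n_beads) * spacing
    return coords


class TestSegmentation:
    def test_20_beads_gives_6_segments_with_remainder(self):
        m = segment_chain(20, 3)
        assert m.n_segments == 6
        assert m.segment_index_ranges[0] == (0, 3)
        assert m.segment_index_ranges[-1] == (15, 18)  # beads 18,19 unassigned

    def test_exact_multiple_has_no_remainder(self):
        m = segment_chain(21, 3)
        assert m.n_segments == 7
        assert m.segment_index_ranges[-1] == (18, 21)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            segment_chain(5, 3)

    def test_segment_length_one_rejected(self):
        with pytest.raises(ValueError):
            segment_chain(20, 1)


class TestSegmentVectors:
    def test_straight_chain_vectors(self, segment_model):
        v = segment_vectors(straight_chain(20), segment_model)
        assert v.shape == (6, 3)
        np.testing.assert_allclose(v, np.tile([2.0, 0, 0], (6, 1)))

    def test_rotation_equivariance_translation_invariance(self, segment_model, rng):
        coords = rng.normal(size=(20, 3))
        Q = random_rotation(rng)
        shift = rng.normal(size=3)
        v0 = segment_vectors(coords, segment_model)
        v1 = segment_vectors(coords @ Q.T + shift, segment_model)
        np.testing.assert_allclose(v1, v0 @ Q.T, atol=1e-12)


class TestOmega:
    def test_collinear_chain_is_zero(self, segment_model):
        assert sum_of_segment_angles(straight_chain(20), segment_model) == 0.0

    def test_single_right_angle(self, segment_model):
        # first segment along x, remaining five along y: one 90-degree kink
        coords = np.zeros((20, 3))
        coords[:3, 0] = np.arange(3)
        coords[3:, 0] = 2.0
        coords[3:, 1] = np.arange(3, 20) - 2.0
        omega = sum_of_segment_angles(coords, segment_model)
        assert omega == pytest.approx(np.pi / 2, abs=1e-12)

    def test_zigzag_matches_per_pair_arccos_oracle(self, segment_model):
        # segment directions alternate +/-60 degrees from the x-axis
        angles = np.where(np.arange(6) % 2 == 0, np.pi / 6, -np.pi / 6)
        dirs = np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(6)]
        )
        coords = np.zeros((20, 3))
        pos = np.zeros(3)
        b = 0
        for s in range(6):
            for k in range(3):
                coords[b] = pos + k * dirs[s]
                b += 1
            pos = pos + 2.9 * dirs[s]  # break contact, keep direction
        coords[18] = coords[17] + dirs[-1]
        coords[19] = coords[18] + dirs[-1]
        omega = sum_of_segment_angles(coords, segment_model)
        # independent oracle: explicit pairwise arccos
        v = segment_vectors(coords, segment_model)
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        expected = sum(
            np.arccos(np.clip(u[i] @ u[i + 1], -1, 1)) for i in range(5)
        )
        assert omega == pytest.approx(expected, abs=1e-12)
        assert omega == pytest.approx(5 * np.pi / 3, abs=1e-9)

    def test_degenerate_segment_raises(self, segment_model):
        coords = straight_chain(20)
        coords[2] = coords[0]  # first segment endpoints coincide
        with pytest.raises(DegenerateGeometryError):
            sum_of_segment_angles(coords, segment_model)


class TestContacts:
    def test_extended_chain_has_no_contacts(self, segment_model):
        coords = straight_chain(20, spacing=0.25)
        assert segment_contacts(coords, segment_model, cutoff=0.8) == 0

    def test_collapsed_chain_counts_all_nonadjacent_pairs(self, segment_model, rng):
        coords = rng.uniform(-0.05, 0.05, size=(20, 3))
        # C(6,2) - 5 adjacent = 10
        assert segment_contacts(coords, segment_model, cutoff=0.8) == 10

    def test_monotone_in_cutoff(self, segment_model, rng):
        coords = rng.normal(scale=0.5, size=(20, 3))
        cutoffs = [0.05, 0.2, 0.5, 1.0, 3.0]
        nus = [segment_contacts(coords, segment_model, c) for c in cutoffs]
        assert nus == sorted(nus)

    def test_tiny_cutoff_gives_zero(self, segment_model, rng):
        coords = rng.normal(size=(20, 3))
        assert segment_contacts(coords, segment_model, cutoff=1e-9) == 0


class TestRg:
    def test_two_beads_half_distance(self):
        coords = np.array([[0.0, 0, 0], [1.4, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(0.7)

    def test_equilateral_triangle(self):
        c = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], dtype=float
        )
        assert radius_of_gyration(c) == pytest.approx(1 / np.sqrt(3), rel=1e-12)

    def test_coincident_beads_zero(self):
        assert radius_of_gyration(np.ones((5, 3))) == 0.0

    def test_mass_weighting(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        masses = np.array([3.0, 1.0])
        # com at 0.25; Rg^2 = (3*0.0625 + 1*0.5625)/4
        assert radius_of_gyration(coords, masses) == pytest.approx(
            np.sqrt(0.1875), rel=1e-12
        )


class TestSasa:
    def test_single_sphere_analytic(self):
        area = sasa(np.zeros((1, 4, 3))[0, :1], radii=0.20, probe_radius=0.14)
        exact = 4 * np.pi * 0.34**2
        assert area == pytest.approx(exact, rel=0.01)

    def test_far_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        area = sasa(coords, radii=0.25, probe_radius=0.14)
        assert area == pytest.approx(2 * 4 * np.pi * 0.39**2, rel=0.01)

    def test_buried_bead_contributes_nothing(self):
        # small bead at the centre of a much larger expanded sphere
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.01]])
        area = sasa(coords, radii=np.array([0.05, 1.0]), probe_radius=0.14)
        exact_big = 4 * np.pi * 1.14**2
        assert area == pytest.approx(exact_big, rel=0.01)

    def test_quadrature_error_shrinks_with_points(self):
        coords = np.array([[0.0, 0, 0], [0.45, 0, 0]])
        exact = None
        errs = []
        ref = sasa(coords, n_sphere_points=61440)
        for n in (240, 960, 3840):
            errs.append(abs(sasa(coords, n_sphere_points=n) - ref))
        assert errs[0] > errs[-1]

    def test_rotating_points_with_frame_is_exactly_invariant(self, rng):
        coords = rng.normal(scale=0.3, size=(8, 3))
        Q = random_rotation(rng)
        pts = sphere_points(960)
        a0 = sasa(coords, points=pts)
        a1 = sasa(coords @ Q.T, points=pts @ Q.T)
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_agrees_with_independent_implementation(self, templates):
        """Cross-check against biotite's Shrake-Rupley on a bead frame."""
        import biotite.structure as struc

        coords = templates[2]  # compact globule: plenty of burial
        atoms = struc.AtomArray(coords.shape[0])
        atoms.coord = coords * 10.0  # nm -> A
        atoms.chain_id = np.full(20, "A")
        atoms.res_id = np.arange(1, 21)
        atoms.res_name = np.full(20, "UNK")
        atoms.atom_name = np.full(20, "CA")
        atoms.element = np.full(20, "C")
        ref = struc.sasa(
            atoms,
            probe_radius=1.4,
            vdw_radii=np.full(20, 2.5),
            point_number=1000,
        ).sum() / 100.0  # A^2 -> nm^2
        ours = sasa(coords, radii=0.25, probe_radius=0.14, n_sphere_points=960)
        assert ours == pytest.approx(ref, rel=0.03)


class TestDihedrals:
    def test_planar_trans_is_pi(self):
        coords = np.array(
            [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float
        )
        phi = backbone_dihedrals(coords)
        assert abs(phi[0]) == pytest.approx(np.pi)

    def test_planar_cis_is_zero(self):
        coords = np.array(
            [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float
        )
        assert backbone_dihedrals(coords)[0] == pytest.approx(0.0, abs=1e-12)

    def test_mirror_negates_dihedrals(self, rng):
        coords = rng.normal(size=(10, 3))
        phi = backbone_dihedrals(coords)
        mirrored = coords * np.array([1, 1, -1])
        phi_m = backbone_dihedrals(mirrored)
        # +pi maps to -pi which wraps back to +pi, exclude near-pi values
        interior = np.abs(np.abs(phi) - np.pi) > 1e-6
        np.testing.assert_allclose(phi_m[interior], -phi[interior], atol=1e-10)

    def test_collinear_triple_raises(self):
        with pytest.raises(DegenerateGeometryError):
            backbone_dihedrals(straight_chain(5))

    def test_count_is_beads_minus_three(self, templates):
        assert backbone_dihedrals(templates[0]).shape == (17,)


class TestDescriptorSeries:
    def test_zero_noise_emission_gives_constant_descriptors(self, templates):
        from cgtkit.synthetic import emit_conformations

        seq = np.array([1] * 5)
        traj = emit_conformations(seq, templates, noise_sd=0.0)
        df = descriptor_series(traj, DescriptorConfig(n_sphere_points=240))
        for col in ("rg_nm", "sasa_nm2", "omega_rad", "nu"):
            assert df[col].nunique() == 1

    def test_concatenation_homomorphism(self, templates, rng):
        from cgtkit.synthetic import emit_conformations

        cfg = DescriptorConfig(n_sphere_points=240)
        t1 = emit_conformations(np.array([0, 1, 2]), templates, 0.02, seed=1)
        t2 = emit_conformations(np.array([3, 2]), templates, 0.02, seed=2)
        both = ChainTrajectory(
            np.concatenate([t1.coordinates, t2.coordinates]), 300.0
        )
        d1 = descriptor_series(t1, cfg)
        d2 = descriptor_series(t2, cfg)
        dd = descriptor_series(both, cfg)
        np.testing.assert_allclose(
            dd["rg_nm"], np.concatenate([d1["rg_nm"], d2["rg_nm"]]), atol=1e-12
        )
        np.testing.assert_allclose(
            dd["nu"], np.concatenate([d1["nu"], d2["nu"]]), atol=0
        )

    def test_rigid_body_invariance_of_all_descriptors(self, templates, rng):
        cfg = DescriptorConfig(n_sphere_points=960)
        coords = templates[np.array([0, 2])]
        moved = np.empty_like(coords)
        for f in range(coords.shape[0]):
            Q = random_rotation(rng)
            moved[f] = coords[f] @ Q.T + rng.normal(size=3)
        d0 = descriptor_series(ChainTrajectory(coords, 300.0), cfg)
        d1 = descriptor_series(ChainTrajectory(moved, 300.0), cfg)
        np.testing.assert_allclose(d1["rg_nm"], d0["rg_nm"], atol=1e-10)
        np.testing.assert_allclose(d1["omega_rad"], d0["omega_rad"], atol=1e-10)
        np.testing.assert_array_equal(d1["nu"], d0["nu"])
        # SASA uses a fixed point set, so rotation changes only quadrature
        np.testing.assert_allclose(d1["sasa_nm2"], d0["sasa_nm2"], rtol=0.01)


@settings(max_examples=25, deadline=None)
@given(st.integers(6, 40), st.integers(2, 5))
def test_segment_count_matches_floor(n_beads, seg_len):
    """Property: n_segments = floor(n_beads / segment_length) whenever valid."""
    if n_beads < 2 * seg_len:
        return
    m = segment_chain(n_beads, seg_len)
    assert m.n_segments == n_beads // seg_len
    covered = sum(stop - start for start, stop in m.segment_index_ranges)
    assert covered == m.n_segments * seg_len


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_descriptor_bounds_on_random_chains(seed):
    """Invariants: 0 <= Omega <= (n_segments-1)*pi and 0 <= nu <= C(n,2)-(n-1)."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=0.4, size=(20, 3))
    m = segment_chain(20, 3)
    omega = sum_of_segment_angles(coords, m)
    assert 0.0 <= omega <= (m.n_segments - 1) * np.pi + 1e-12
    nu = segment_contacts(coords, m, cutoff=0.8)
    max_pairs = m.n_segments * (m.n_segments - 1) // 2 - (m.n_segments - 1)
    assert 0 <= nu <= max_pairs
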