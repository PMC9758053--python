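"""Crick backbone generation, transforms and superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bundleforge.geometry import (
    BundleSpec,
    CrickParams,
    GeometryError,
    Transform,
    assemble_bundle,
    build_helix,
    dihedral,
    kabsch,
    supercoil_local_phase,
    supercoil_track,
    superpose,
)

from conftest import quaternion_superpose


def phi_psi(model):
    n = model.atom_coords("N")
    ca = model.ca
    c = model.atom_coords("C")
    phis = np.array(
        [dihedral(c[i - 1], n[i], ca[i], c[i]) for i in range(1, len(model))]
    )
    psis = np.array(
        [dihedral(n[i], ca[i], c[i], n[i + 1]) for i in range(len(model) - 1)]
    )
    return phis, psis


class TestBuildHelix:
    def test_straight_helix_radius_and_spacing(self):
        model = build_helix(
            CrickParams(supercoil_radius=0.0, supercoil_twist=0.0, length=14)
        )
        radial = np.linalg.norm(model.ca[:, :2], axis=1)
        np.testing.assert_allclose(radial, 2.26, atol=1e-9)
        spacing = np.linalg.norm(np.diff(model.ca, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 3.8, atol=0.1)

    def test_supercoil_phase_shift_is_z_rotation(self):
        base = CrickParams(supercoil_radius=7.0, length=77)
        a = build_helix(base)
        b = build_helix(base.replace(supercoil_phase=120.0))
        rot = Transform.rotation_about_axis([0, 0, 1], 120.0)
        rotated = rot.apply(a.coords.reshape(-1, 3))
        np.testing.assert_allclose(rotated, b.coords.reshape(-1, 3), atol=1e-9)

    def test_heptad_periodicity_of_local_phase(self):
        params = CrickParams(supercoil_radius=7.0, length=77)
        phase = supercoil_local_phase(params)
        delta = (phase[7:] - phase[:-7]) % 360.0
        delta = np.minimum(delta, 360.0 - delta)
        assert delta.max() < 0.2

    def test_residues_per_turn(self):
        assert round(360.0 / CrickParams().helical_twist, 3) == 3.5

    def test_backbone_torsions_alpha_helical(self):
        for radius, twist in [(0.0, 0.0), (7.0, -2.85)]:
            model = build_helix(
                CrickParams(supercoil_radius=radius, supercoil_twist=twist, length=35)
            )
            phis, psis = phi_psi(model)
            assert np.all(np.abs(phis + 60.0) < 20.0)
            assert np.all(np.abs(psis + 45.0) < 20.0)

    def test_ca_ca_distance_invariant(self):
        model = build_helix(CrickParams(length=77))
        spacing = np.linalg.norm(np.diff(model.ca, axis=0), axis=1)
        assert np.all(np.abs(spacing - 3.8) < 0.15)

    def test_z_offset_is_additive(self):
        base = CrickParams(length=28)
        shifted = build_helix(base.replace(z_offset=2.5))
        ref = build_helix(base)
        np.testing.assert_allclose(
            shifted.coords, ref.coords + np.array([0.0, 0.0, 2.5]), atol=1e-12
        )

    def test_deterministic_bitwise(self):
        a = build_helix(CrickParams(length=35))
        b = build_helix(CrickParams(length=35))
        assert np.array_equal(a.coords, b.coords)

    def test_inverted_helix_flips_direction(self):
        params = CrickParams(length=35)
        fwd = build_helix(params)
        rev = build_helix(params.replace(inverted=True))
        assert fwd.ca[0, 2] < fwd.ca[-1, 2]
        assert rev.ca[0, 2] > rev.ca[-1, 2]

    def test_left_handed_supercoil_winds_clockwise(self):
        params = CrickParams(supercoil_radius=7.0, length=77)
        assert params.supercoil_twist < 0
        track = supercoil_track(params)
        winding = sum(
            track[i, 0] * track[i + 1, 1] - track[i, 1] * track[i + 1, 0]
            for i in range(len(track) - 1)
        )
        assert winding < 0  # clockwise viewed down +z

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": 5},
            {"supercoil_radius": -1.0},
            {"supercoil_radius": float("nan")},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            CrickParams(**kwargs)

    def test_pitch_angle_zero_without_supercoil(self):
        assert CrickParams(supercoil_twist=0.0).pitch_angle == 0.0
        assert CrickParams(supercoil_radius=7.0).pitch_angle < 0.0


class TestAssembleBundle:
    def test_c3_symmetry(self, trimer35):
        rot = Transform.rotation_about_axis([0, 0, 1], 120.0)
        rotated = rot.apply(trimer35.coords.reshape(-1, 3)).reshape(
            trimer35.coords.shape
        )
        rolled = np.roll(trimer35.coords, -35, axis=0)
        assert np.abs(rotated - rolled).max() < 1e-6

    def test_antiparallel_third_helix(self):
        spec = BundleSpec(
            (
                CrickParams(supercoil_phase=0.0, length=35),
                CrickParams(supercoil_phase=120.0, length=35),
                CrickParams(supercoil_phase=240.0, length=35, inverted=True),
            ),
            ("A", "B", "C"),
        )
        model = assemble_bundle(spec)
        a = model.chain_slice("A")
        c = model.chain_slice("C")
        assert a.ca[0, 2] < a.ca[-1, 2]
        assert c.ca[0, 2] > c.ca[-1, 2]

    def test_outer_helices_lie_further_out(self):
        inner = [
            CrickParams(supercoil_phase=p, supercoil_radius=7.0, length=35)
            for p in (0.0, 120.0, 240.0)
        ]
        outer = [
            CrickParams(supercoil_phase=p, supercoil_radius=13.0, length=35)
            for p in (60.0, 180.0, 300.0)
        ]
        model = assemble_bundle(
            BundleSpec(tuple(inner + outer), tuple("ABCDEF"))
        )
        radii = {
            c: np.linalg.norm(model.chain_slice(c).ca[:, :2], axis=1).mean()
            for c in "ABCDEF"
        }
        inner_mean = np.mean([radii[c] for c in "ABC"])
        outer_mean = np.mean([radii[c] for c in "DEF"])
        assert outer_mean - inner_mean == pytest.approx(6.0, abs=0.5)

    def test_first_helix_z_offset_enforced(self):
        with pytest.raises(GeometryError):
            BundleSpec((CrickParams(z_offset=1.0),))

    def test_phase_lattice_enforced(self):
        with pytest.raises(GeometryError):
            BundleSpec((CrickParams(supercoil_phase=45.0),))

    def test_axis_clash_warns_but_builds(self):
        spec = BundleSpec(
            (
                CrickParams(supercoil_phase=0.0, supercoil_radius=2.0, length=14),
                CrickParams(supercoil_phase=120.0, supercoil_radius=2.0, length=14),
            ),
            ("A", "B"),
        )
        with pytest.warns(UserWarning, match="helix axes"):
            model = assemble_bundle(spec)
        assert "axis_clashes" in model.meta


class TestSuperpose:
    def test_self_superposition_identity(self, trimer35):
        transform, rmsd = superpose(trimer35, trimer35)
        assert rmsd < 1e-12
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)

    def test_rigid_invariance(self, trimer35):
        moved = trimer35.transformed(
            Transform.rotation_about_axis([1, 2, 3], 37.0, point=[5, -2, 1])
        )
        _, rmsd = superpose(trimer35, moved)
        assert rmsd < 1e-9

    def test_matches_quaternion_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.normal(scale=5.0, size=(20, 3))
            q = rng.normal(scale=5.0, size=(20, 3))
            _, rmsd = kabsch(p, q)
            _, _, oracle_rmsd = quaternion_superpose(p, q)
            assert abs(rmsd - oracle_rmsd) < 1e-6

    def test_noisy_copy_rmsd_close_to_oracle(self, trimer35):
        rng = np.random.default_rng(7)
        noisy = trimer35.copy()
        noisy.coords = noisy.coords + rng.normal(scale=0.5, size=noisy.coords.shape)
        moved = noisy.transformed(Transform.rotation_about_axis([0, 1, 0], 80.0))
        _, rmsd = superpose(trimer35, moved)
        _, _, oracle = quaternion_superpose(moved.ca, trimer35.ca)
        assert rmsd == pytest.approx(oracle, rel=0.10)

    def test_size_mismatch_and_collinear_rejected(self):
        with pytest.raises(GeometryError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            kabsch(line, line)

    def test_no_reflection(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(10, 3))
        mirrored = p * np.array([1.0, 1.0, -1.0])
        transform, _ = kabsch(p, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestTransform:
    @given(st.integers(0, 6), st.integers(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_power_composes(self, n, m):
        t = Transform.rotation_about_axis([0.3, -1.0, 0.5], 33.0, point=[1, 0, 2])
        lhs = t.power(n).compose(t.power(m))
        rhs = t.power(n + m)
        np.testing.assert_allclose(lhs.rotation, rhs.rotation, atol=1e-9)
        np.testing.assert_allclose(lhs.translation, rhs.translation, atol=1e-9)

    def test_inverse(self):
        t = Transform.rotation_about_axis([1, 1, 0], 51.0, point=[2, 2, 2])
        combined = t.compose(t.inverse())
        np.testing.assert_allclose(combined.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(combined.translation, 0.0, atol=1e-12)

    def test_reflection_rejected(self):
        with pytest.raises(GeometryError):
            Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
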