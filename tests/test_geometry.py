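"""Lattice geometry: poses, distances, geodesics, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmad.errors import DomainError, InputError
from dmad.geometry import (
    LatticeSpec,
    geodesic_length,
    interstrand_distance,
    iteration_displacement,
    layer_end_states_from_structures,
    path_ratio,
    pose_at_fraction,
    read_lattice_table,
    write_lattice_table,
)

from conftest import make_layer, toy_spec


class TestPoseAtFraction:
    def test_endpoints_and_midpoint(self):
        lay = make_layer()
        p0 = pose_at_fraction(lay, 0.0)
        assert (p0.r, p0.theta, p0.z, p0.kappa) == (100.0, 0.0, 40.0, 0.0)
        p1 = pose_at_fraction(lay, 1.0)
        assert (p1.r, p1.theta, p1.z, p1.kappa) == (120.0, 0.5, 20.0, 1.0)
        pm = pose_at_fraction(lay, 0.5)
        assert (pm.r, pm.theta, pm.z, pm.kappa) == (110.0, 0.25, 30.0, 0.5)

    def test_out_of_domain(self):
        lay = make_layer()
        with pytest.raises(DomainError):
            pose_at_fraction(lay, -0.01)
        with pytest.raises(DomainError):
            pose_at_fraction(lay, 1.01)

    @given(lam=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, lam):
        """Each pose coordinate is exactly the linear blend of its end states."""
        lay = make_layer(r_ext=90.0, r_cnt=130.0, theta0=0.3, theta_sweep=0.7,
                         z_ext=55.0, z_cnt=12.0, kappa_cnt=0.9)
        p = pose_at_fraction(lay, lam)
        assert p.r == pytest.approx(90.0 + lam * 40.0, abs=1e-12)
        assert p.theta == pytest.approx(0.3 + lam * 0.7, abs=1e-12)
        assert p.z == pytest.approx(55.0 - lam * 43.0, abs=1e-12)
        assert p.kappa == pytest.approx(lam * 0.9, abs=1e-12)

    def test_linear_on_grid(self):
        lay = make_layer()
        lams = np.linspace(0, 1, 11)
        rs = [pose_at_fraction(lay, x).r for x in lams]
        assert np.allclose(rs, 100.0 + 20.0 * lams)


class TestDistances:
    def test_interstrand_trivials(self):
        a = pose_at_fraction(make_layer(layer_index=2), 0.0)
        b = pose_at_fraction(make_layer(layer_index=1), 0.0)
        assert interstrand_distance(a, b, 0.0) == pytest.approx(0.0)

    def test_interstrand_diameter(self):
        a = pose_at_fraction(make_layer(layer_index=2, r_ext=1.0, r_cnt=1.0,
                                        z_ext=0.0, z_cnt=0.0, theta_sweep=0.0), 0.0)
        b = pose_at_fraction(make_layer(layer_index=1, r_ext=1.0, r_cnt=1.0,
                                        z_ext=0.0, z_cnt=0.0, theta_sweep=0.0), 0.0)
        assert interstrand_distance(a, b, math.pi) == pytest.approx(2.0, abs=1e-12)

    def test_interstrand_law_of_cosines(self):
        """Hand-computed law-of-cosines value for a pi/3 offset pair."""
        a = pose_at_fraction(make_layer(layer_index=2, r_ext=100.0, r_cnt=100.0,
                                        z_ext=40.0, z_cnt=40.0, theta_sweep=0.0), 0.0)
        b = pose_at_fraction(make_layer(layer_index=1, r_ext=100.0, r_cnt=100.0,
                                        z_ext=0.0, z_cnt=0.0, theta_sweep=0.0), 0.0)
        expected = math.sqrt(2 * 100**2 - 2 * 100**2 * math.cos(math.pi / 3) + 40**2)
        got = interstrand_distance(a, b, math.pi / 3)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(107.70, abs=0.005)

    def test_interstrand_layer_precondition(self):
        a = pose_at_fraction(make_layer(layer_index=3), 0.0)
        b = pose_at_fraction(make_layer(layer_index=1), 0.0)
        with pytest.raises(InputError):
            interstrand_distance(a, b, 0.0)

    def test_interstrand_offset_symmetry(self):
        """Swapping which pose carries the offset (negated) gives the same distance."""
        a = pose_at_fraction(make_layer(layer_index=2, theta0=0.4), 0.3)
        b = pose_at_fraction(make_layer(layer_index=1, theta0=0.1), 0.6)
        d1 = interstrand_distance(a, b, math.pi / 3)
        # shift a by -offset instead
        from dmad.geometry import Pose
        a2 = Pose(a.layer_index, a.lam, a.r, a.theta - math.pi / 3, a.z, a.kappa)
        d2 = interstrand_distance(a2, b, 0.0)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_displacement_trivials(self):
        lay = make_layer()
        p = pose_at_fraction(lay, 0.3)
        assert iteration_displacement(p, p) == 0.0
        z1 = pose_at_fraction(make_layer(z_ext=40.0, z_cnt=30.0, r_ext=100.0,
                                         r_cnt=100.0, theta_sweep=0.0), 0.0)
        z2 = pose_at_fraction(make_layer(z_ext=40.0, z_cnt=30.0, r_ext=100.0,
                                         r_cnt=100.0, theta_sweep=0.0), 1.0)
        assert iteration_displacement(z2, z1) == pytest.approx(10.0, abs=1e-12)

    def test_displacement_matches_cartesian_conversion(self):
        lay = make_layer(r_ext=100.0, r_cnt=120.0, theta0=0.0, theta_sweep=0.5,
                         z_ext=40.0, z_cnt=20.0)
        p0 = pose_at_fraction(lay, 0.0)
        p1 = pose_at_fraction(lay, 0.5)
        a = np.array([110 * math.cos(0.25), 110 * math.sin(0.25), 30.0])
        b = np.array([100.0, 0.0, 40.0])
        assert iteration_displacement(p1, p0) == pytest.approx(
            float(np.linalg.norm(a - b)), rel=1e-12
        )

    def test_rotation_invariance(self):
        """Distances are unchanged by a global rotation about the helical axis."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            t0a, t0b, rot = rng.uniform(0, 2 * math.pi, 3)
            a = pose_at_fraction(make_layer(layer_index=2, theta0=t0a), 0.4)
            b = pose_at_fraction(make_layer(layer_index=1, theta0=t0b), 0.1)
            from dmad.geometry import Pose
            ar = Pose(2, a.lam, a.r, a.theta + rot, a.z, a.kappa)
            br = Pose(1, b.lam, b.r, b.theta + rot, b.z, b.kappa)
            assert interstrand_distance(a, b, 0.4) == pytest.approx(
                interstrand_distance(ar, br, 0.4), rel=1e-10
            )


class TestGeodesic:
    def test_straight_segment(self):
        lay = make_layer(r_ext=100.0, r_cnt=100.0, theta_sweep=0.0, z_ext=40.0, z_cnt=15.0)
        assert geodesic_length(lay, 100) == pytest.approx(25.0, rel=1e-12)

    def test_circular_arc(self):
        lay = make_layer(r_ext=80.0, r_cnt=80.0, theta_sweep=0.9, z_ext=10.0, z_cnt=10.0)
        assert geodesic_length(lay, 1000) == pytest.approx(80.0 * 0.9, rel=1e-3)

    def test_refinement_oracle(self):
        """General conical-helical arc length against a much finer quadrature."""
        lay = make_layer(r_ext=42.0, r_cnt=60.0, theta0=0.2, theta_sweep=1.6,
                         z_ext=473.0, z_cnt=236.5)
        coarse = geodesic_length(lay, 1000)
        fine = geodesic_length(lay, 100_000)
        assert coarse == pytest.approx(fine, rel=1e-4)

    def test_convergence(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            lay = make_layer(
                r_ext=rng.uniform(30, 90), r_cnt=rng.uniform(95, 150),
                theta_sweep=rng.uniform(0, 2), z_ext=rng.uniform(0, 400),
                z_cnt=rng.uniform(0, 400),
            )
            a = geodesic_length(lay, 10_000)
            b = geodesic_length(lay, 100_000)
            assert abs(a - b) / b < 1e-6

    def test_at_least_straight_line(self):
        lay = make_layer(theta_sweep=1.2)
        p0 = pose_at_fraction(lay, 0.0)
        p1 = pose_at_fraction(lay, 1.0)
        straight = iteration_displacement(p1, p0)
        assert geodesic_length(lay, 500) >= straight - 1e-9

    def test_n_steps_domain(self):
        with pytest.raises(DomainError):
            geodesic_length(make_layer(), 1)


class TestPathRatio:
    def test_identity(self):
        spec = toy_spec(4)
        assert path_ratio(spec, spec) == pytest.approx(1.0, abs=1e-12)

    def test_pure_axial_scaling(self):
        small = toy_spec(3, rise_ext=40.0, rise_cnt=20.0)
        # doubling every z-span with no radial/azimuthal motion doubles paths
        big = toy_spec(3, rise_ext=80.0, rise_cnt=40.0)
        assert path_ratio(small, big) == pytest.approx(0.5, rel=1e-9)

    def test_zero_denominator(self):
        degenerate = toy_spec(3, rise_ext=40.0, rise_cnt=40.0)  # no motion at all
        with pytest.raises(DomainError):
            path_ratio(toy_spec(3), degenerate)


class TestEndStateDerivation:
    def test_kabsch_recovery(self):
        """COM and axis/angle recovered from a synthetic rigid transform."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        sub = rng.normal(size=(40, 3)) * 8.0
        sub -= sub.mean(axis=0)
        axis = np.array([0.2, -0.3, 0.93])
        axis /= np.linalg.norm(axis)
        kappa = 0.55
        rot = Rotation.from_rotvec(axis * kappa)
        com_e = np.array([50.0, 0.0, 10.0])
        com_c = np.array([60.0, 20.0, 5.0])
        ext = sub + com_e
        cnt = rot.apply(sub) + com_c
        lay = layer_end_states_from_structures(ext, cnt, layer_index=1)
        assert lay.kappa_cnt == pytest.approx(kappa, abs=1e-9)
        got_axis = np.array([
            math.sin(lay.axis_omega) * math.cos(lay.axis_phi),
            math.sin(lay.axis_omega) * math.sin(lay.axis_phi),
            math.cos(lay.axis_omega),
        ])
        assert np.allclose(got_axis, axis, atol=1e-8)
        assert lay.r_ext == pytest.approx(50.0, abs=1e-9)
        assert lay.z_cnt == pytest.approx(5.0, abs=1e-9)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        spec = LatticeSpec(
            layers=tuple(
                make_layer(layer_index=i + 1, theta0=i * 0.123456789012345,
                           z_ext=i * 43.0, z_cnt=i * 21.5)
                for i in range(5)
            ),
            max_com_separation=61.25,
        )
        path = tmp_path / "lattice.tsv"
        write_lattice_table(spec, path)
        back = read_lattice_table(path)
        assert back.symmetry_order == spec.symmetry_order
        assert back.max_com_separation == spec.max_com_separation
        for a, b in zip(spec.layers, back.layers):
            for f in ("r_ext", "r_cnt", "theta0", "theta_sweep", "z_ext", "z_cnt",
                      "axis_omega", "axis_phi", "kappa_cnt"):
                assert getattr(a, f) == getattr(b, f)  # bit-exact

    def test_reject_garbage(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("not\ta\tlattice\n")
        with pytest.raises(InputError):
            read_lattice_table(path)
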