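"""Potentials, chain builders, platelet template and rigid transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vwfsim.mechanics import (
    PlateletBody,
    build_chain,
    export_mesh_obj,
    fene_energy,
    fene_force_mag,
    harmonic_bond_energy,
    harmonic_bond_force_mag,
    lj_energy,
    lj_force_mag,
    make_platelet_template,
    quat_from_rotvec,
    rigid_transform,
    template_area_volume,
    wca_energy,
    wca_force_mag,
)
from vwfsim.parameters import VWFParams
from vwfsim.units import DEFAULT_UNITS

SIGMA = 0.077
KS_RED = 25_000.0 / SIGMA**2  # kBT/Dr^2
RMAX = 2 * SIGMA


class TestFene:
    def test_zero_extension(self):
        assert fene_energy(0.0, KS_RED, RMAX) == 0.0

    def test_printed_parameter_value(self):
        # -(ks/2) rmax^2 ln(1 - 1/4) with ks = 25,000 kBT/sigma^2, r = sigma
        e = fene_energy(SIGMA, KS_RED, RMAX)
        assert e == pytest.approx(-12_500.0 * 4.0 * math.log(0.75), rel=1e-12)
        assert e == pytest.approx(14_384.0, rel=1e-4)

    def test_monotone_divergence_near_rmax(self):
        rs = RMAX * (1.0 - np.logspace(-1, -9, 9))
        es = fene_energy(rs, KS_RED, RMAX)
        assert np.all(np.diff(es) > 0)
        assert es[-1] > 1e5  # ~ -(ks/2) rmax^2 ln(2e-9), still climbing

    def test_domain_error(self):
        with pytest.raises(ValueError, match="FENE domain"):
            fene_energy(RMAX, KS_RED, RMAX)
        with pytest.raises(ValueError):
            fene_force_mag(1.01 * RMAX, KS_RED, RMAX)

    def test_force_is_negative_gradient(self):
        h = 1e-8
        for r in (0.3 * RMAX, 0.6 * RMAX, 0.9 * RMAX):
            num = (fene_energy(r + h, KS_RED, RMAX) - fene_energy(r - h, KS_RED, RMAX)) / (2 * h)
            assert fene_force_mag(r, KS_RED, RMAX) == pytest.approx(num, rel=1e-6)


class TestLennardJones:
    def test_zero_at_sigma(self):
        assert lj_energy(SIGMA, 16.0, SIGMA) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth(self):
        r_min = 2 ** (1 / 6) * SIGMA
        assert lj_energy(r_min, 16.0, SIGMA) == pytest.approx(-16.0, rel=1e-12)
        assert lj_force_mag(r_min, 16.0, SIGMA) == pytest.approx(0.0, abs=1e-9)

    def test_value_at_two_sigma(self):
        # 4*16*(2^-12 - 2^-6) = -0.984375
        assert lj_energy(2 * SIGMA, 16.0, SIGMA) == pytest.approx(-0.984375, rel=1e-12)

    def test_singularity(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 16.0, SIGMA)

    def test_truncation(self):
        assert lj_energy(2.6 * SIGMA, 16.0, SIGMA, rcut=2.5 * SIGMA) == 0.0


class TestWca:
    def test_nonnegative_and_zero_beyond_cutoff(self):
        rs = np.linspace(0.02, 0.3, 200)
        es = wca_energy(rs, 16.0, SIGMA)
        assert np.all(es >= 0)
        beyond = rs >= 2 ** (1 / 6) * SIGMA
        assert np.all(es[beyond] == 0.0)
        assert np.all(wca_force_mag(rs, 16.0, SIGMA)[beyond] == 0.0)

    def test_continuous_at_cutoff(self):
        rc = 2 ** (1 / 6) * SIGMA
        assert wca_energy(rc * (1 - 1e-9), 16.0, SIGMA) == pytest.approx(0.0, abs=1e-6)


class TestHarmonicBond:
    KB = 8.45e6
    R0 = 0.062

    def test_zero_at_rest(self):
        assert harmonic_bond_energy(self.R0, self.KB, self.R0) == 0.0

    def test_no_half_prefactor(self):
        # kb (r-r0)^2 exactly: 8.45e6 * (1e-3)^2 = 8.45
        assert harmonic_bond_energy(self.R0 + 1e-3, self.KB, self.R0) == pytest.approx(8.45)

    def test_symmetric(self):
        d = 0.004
        assert harmonic_bond_energy(self.R0 + d, self.KB, self.R0) == pytest.approx(
            harmonic_bond_energy(self.R0 - d, self.KB, self.R0)
        )

    def test_force_magnitude(self):
        assert harmonic_bond_force_mag(self.R0 + 1e-3, self.KB, self.R0) == pytest.approx(
            2 * self.KB * 1e-3
        )


class TestBuildChain:
    def test_straight_end_to_end(self):
        ch = build_chain(30, SIGMA, "straight")
        assert ch.end_to_end() == pytest.approx(29 * SIGMA)
        assert np.allclose(ch.bond_lengths(), SIGMA)

    def test_minimum_size(self):
        build_chain(3, SIGMA, "straight")
        with pytest.raises(ValueError):
            build_chain(2, SIGMA, "straight")

    def test_globule_seed_compact_and_separated(self, rng):
        ch = build_chain(30, 0.9 * SIGMA, "globule-seed", rng=rng)
        assert ch.radius_of_gyration() < 2 * SIGMA * 30 ** (1 / 3)
        d = np.linalg.norm(ch.positions[:, None] - ch.positions[None, :], axis=2)
        iu = np.triu_indices(30, k=2)
        assert d[iu].min() >= 0.8 * 2 ** (1 / 6) * SIGMA - 1e-12

    def test_spacing_must_fit_fene(self):
        with pytest.raises(ValueError):
            build_chain(10, 2.1 * SIGMA, "straight")


class TestPlateletTemplate:
    def test_vertices_on_spheroid(self):
        d = 2.0 / (DEFAULT_UNITS.Dr_phys * 1e6)
        tmpl = make_platelet_template(60, d, 0.3)
        assert tmpl.shape == (60, 3)
        a = d / 2
        c = 0.3 * a
        vals = (tmpl[:, 0] / a) ** 2 + (tmpl[:, 1] / a) ** 2 + (tmpl[:, 2] / c) ** 2
        assert np.allclose(vals, 1.0, atol=1e-10)

    def test_aspect_one_is_sphere(self):
        tmpl = make_platelet_template(60, 1.0, 1.0)
        assert np.allclose(np.linalg.norm(tmpl, axis=1), 0.5, atol=1e-10)

    def test_surface_area_near_printed(self):
        """Triangulated area within 10% of the printed platelet area."""
        tmpl = make_platelet_template()
        area, vol = template_area_volume(tmpl)
        area_um2 = area * (DEFAULT_UNITS.Dr_phys * 1e6) ** 2
        assert area_um2 == pytest.approx(6.85, rel=0.10)

    def test_unsupported_count(self):
        with pytest.raises(ValueError):
            make_platelet_template(50)
        with pytest.raises(ValueError):
            make_platelet_template(11)

    def test_obj_export(self, tmp_path):
        tmpl = make_platelet_template()
        path = tmp_path / "platelet.obj"
        export_mesh_obj(tmpl, path)
        text = path.read_text()
        assert text.count("v ") == 60
        assert "f " in text


class TestRigidTransform:
    def _body(self, q):
        tmpl = make_platelet_template()
        return PlateletBody(com=np.array([1.0, 2.0, 3.0]), orientation=np.asarray(q), template=tmpl)

    def test_identity_pose(self):
        body = self._body([1.0, 0, 0, 0])
        assert np.allclose(rigid_transform(body), body.template + body.com)

    def test_double_half_turn_is_identity(self):
        q = quat_from_rotvec(np.array([0, 0, math.pi]))
        body = self._body(q)
        v1 = rigid_transform(body)
        body.orientation = np.array([1.0, 0, 0, 0])
        twice = rigid_transform(self._body(quat_from_rotvec(np.array([0, 0, 2 * math.pi]))))
        assert np.allclose(twice, body.template + body.com, atol=1e-12)
        # one half turn flips x and y
        assert np.allclose(v1[:, 2], body.template[:, 2] + body.com[2])

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_random_pose_is_isometry(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=3)
        body = self._body(quat_from_rotvec(v))
        w = rigid_transform(body)
        d0 = np.linalg.norm(body.template[:, None] - body.template[None, :], axis=2)
        d1 = np.linalg.norm(w[:, None] - w[None, :], axis=2)
        assert np.allclose(d0, d1, atol=1e-10)

    def test_denormalized_quaternion_warns(self):
        body = self._body([1.0 + 1e-3, 0, 0, 0])
        with pytest.warns(RuntimeWarning):
            rigid_transform(body)
        assert np.linalg.norm(body.orientation) == pytest.approx(1.0, abs=1e-12)


class TestForceGradientConsistency:
    """Forces are exact negative gradients (central differences, 1e-6 rel)."""

    @pytest.mark.parametrize(
        "energy, force, args",
        [
            (fene_energy, fene_force_mag, (KS_RED, RMAX)),
            (lj_energy, lj_force_mag, (16.0, SIGMA)),
            (wca_energy, wca_force_mag, (16.0, SIGMA)),
        ],
    )
    def test_central_difference(self, energy, force, args):
        rng = np.random.default_rng(7)
        rs = rng.uniform(0.5 * SIGMA, 1.05 * SIGMA, size=20)
        h = 1e-8
        for r in rs:
            num = -(energy(r + h, *args) - energy(r - h, *args)) / (2 * h)
            f = force(r, *args)
            # force() returns the magnitude of -dU/dr with sign convention
            # positive = repulsive, so compare absolute values
            assert abs(f) == pytest.approx(abs(num), rel=1e-6, abs=1e-6)
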