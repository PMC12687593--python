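"""Integrator, flow fields, neighbor search and rigid-body behavior."""

import math

import numpy as np
import pytest

from vwfsim.dynamics import (
    FlowField,
    bead_drag,
    build_state,
    default_timestep,
    effective_bond_stiffness,
    neighbor_pairs,
    run,
)
from vwfsim.mechanics import build_chain, fene_energy
from vwfsim.parameters import SimulationConfig, VWFParams, bond_preset
from vwfsim.units import DEFAULT_UNITS

DR_UM = DEFAULT_UNITS.Dr_phys * 1e6


def chain_state(n_chains=1, vwf=None, shear=2000.0, walls=True, seed=1,
                box=(40.0, 26.0, 26.0), cal=0.36, dt_tau=None, kind="couette",
                spacing_factor=0.9, grid_pitch=2.0):
    """Helper: chains on a grid in a box, optional couette flow."""
    vwf = vwf or VWFParams()
    flow = {"type": kind}
    if kind == "couette":
        flow["shear_rate_per_s"] = shear
    cfg = SimulationConfig(
        seed=seed, n_vwf=n_chains, n_platelet=0, duration_tau=1.0,
        drag_calibration=cal, dt_tau=dt_tau, vwf=vwf, flow=flow,
        domain={"Lx_um": box[0], "Ly_um": box[1], "Lz_um": box[2], "walls": walls},
    )
    chains = []
    Lx, Ly, Lz = (b / DR_UM for b in box)
    nside = max(1, int(math.ceil(n_chains ** (1 / 3))))
    k = 0
    for i in range(nside):
        for j in range(nside):
            for l in range(nside):
                if k >= n_chains:
                    break
                ch = build_chain(vwf.Nm, spacing_factor * vwf.sigma, "straight", params=vwf)
                ch.positions += np.array(
                    [0.5 + i * grid_pitch, Ly / 2 + (j - nside / 2) * 0.5,
                     0.5 + l * 0.5]
                )
                chains.append(ch)
                k += 1
    return build_state(cfg, chains, [])


class TestFlowField:
    def test_couette_profile(self):
        f = FlowField(kind="couette", Ly=2.0, gdot=3.0)
        assert f.velocity_x(1.0) == 0.0
        assert f.velocity_x(2.0) == pytest.approx(3.0)
        assert f.local_shear_rate(0.3) == 3.0

    def test_poiseuille_wall_and_centerline(self):
        fn, eta, Ly = 100.0, 50.0, 2.0
        f = FlowField(kind="poiseuille", Ly=Ly, fn=fn, eta=eta)
        assert f.local_shear_rate(Ly / 2) == 0.0
        assert f.local_shear_rate(0.0) == pytest.approx(fn * Ly / (2 * eta))
        assert f.velocity_x(0.0) == 0.0 and f.velocity_x(Ly) == pytest.approx(0.0)

    def test_quiescent(self):
        f = FlowField(kind="quiescent", Ly=1.0)
        assert f.velocity_x(0.7) == 0.0

    def test_y_domain_checked(self):
        with pytest.raises(ValueError):
            FlowField(kind="couette", Ly=1.0, gdot=1.0).local_shear_rate(1.5)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            FlowField(kind="plug")


class TestNeighborSearch:
    def test_cutoff_edge_cases(self):
        pos = np.array([[0.0, 0.5, 0.0], [0.1, 0.5, 0.0], [0.5, 0.5, 0.0]])
        pairs = neighbor_pairs(pos, 0.1 + 1e-12, (1.0, 1.0, 1.0))
        assert {tuple(p) for p in pairs} == {(0, 1)}
        pairs = neighbor_pairs(pos, 0.0999, (1.0, 1.0, 1.0))
        assert len(pairs) == 0

    def test_periodic_wrap(self):
        pos = np.array([[0.01, 0.5, 0.5], [0.99, 0.5, 0.5]])
        pairs = neighbor_pairs(pos, 0.05, (1.0, 1.0, 1.0))
        assert len(pairs) == 1

    @pytest.mark.parametrize("n, L", [(64, 1.0), (200, 2.0), (40, 0.2)])
    def test_against_all_pairs_oracle(self, n, L, rng):
        """Cell list reproduces the brute-force O(N^2) pair set exactly."""
        pos = rng.uniform(0, L, size=(n, 3))
        cutoff = 0.12
        got = {tuple(sorted(p)) for p in neighbor_pairs(pos, cutoff, (L, L, L))}
        want = set()
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d[0] -= L * round(d[0] / L)
                d[2] -= L * round(d[2] / L)
                if np.linalg.norm(d) <= cutoff:
                    want.add((i, j))
        assert got == want


class TestIntegrator:
    def test_pure_advection(self):
        """Zero noise, negligible forces: beads drift with the local couette
        velocity u_x = gdot (y - Ly/2) and do not move in y or z."""
        vwf = VWFParams(Nm=3, ks=1e-6, eps=0.0)
        st = chain_state(vwf=vwf, shear=2000.0, spacing_factor=0.5, dt_tau=1e-3)
        gdot = st.flow.gdot
        y0 = st.chains[0].positions[:, 1].copy()
        x0 = st.chains[0].positions[:, 0].copy()
        n = 500
        run(st, n, kT=0.0)
        expected = x0 + gdot * (y0 - st.flow.Ly / 2) * (n * st.dt)
        assert np.allclose(st.chains[0].positions[:, 0], expected, rtol=1e-9, atol=1e-9)
        assert np.allclose(st.chains[0].positions[:, 1], y0, atol=1e-9)

    def test_com_diffusion_einstein(self):
        """Quiescent flow: chain COM diffuses with D = kBT / (Nm zeta)."""
        vwf = VWFParams(Nm=3, eps=0.0)
        st = chain_state(
            n_chains=125, vwf=vwf, kind="quiescent", walls=False,
            box=(60.0, 60.0, 60.0), cal=0.36, grid_pitch=1.2, spacing_factor=0.3,
        )
        zeta = bead_drag(vwf, 0.36)
        D_com = 1.0 / (3 * zeta)
        lag = 0.05
        n_steps = max(1, int(round(lag / st.dt)))
        lag = n_steps * st.dt
        coms = [np.array([c.positions.mean(axis=0) for c in st.chains])]
        n_blocks = 16
        for _ in range(n_blocks):
            run(st, n_steps)
            coms.append(np.array([c.positions.mean(axis=0) for c in st.chains]))
        disp = np.diff(np.array(coms), axis=0)  # (blocks, chains, 3)
        msd = float((disp**2).sum(axis=2).mean())
        expected = 6 * D_com * lag
        n_samples = disp.shape[0] * disp.shape[1]
        tol = 5 * expected * math.sqrt(2.0 / n_samples)
        assert abs(msd - expected) < max(tol, 0.05 * expected)

    def test_bonded_pair_at_rest_length_is_forceless(self):
        """A bond at its rest length contributes no force (trivially: the
        harmonic force magnitude vanishes at r0)."""
        m1 = bond_preset("m1")
        from vwfsim.mechanics import harmonic_bond_force_mag

        assert harmonic_bond_force_mag(m1.r0, m1.kb, m1.r0) == 0.0

    def test_fene_blowup_halves_dt_then_raises(self):
        """A chain built at the FENE limit triggers the rejection path."""
        vwf = VWFParams(eps=0.0)
        st = chain_state(vwf=vwf, spacing_factor=1.9, shear=8000.0, dt_tau=5e-3)
        with pytest.raises(RuntimeError, match="FENE"):
            run(st, 200, kT=0.0)

    def test_default_timestep_scales_with_drag(self):
        vwf = VWFParams()
        m1 = bond_preset("m1")
        assert default_timestep(vwf, m1, 0.5, fraction=0.3) == pytest.approx(
            2 * default_timestep(vwf, m1, 0.25, fraction=0.3)
        )
        k = effective_bond_stiffness(vwf)
        assert k > 2e7  # steeper than the adhesive spring


class TestRigidity:
    def test_platelet_distance_matrix_preserved(self, small_config):
        from vwfsim.scenarios import generate_initial_configuration

        cfg = small_config.model_copy(update={"n_vwf": 0, "n_platelet": 6})
        st = generate_initial_configuration(cfg)
        ref = st.template
        d0 = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        run(st, 10_000)
        for p in st.platelets:
            w = p.world_vertices()
            d1 = np.linalg.norm(w[:, None] - w[None, :], axis=2)
            assert np.allclose(d0, d1, atol=1e-8)


class TestDeterminism:
    def test_identical_seeds_bitwise_identical(self, small_config):
        from vwfsim.scenarios import generate_initial_configuration

        def one():
            st = generate_initial_configuration(small_config)
            run(st, 3000)
            return st

        a, b = one(), one()
        assert np.array_equal(a.bead_positions(), b.bead_positions())
        assert np.array_equal(a.active_flags(), b.active_flags())
        assert a.events == b.events
        assert a.registry.bonds() == b.registry.bonds()


class TestEquilibriumSampling:
    def test_ideal_fene_end_to_end_matches_monte_carlo(self):
        """BD sampling of an ideal chain (FENE only, no attraction) matches
        a direct Monte-Carlo sample of the same Hamiltonian (two-sample
        Kolmogorov-Smirnov at alpha = 0.01)."""
        from scipy import stats

        vwf = VWFParams(Nm=5, ks=100.0, eps=0.0)
        ks_red = vwf.ks_red
        rmax = vwf.rmax
        rng = np.random.default_rng(99)

        # --- Monte-Carlo oracle: p(r) ~ r^2 exp(-U_FENE(r)) per bond -----
        def sample_bond_lengths(n):
            out = np.empty(n)
            k = 0
            r_grid = np.linspace(1e-6, rmax * (1 - 1e-9), 2001)
            w = r_grid**2 * np.exp(-(fene_energy(r_grid, ks_red, rmax)
                                     - fene_energy(r_grid, ks_red, rmax).min()))
            wmax = w.max()
            while k < n:
                r = rng.uniform(0, rmax * (1 - 1e-9), size=2 * (n - k))
                u = rng.uniform(0, wmax, size=r.size)
                wr = r**2 * np.exp(-fene_energy(r, ks_red, rmax))
                acc = r[u < wr]
                take = min(len(acc), n - k)
                out[k : k + take] = acc[:take]
                k += take
            return out

        n_mc = 4000
        bonds = sample_bond_lengths(4 * n_mc).reshape(n_mc, 4)
        dirs = rng.normal(size=(n_mc, 4, 3))
        dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
        e2e_mc = np.linalg.norm((bonds[:, :, None] * dirs).sum(axis=1), axis=1)

        # --- BD sampling of the same Hamiltonian -------------------------
        samples = []
        for seed in (1, 2, 3, 4):
            st = chain_state(
                vwf=vwf, kind="quiescent", walls=False, seed=seed,
                box=(60.0, 60.0, 60.0), cal=0.02, spacing_factor=0.1,
                dt_tau=None,
            )
            st.dt = st.dt / 5  # tighten the step for unbiased sampling
            stride = max(1, int(round(1.0 / st.dt)))
            run(st, 10 * stride)  # equilibrate
            for _ in range(40):
                run(st, stride)
                samples.append(st.chains[0].end_to_end())
        res = stats.ks_2samp(np.asarray(samples), e2e_mc)
        assert res.pvalue > 0.01
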