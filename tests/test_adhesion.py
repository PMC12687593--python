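"""Two-pathway off-rate law and stochastic bond kinetics."""

import math

import numpy as np
import pandas as pd
import pytest
from mpmath import mp

from vwfsim.adhesion import (
    BondRegistry,
    attempt_associations,
    attempt_dissociations,
    koff,
    lifetime_curve,
    mean_bond_lifetime,
)
from vwfsim.parameters import BOND_PRESETS, bond_preset


def koff_oracle(r, preset):
    """Independent high-precision (50-digit) evaluation of the off-rate law."""
    mp.dps = 50
    p = BOND_PRESETS[preset]
    lam = mp.mpf("1.06e5")
    kc0, ks0 = mp.mpf(repr(p["kc0"])), mp.mpf(repr(p["ks0"]))
    xc, xeq, xs = mp.mpf(repr(p["xc"])), mp.mpf(repr(p["xeq"])), mp.mpf(repr(p["xs"]))
    r = mp.mpf(repr(float(r)))
    dc = xc - xeq
    ds = xs - xeq
    ec = lam * (r - xeq) * dc
    es = lam * (r - xeq) * ds
    clamp = mp.mpf(60)
    ec = max(min(ec, clamp), -clamp)
    es = max(min(es, clamp), -clamp)
    return float(kc0 * mp.e**ec + ks0 * mp.e**es)


class TestKoff:
    def test_fixed_model_r_independent(self):
        fixed = bond_preset("fixed")
        rs = np.linspace(0.0, 0.23, 57)
        vals = koff(rs, fixed)
        assert np.allclose(vals, 5.77e-1, rtol=1e-14)

    def test_m1_at_equilibrium_length(self):
        m1 = bond_preset("m1")
        assert koff(m1.xeq, m1) == pytest.approx(5.76e-1 + 5.76e-4, rel=1e-12)

    def test_m1_slip_dominated_above_xs(self):
        """Beyond the slip length the slip pathway dominates the off-rate."""
        m1 = bond_preset("m1")
        r = 0.067
        dr = r - m1.xeq
        slip_term = m1.ks0 * math.exp(m1.lambda_s * dr * m1.delta_s)
        catch_term = m1.kc0 * math.exp(m1.lambda_c * dr * m1.delta_c)
        assert slip_term > 100 * catch_term
        assert koff(r, m1) == pytest.approx(koff_oracle(r, "m1"), rel=1e-12)

    @pytest.mark.parametrize("preset", sorted(BOND_PRESETS))
    def test_against_high_precision_oracle(self, preset):
        """1,000-point r-grid against the 50-digit oracle for each preset."""
        model = bond_preset(preset)
        rs = np.linspace(0.0, model.rcut_off, 1000)
        ours = koff(rs, model)
        theirs = np.array([koff_oracle(r, preset) for r in rs])
        assert np.allclose(ours, theirs, rtol=1e-10)

    def test_degenerate_reductions(self):
        """kc0=0 reduces to pure slip; delta_c=0 with ks0=0 to a constant."""
        slip = bond_preset("slip")
        rs = np.linspace(0.062, 0.23, 50)
        expected = slip.ks0 * np.exp(
            np.clip(slip.lambda_s * (rs - slip.xeq) * slip.delta_s, -60, 60)
        )
        assert np.allclose(koff(rs, slip), expected, rtol=1e-12)
        fixed = bond_preset("fixed")
        assert koff(0.0, fixed) == koff(0.2, fixed) == fixed.kc0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            koff(-0.01, bond_preset("m1"))


class TestLifetimeCurve:
    def test_m1_interior_maximum(self):
        """Catch-slip lifetime peaks strictly between xeq and xs."""
        m1 = bond_preset("m1")
        rs = np.linspace(m1.xeq * 0.9, m1.rcut_off, 4001)
        df = lifetime_curve(m1, rs)
        r_star = df.loc[df["lifetime"].idxmax(), "r"]
        assert m1.xeq < r_star < m1.xs
        # grid-search oracle on the high-precision law agrees
        oracle_vals = [koff_oracle(r, "m1") for r in rs]
        r_star_oracle = rs[int(np.argmin(oracle_vals))]
        assert r_star == pytest.approx(r_star_oracle, abs=1e-6)

    def test_slip_monotone_decreasing_lifetime(self):
        slip = bond_preset("slip")
        df = lifetime_curve(slip, np.linspace(slip.xeq, slip.rcut_off, 200))
        assert (np.diff(df["lifetime"].to_numpy()) <= 0).all()
        assert df["lifetime"].iloc[0] > df["lifetime"].iloc[-1]

    def test_fixed_constant(self):
        df = lifetime_curve(bond_preset("fixed"))
        assert df["lifetime"].std() == pytest.approx(0.0, abs=1e-12)

    def test_grid_domain_checked(self):
        with pytest.raises(ValueError):
            lifetime_curve(bond_preset("m1"), np.array([0.5]))

    def test_preset_off_rate_ordering_at_rest(self):
        """kc0 ordering M1 > M2 > M3 puts their rest off-rates in order."""
        k = [koff(BOND_PRESETS[m]["xeq"], bond_preset(m)) for m in ("m1", "m2", "m3")]
        assert k[0] > k[1] > k[2]


class TestRegistry:
    def test_single_bond_per_site(self):
        reg = BondRegistry(n_monomers=5, n_vertices=5)
        reg.form(0, 1, 0.0)
        with pytest.raises(ValueError):
            reg.form(0, 2, 0.0)
        with pytest.raises(ValueError):
            reg.form(3, 1, 0.0)
        reg.check_invariants()

    def test_bookkeeping_identity(self, rng):
        """#formed - #ruptured == #live at all times."""
        reg = BondRegistry(n_monomers=30, n_vertices=30)
        live = set()
        for _ in range(500):
            if live and rng.random() < 0.45:
                m, v = live.pop()
                reg.rupture(m, v)
            else:
                m = int(rng.integers(30))
                v = int(rng.integers(30))
                if reg.is_monomer_free(m) and reg.is_vertex_free(v):
                    reg.form(m, v, 0.0)
                    live.add((m, v))
            reg.check_invariants()
        assert reg.n_formed_total - reg.n_ruptured_total == len(live)


class TestAssociation:
    def test_out_of_range_never_forms(self, m1, rng):
        reg = BondRegistry(4, 4)
        cands = np.array([[0, 0, m1.rcut_on * 1.01]])
        for _ in range(200):
            assert attempt_associations(cands, reg, m1, 1e-3, 0.0, rng) == []

    def test_probability_half_at_ln2(self, m1, rng):
        """kon*dt = ln 2 gives formation probability exactly 1/2."""
        dt = math.log(2.0) / m1.kon
        n_formed = 0
        trials = 4000
        for _ in range(trials):
            reg = BondRegistry(1, 1)
            formed = attempt_associations(
                np.array([[0, 0, m1.r0]]), reg, m1, dt, 0.0, rng
            )
            n_formed += len(formed)
        p = n_formed / trials
        assert p == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(trials))

    def test_occupancy_conflicts_resolved(self, m1, rng):
        """Two monomers competing for one vertex: at most one bond forms."""
        reg = BondRegistry(2, 1)
        cands = np.array([[0, 0, m1.r0], [1, 0, m1.r0]])
        attempt_associations(cands, reg, m1, 1.0, 0.0, rng)
        assert reg.n_bonds <= 1
        reg.check_invariants()


class TestDissociation:
    def test_beyond_cutoff_certain_rupture(self, m1, rng):
        reg = BondRegistry(1, 1)
        reg.form(0, 0, 0.0)
        events = attempt_dissociations({(0, 0): m1.rcut_off * 1.01}, reg, m1, 1e-9, 1.0, rng)
        assert len(events) == 1
        assert reg.n_bonds == 0

    def test_zero_rate_never_ruptures(self, rng):
        model = bond_preset("fixed").model_copy(update={"kc0": 0.0})
        reg = BondRegistry(1, 1)
        reg.form(0, 0, 0.0)
        for _ in range(100):
            assert attempt_dissociations({(0, 0): model.r0}, reg, model, 1.0, 0.0, rng) == []

    def test_frozen_length_exponential_lifetime(self, m1, rng):
        """At frozen bond length the sampled mean lifetime matches 1/koff
        within 3 standard errors over 10^4 draws."""
        r = 0.064
        k = koff(r, m1)
        dt = 0.02 / k
        n = 10_000
        lifetimes = np.zeros(n)
        for i in range(n):
            reg = BondRegistry(1, 1)
            reg.form(0, 0, 0.0)
            t = 0.0
            while reg.n_bonds:
                t += dt
                attempt_dissociations({(0, 0): r}, reg, m1, dt, t, rng)
            lifetimes[i] = t
        # discrete-step correction: geometric mean = dt/p ~ 1/k + dt/2
        expected = 1.0 / k + dt / 2.0
        se = lifetimes.std() / math.sqrt(n)
        assert abs(lifetimes.mean() - expected) < 3 * se

    def test_fixed_model_lifetimes_exponential(self, rng):
        """Kolmogorov-Smirnov check of the lifetime distribution for the
        constant off-rate model at alpha = 0.01 (seeded)."""
        from scipy import stats

        fixed = bond_preset("fixed")
        k = fixed.kc0
        dt = 0.01 / k
        n = 10_000
        p_step = 1.0 - math.exp(-k * dt)
        draws = rng.geometric(p_step, size=n) * dt
        # compare against the discrete geometric law's continuous analogue
        res = stats.kstest(draws - dt * rng.random(n), "expon", args=(0.0, 1.0 / k))
        assert res.pvalue > 0.01


class TestMeanLifetime:
    def test_single_and_pair(self):
        ev = pd.DataFrame({"t_formed": [0.0], "t_ruptured": [2.5]})
        assert mean_bond_lifetime(ev) == 2.5
        ev2 = pd.DataFrame({"t_formed": [0.0, 0.0], "t_ruptured": [1.0, 3.0]})
        assert mean_bond_lifetime(ev2) == 2.0

    def test_empty_window_is_nan(self):
        ev = pd.DataFrame({"t_formed": [0.0], "t_ruptured": [2.5]})
        assert math.isnan(mean_bond_lifetime(ev, window=(10.0, 20.0)))
        assert math.isnan(mean_bond_lifetime(ev.iloc[:0]))

    def test_synthetic_exponential_events(self, rng):
        k = 3.0
        life = rng.exponential(1.0 / k, size=5000)
        t0 = rng.uniform(0, 10, size=5000)
        ev = pd.DataFrame({"t_formed": t0, "t_ruptured": t0 + life})
        assert mean_bond_lifetime(ev) == pytest.approx(1.0 / k, rel=0.05)
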