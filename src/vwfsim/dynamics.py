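"""Time integration in a prescribed background flow.

The suspending fluid is not solved for: bodies move by free-draining
overdamped (Brownian) dynamics in a *prescribed* flow profile,

    dx = u(x) dt + (F / zeta) dt + sqrt(2 kBT dt / zeta) N(0,1),

which realizes the frictional coupling of the polymers to the fluid while
deliberately omitting hydrodynamic lift and inter-bead hydrodynamic
interactions (documented limitation).  Platelets move as rigid bodies under
the summed vertex forces and torques with isotropic translational and
rotational drags, advected by the local flow velocity and rotated by half
the local vorticity.

Per step the sub-operations run in a fixed order:
move -> activation update -> dissociations -> associations.

The inner loop is compiled with numba; the pure-Python operation functions
in :mod:`vwfsim.adhesion` and :mod:`vwfsim.activation` are the readable
references against which the compiled engine is tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

from .adhesion import BondRegistry
from .mechanics import PlateletBody, VWFChain, make_platelet_template, template_area_volume
from .parameters import BondModel, RepulsionTable, SimulationConfig, VWFParams
from .units import DEFAULT_UNITS, UnitSystem

__all__ = [
    "FlowField",
    "SimulationState",
    "build_state",
    "step",
    "run",
    "neighbor_pairs",
    "bead_drag",
    "platelet_drags",
    "default_timestep",
    "effective_bond_stiffness",
]

FLOW_KINDS = {"quiescent": 0, "couette": 1, "poiseuille": 2}

#: Cap on the deterministic per-step displacement [Dr]; a numerical
#: safeguard against force spikes from transient deep overlaps.  Kept well
#: below the backbone bond scale so a clipped step cannot ratchet a FENE
#: bond toward its divergence.
MAX_FORCE_DISP = 0.005


# ---------------------------------------------------------------------------
# flow field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowField:
    """Prescribed unidirectional flow u_x(y) between walls at y=0 and y=Ly.

    couette:    u_x = gdot (y - Ly/2)
    poiseuille: u_x = (fn / 2 eta) y (Ly - y), wall shear rate fn Ly / (2 eta)
    quiescent:  u = 0

    All quantities in reduced units (Dr, kBT, tau).
    """

    kind: str = "couette"
    Ly: float = 1.0
    gdot: float = 0.0  # couette shear rate [1/tau]
    fn: float = 0.0  # poiseuille force density [kBT/Dr^4]
    eta: float = DEFAULT_UNITS.eta_red

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}")

    @property
    def pois_coeff(self) -> float:
        return self.fn / (2.0 * self.eta)

    def velocity_x(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "couette":
            out = self.gdot * (y - self.Ly / 2.0)
        elif self.kind == "poiseuille":
            out = self.pois_coeff * y * (self.Ly - y)
        else:
            out = np.zeros_like(y)
        return float(out) if out.ndim == 0 else out

    def local_shear_rate(self, y):
        """|du_x/dy| at height y (zero at a poiseuille centerline)."""
        y = np.asarray(y, dtype=float)
        if np.any(y < -1e-12) or np.any(y > self.Ly + 1e-12):
            raise ValueError("y outside [0, Ly]")
        if self.kind == "couette":
            out = np.full_like(y, abs(self.gdot))
        elif self.kind == "poiseuille":
            out = np.abs(self.pois_coeff * (self.Ly - 2.0 * y))
        else:
            out = np.zeros_like(y)
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# drags and timestep
# ---------------------------------------------------------------------------

def bead_drag(vwf: VWFParams, calibration: float, units: UnitSystem = DEFAULT_UNITS) -> float:
    """Bead friction coefficient [kBT tau / Dr^2]: calibration * 3 pi eta sigma."""
    return calibration * 3.0 * math.pi * units.eta_red * vwf.sigma


def platelet_drags(
    template: np.ndarray, calibration: float, units: UnitSystem = DEFAULT_UNITS
) -> tuple[float, float, float]:
    """(translational, rotational drag, R_eff) for the rigid platelet.

    R_eff is the radius of the volume-equivalent sphere of the template;
    drags are the isotropic Stokes values 6 pi eta R and 8 pi eta R^3.
    """
    _, vol = template_area_volume(template)
    r_eff = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    zt = calibration * 6.0 * math.pi * units.eta_red * r_eff
    zr = calibration * 8.0 * math.pi * units.eta_red * r_eff**3
    return zt, zr, r_eff


def effective_bond_stiffness(vwf: VWFParams) -> float:
    """Curvature [kBT/Dr^2] of FENE + LJ at the backbone bond minimum.

    This is the stiffest deterministic mode of the chain and sets the
    stability bound of the explicit integrator.
    """
    ks = vwf.ks_red
    rmax = vwf.rmax
    eps = vwf.eps
    sig = vwf.sigma
    if eps <= 0.0:
        # pure FENE: thermal bonds sit in the nonlinear region; 4x the
        # linear stiffness bounds the curvature over the occupied range
        return 4.0 * ks

    def force(r):  # net outward force; zero at the minimum
        x6 = (sig / r) ** 6
        f_lj = 24.0 * eps * (2.0 * x6 * x6 - x6) / r
        f_fene = ks * r / (1.0 - (r / rmax) ** 2)
        return f_lj - f_fene

    r_eq = brentq(force, 0.3 * sig, 1.2 * sig)
    h = 1e-6 * sig
    return float(-(force(r_eq + h) - force(r_eq - h)) / (2 * h))


def default_timestep(
    vwf: VWFParams, bond: BondModel, calibration: float, units: UnitSystem = DEFAULT_UNITS,
    fraction: float = 0.3,
) -> float:
    """Timestep [tau] from the explicit-integrator stability rule.

    dt = fraction * zeta_bead / k_max with k_max the stiffest mode among the
    backbone (FENE+LJ) and the adhesive spring (2 kb).  fraction=0.3 keeps
    the stiff relaxation non-oscillatory with modest thermal inflation.
    """
    zeta = bead_drag(vwf, calibration, units)
    k_max = max(effective_bond_stiffness(vwf), 2.0 * bond.kb)
    return fraction * zeta / k_max


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """All bodies, bonds, flow and RNG bookkeeping for one run."""

    config: SimulationConfig
    chains: list  # list[VWFChain]
    platelets: list  # list[PlateletBody]
    registry: BondRegistry
    flow: FlowField
    template: np.ndarray
    t: float = 0.0
    dt: float = 0.0
    rng: np.random.Generator = None
    units: UnitSystem = DEFAULT_UNITS
    events: list = field(default_factory=list)  # rupture event dicts
    dt_halved: bool = False
    _warned_fast_rupture: bool = False

    # --- packed views ---------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_platelets(self) -> int:
        return len(self.platelets)

    @property
    def Nm(self) -> int:
        return self.config.vwf.Nm

    @property
    def Nv(self) -> int:
        return self.template.shape[0]

    def bead_positions(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 3))
        return np.concatenate([c.positions for c in self.chains], axis=0)

    def active_flags(self) -> np.ndarray:
        if not self.chains:
            return np.zeros(0, dtype=bool)
        return np.concatenate([c.active for c in self.chains])

    def set_bead_positions(self, pos: np.ndarray) -> None:
        for i, c in enumerate(self.chains):
            c.positions = pos[i * self.Nm : (i + 1) * self.Nm].copy()

    def set_active_flags(self, flags: np.ndarray) -> None:
        for i, c in enumerate(self.chains):
            c.active = flags[i * self.Nm : (i + 1) * self.Nm].astype(bool).copy()

    def body_of_monomer(self, gid: int) -> int:
        return gid // self.Nm

    def body_of_vertex(self, gid: int) -> int:
        return self.n_chains + gid // self.Nv

    def bond_edges(self) -> list[tuple[int, int]]:
        """Body-level edges (chain body, platelet body) from live bonds."""
        return [
            (self.body_of_monomer(m), self.body_of_vertex(v))
            for (m, v) in self.registry.bonds()
        ]

    def events_dataframe(self) -> pd.DataFrame:
        cols = ["t_formed", "t_ruptured", "monomer_gid", "vertex_gid", "r_at_rupture", "model_name"]
        if not self.events:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.events, columns=cols)


def build_state(
    config: SimulationConfig,
    chains: list,
    platelets: list,
    units: UnitSystem = DEFAULT_UNITS,
) -> SimulationState:
    """Assemble a SimulationState from prepared bodies and a config."""
    template = make_platelet_template(
        Nv=config.platelet.Nv,
        diameter=config.platelet.diameter_um / (units.Dr_phys * 1e6),
        aspect=config.platelet.aspect,
    )
    Ly = config.domain.Ly_um / (units.Dr_phys * 1e6)
    fp = config.flow
    if fp.type == "couette":
        gdot = units.shear_rate_to_reduced(fp.shear_rate_per_s)
        flow = FlowField(kind="couette", Ly=Ly, gdot=gdot, eta=units.eta_red)
    elif fp.type == "poiseuille":
        fn_red = fp.fn / fp.rc_Dr**4
        flow = FlowField(kind="poiseuille", Ly=Ly, fn=fn_red, eta=units.eta_red)
    else:
        flow = FlowField(kind="quiescent", Ly=Ly, eta=units.eta_red)
    bond = config.bond()
    dt = config.dt_tau or default_timestep(config.vwf, bond, config.drag_calibration, units)
    Nm = config.vwf.Nm
    registry = BondRegistry(
        n_monomers=len(chains) * Nm, n_vertices=len(platelets) * config.platelet.Nv
    )
    rng = np.random.default_rng(config.seed)
    return SimulationState(
        config=config,
        chains=chains,
        platelets=platelets,
        registry=registry,
        flow=flow,
        template=template,
        dt=dt,
        rng=rng,
        units=units,
    )


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cell_pairs(pos, cutoff, Lx, Ly, Lz, pbc_x, pbc_z, out_pairs):
    """Cell-list pair search; returns count of pairs within cutoff.

    Minimum-image convention in x and z when periodic.  Falls back to
    all-pairs when fewer than 3 cells fit a periodic dimension.
    """
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    ncx = max(1, int(Lx / cutoff))
    ncy = max(1, int(Ly / cutoff))
    ncz = max(1, int(Lz / cutoff))
    brute = (pbc_x and ncx < 3) or (pbc_z and ncz < 3)
    count = 0
    if brute or n < 32:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if pbc_x:
                    dx -= Lx * round(dx / Lx)
                if pbc_z:
                    dz -= Lz * round(dz / Lz)
                if dx * dx + dy * dy + dz * dz <= cut2:
                    if count < out_pairs.shape[0]:
                        out_pairs[count, 0] = i
                        out_pairs[count, 1] = j
                    count += 1
        return count

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cix = np.empty(n, dtype=np.int64)
    ciy = np.empty(n, dtype=np.int64)
    ciz = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] % Lx if pbc_x else min(max(pos[i, 0], 0.0), Lx * 0.999999)
        y = min(max(pos[i, 1], 0.0), Ly * 0.999999)
        z = pos[i, 2] % Lz if pbc_z else min(max(pos[i, 2], 0.0), Lz * 0.999999)
        cx = min(int(x / Lx * ncx), ncx - 1)
        cy = min(int(y / Ly * ncy), ncy - 1)
        cz = min(int(z / Lz * ncz), ncz - 1)
        cix[i] = cx
        ciy[i] = cy
        ciz[i] = cz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        for ox in range(-1, 2):
            cx = cix[i] + ox
            if pbc_x:
                cx %= ncx
            elif cx < 0 or cx >= ncx:
                continue
            for oy in range(-1, 2):
                cy = ciy[i] + oy
                if cy < 0 or cy >= ncy:
                    continue
                for oz in range(-1, 2):
                    cz = ciz[i] + oz
                    if pbc_z:
                        cz %= ncz
                    elif cz < 0 or cz >= ncz:
                        continue
                    j = head[(cx * ncy + cy) * ncz + cz]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if pbc_x:
                                dx -= Lx * round(dx / Lx)
                            if pbc_z:
                                dz -= Lz * round(dz / Lz)
                            if dx * dx + dy * dy + dz * dz <= cut2:
                                if count < out_pairs.shape[0]:
                                    out_pairs[count, 0] = i
                                    out_pairs[count, 1] = j
                                count += 1
                        j = nxt[j]
    return count


def neighbor_pairs(
    positions: np.ndarray,
    cutoff: float,
    box: tuple[float, float, float],
    pbc: tuple[bool, bool, bool] = (True, False, True),
) -> np.ndarray:
    """All particle pairs within ``cutoff`` (cell list, minimum image in x/z)."""
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = pos.shape[0]
    cap = max(1024, 64 * n)
    while True:
        buf = np.empty((cap, 2), dtype=np.int64)
        cnt = _cell_pairs(pos, cutoff, box[0], box[1], box[2], pbc[0], pbc[2], buf)
        if cnt <= cap:
            return buf[:cnt].copy()
        cap = cnt + 16


# ---------------------------------------------------------------------------
# compiled engine
# ---------------------------------------------------------------------------

ERR_NONE = 0
ERR_FENE = 1
ERR_EVENT_OVERFLOW = 2

_EMPTY = np.zeros(0)

# half stencil for the cell scan: the zero offset (own cell, list-ordered)
# plus 13 neighbor offsets covering each unordered cell pair exactly once
_STENCIL = np.array(
    [[0, 0, 0], [0, 0, 1], [0, 1, -1], [0, 1, 0], [0, 1, 1],
     [1, -1, -1], [1, -1, 0], [1, -1, 1], [1, 0, -1], [1, 0, 0],
     [1, 0, 1], [1, 1, -1], [1, 1, 0], [1, 1, 1]],
    dtype=np.int64,
)


@njit(cache=True, fastmath=True)
def _update_activation_kernel(bead_pos, active, C, Nm, cos_thres, Rthres):
    R2 = Rthres * Rthres
    for c in range(C):
        o = c * Nm
        for i in range(Nm):
            ok = True
            if 2 <= i <= Nm - 3:
                ux = bead_pos[o + i - 1, 0] - bead_pos[o + i, 0]
                uy = bead_pos[o + i - 1, 1] - bead_pos[o + i, 1]
                uz = bead_pos[o + i - 1, 2] - bead_pos[o + i, 2]
                vx = bead_pos[o + i + 1, 0] - bead_pos[o + i, 0]
                vy = bead_pos[o + i + 1, 1] - bead_pos[o + i, 1]
                vz = bead_pos[o + i + 1, 2] - bead_pos[o + i, 2]
                nu = math.sqrt(ux * ux + uy * uy + uz * uz)
                nv = math.sqrt(vx * vx + vy * vy + vz * vz)
                if nu == 0.0 or nv == 0.0:
                    ok = False
                else:
                    cosang = (ux * vx + uy * vy + uz * vz) / (nu * nv)
                    if cosang > cos_thres:
                        ok = False
            if ok:
                for j in range(Nm):
                    if j < i - 1 or j > i + 1:
                        dx = bead_pos[o + i, 0] - bead_pos[o + j, 0]
                        dy = bead_pos[o + i, 1] - bead_pos[o + j, 1]
                        dz = bead_pos[o + i, 2] - bead_pos[o + j, 2]
                        if dx * dx + dy * dy + dz * dz <= R2:
                            ok = False
                            break
            active[o + i] = 1 if ok else 0


@njit(cache=True, fastmath=True)
def _run_kernel(
    bead_pos, active, C, Nm,
    plat_com, plat_quat, template,
    mon_partner, vert_partner, bond_t0,
    # chain parameters
    sigma, ks_red, rmax, eps_att, rlj_cut, cos_thres, Rthres,
    # excluded volume
    sig_vv, sig_pv, sig_pp, eps_rep,
    # adhesion
    kb, r0b, kon, rcut_on, rcut_off,
    kc0, ks0, expo_c, expo_s, xeq,
    # dynamics
    zeta_b, zeta_t, zeta_r, kT,
    dt, n_steps, t_start,
    flow_kind, gdot, pois_coeff, Ly, use_walls, Lx, Lz,
    wall_margin_bead, wall_margin_plat,
    seed,
    # event buffers
    ev_t0, ev_t1, ev_m, ev_v, ev_r,
    max_force_disp,
):
    """Advance the whole system n_steps; returns (steps_done, n_events, err)."""
    np.random.seed(seed)
    NB = C * Nm
    P = plat_com.shape[0]
    Nv = template.shape[0]
    N = NB + P * Nv
    n_events = 0

    rmax2 = rmax * rmax
    rlj2 = rlj_cut * rlj_cut
    wca_vv = 2.0 ** (1.0 / 6.0) * sig_vv
    wca_pv = 2.0 ** (1.0 / 6.0) * sig_pv
    wca_pp = 2.0 ** (1.0 / 6.0) * sig_pp
    cutoff = max(wca_vv, max(wca_pv, max(wca_pp, rcut_on + 0.01)))
    cut2 = cutoff * cutoff
    p_on = 1.0 - math.exp(-kon * dt)

    # work arrays
    f_bead = np.zeros((NB, 3))
    f_plat = np.zeros((P, 3))
    tq_plat = np.zeros((P, 3))
    verts = np.zeros((P * Nv, 3))
    rot = np.zeros((3, 3))
    cand_cap = 16384
    cand_m = np.empty(cand_cap, dtype=np.int64)
    cand_v = np.empty(cand_cap, dtype=np.int64)
    pair_cap = max(1024, 64 * N)
    pair_i = np.empty(pair_cap, dtype=np.int64)
    pair_j = np.empty(pair_cap, dtype=np.int64)
    # static per-particle body ids (beads first, then platelet vertices)
    body_id = np.empty(N, dtype=np.int64)
    for i in range(NB):
        body_id[i] = i // Nm
    for k in range(P * Nv):
        body_id[NB + k] = C + k // Nv

    # Verlet pair list with a drift-tracked skin: rebuilt only once the
    # accumulated relative motion could have moved a pair across the skin.
    skin = 0.06
    cut_list = cutoff + skin
    # per-pair-type list cutoffs: platelet-platelet contacts are much
    # shorter-ranged than the bead capture radius, so listing them at the
    # global cutoff would inflate the pair list ~5x in dense aggregates
    cl2_vv = (wca_vv + skin) ** 2
    cl2_pp = (wca_pp + skin) ** 2
    cl2_pv = (max(wca_pv, rcut_on + 0.01) + skin) ** 2
    ncx = max(1, int(Lx / cut_list))
    ncy = max(1, int(Ly / cut_list))
    ncz = max(1, int(Lz / cut_list))
    use_cells = ncx >= 3 and ncz >= 3 and N >= 64
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    ccx = np.empty(N, dtype=np.int64)
    ccy = np.empty(N, dtype=np.int64)
    ccz = np.empty(N, dtype=np.int64)
    wpos = np.zeros((N, 3))
    n_pairs = 0
    drift_acc = 1e9  # forces an initial build
    nvar_acc = 0.0
    # incremental wrap offsets (replace per-step fmod with O(1) updates)
    offx = np.empty(N)
    offz = np.empty(N)
    for i in range(NB):
        offx[i] = Lx * math.floor(bead_pos[i, 0] / Lx)
        offz[i] = Lz * math.floor(bead_pos[i, 2] / Lz)
    for k in range(P * Nv):
        offx[NB + k] = 0.0
        offz[NB + k] = 0.0
    a_max = 0.0
    for k in range(Nv):
        nk = math.sqrt(
            template[k, 0] ** 2 + template[k, 1] ** 2 + template[k, 2] ** 2
        )
        if nk > a_max:
            a_max = nk
    if flow_kind == 1:
        shear_max = abs(gdot)
    elif flow_kind == 2:
        shear_max = abs(pois_coeff) * Ly
    else:
        shear_max = 0.0

    # world-frame platelet vertices for the first force pass; afterwards the
    # post-move recomputation at the end of each step keeps them current
    for p in range(P):
        w = plat_quat[p, 0]
        x = plat_quat[p, 1]
        y = plat_quat[p, 2]
        z = plat_quat[p, 3]
        qn = math.sqrt(w * w + x * x + y * y + z * z)
        w /= qn; x /= qn; y /= qn; z /= qn
        plat_quat[p, 0] = w; plat_quat[p, 1] = x
        plat_quat[p, 2] = y; plat_quat[p, 3] = z
        rot[0, 0] = 1 - 2 * (y * y + z * z)
        rot[0, 1] = 2 * (x * y - w * z)
        rot[0, 2] = 2 * (x * z + w * y)
        rot[1, 0] = 2 * (x * y + w * z)
        rot[1, 1] = 1 - 2 * (x * x + z * z)
        rot[1, 2] = 2 * (y * z - w * x)
        rot[2, 0] = 2 * (x * z - w * y)
        rot[2, 1] = 2 * (y * z + w * x)
        rot[2, 2] = 1 - 2 * (x * x + y * y)
        for k in range(Nv):
            gx = rot[0, 0] * template[k, 0] + rot[0, 1] * template[k, 1] + rot[0, 2] * template[k, 2]
            gy = rot[1, 0] * template[k, 0] + rot[1, 1] * template[k, 1] + rot[1, 2] * template[k, 2]
            gz = rot[2, 0] * template[k, 0] + rot[2, 1] * template[k, 1] + rot[2, 2] * template[k, 2]
            verts[p * Nv + k, 0] = plat_com[p, 0] + gx
            verts[p * Nv + k, 1] = plat_com[p, 1] + gy
            verts[p * Nv + k, 2] = plat_com[p, 2] + gz

    t = t_start
    for istep in range(n_steps):
        # ---- zero accumulators --------------------------------------
        for i in range(NB):
            f_bead[i, 0] = 0.0; f_bead[i, 1] = 0.0; f_bead[i, 2] = 0.0
        for p in range(P):
            f_plat[p, 0] = 0.0; f_plat[p, 1] = 0.0; f_plat[p, 2] = 0.0
            tq_plat[p, 0] = 0.0; tq_plat[p, 1] = 0.0; tq_plat[p, 2] = 0.0
        n_cand = 0

        # ---- intra-chain FENE + LJ (unwrapped coordinates) ----------
        for c in range(C):
            o = c * Nm
            for i in range(Nm):
                for j in range(i + 1, Nm):
                    dx = bead_pos[o + i, 0] - bead_pos[o + j, 0]
                    dy = bead_pos[o + i, 1] - bead_pos[o + j, 1]
                    dz = bead_pos[o + i, 2] - bead_pos[o + j, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    fmag = 0.0
                    if eps_att > 0.0 and r2 < rlj2 and r2 > 0.0:
                        inv_r2 = 1.0 / r2
                        inv2 = sigma * sigma * inv_r2
                        x6 = inv2 * inv2 * inv2
                        fmag += 24.0 * eps_att * (2.0 * x6 * x6 - x6) * inv_r2
                    if j == i + 1 and ks_red > 0.0:
                        if r2 >= rmax2:
                            return istep, n_events, ERR_FENE
                        fmag -= ks_red / (1.0 - r2 / rmax2)
                    if fmag != 0.0:
                        fx = fmag * dx; fy = fmag * dy; fz = fmag * dz
                        f_bead[o + i, 0] += fx; f_bead[o + i, 1] += fy; f_bead[o + i, 2] += fz
                        f_bead[o + j, 0] -= fx; f_bead[o + j, 1] -= fy; f_bead[o + j, 2] -= fz

        # ---- inter-body pass: excluded volume + association candidates
        if C + P > 1:
            # wrapped coordinates for minimum-image pair search
            for i in range(N):
                raw_x = bead_pos[i, 0] if i < NB else verts[i - NB, 0]
                raw_y = bead_pos[i, 1] if i < NB else verts[i - NB, 1]
                raw_z = bead_pos[i, 2] if i < NB else verts[i - NB, 2]
                w = raw_x - offx[i]
                while w < 0.0:
                    w += Lx
                    offx[i] -= Lx
                while w >= Lx:
                    w -= Lx
                    offx[i] += Lx
                wpos[i, 0] = w
                wpos[i, 1] = raw_y
                w = raw_z - offz[i]
                while w < 0.0:
                    w += Lz
                    offz[i] -= Lz
                while w >= Lz:
                    w -= Lz
                    offz[i] += Lz
                wpos[i, 2] = w

            # rebuild the Verlet list when drift could cross the skin
            rebuild = drift_acc + 3.0 * math.sqrt(6.0 * nvar_acc) > 0.5 * skin
            if rebuild:
                drift_acc = 0.0
                nvar_acc = 0.0
                n_pairs = 0
            if rebuild and use_cells:
                for i in range(ncell):
                    head[i] = -1
                for i in range(N):
                    yy = min(max(wpos[i, 1], 0.0), Ly * 0.999999)
                    cx = min(int(wpos[i, 0] / Lx * ncx), ncx - 1)
                    cy = min(int(yy / Ly * ncy), ncy - 1)
                    cz = min(int(wpos[i, 2] / Lz * ncz), ncz - 1)
                    if cx < 0:
                        cx = 0
                    if cz < 0:
                        cz = 0
                    ccx[i] = cx; ccy[i] = cy; ccz[i] = cz
                    cell = (cx * ncy + cy) * ncz + cz
                    nxt[i] = head[cell]
                    head[cell] = i
                # half stencil: own cell (ordered) + 13 of the 26 neighbors
                for i in range(N):
                    bi = body_id[i]
                    xi = wpos[i, 0]; yi = wpos[i, 1]; zi = wpos[i, 2]
                    for st_k in range(14):
                        ox = _STENCIL[st_k, 0]
                        oy = _STENCIL[st_k, 1]
                        oz = _STENCIL[st_k, 2]
                        cy = ccy[i] + oy
                        if cy < 0 or cy >= ncy:
                            continue
                        cx = (ccx[i] + ox) % ncx
                        cz = (ccz[i] + oz) % ncz
                        same_cell = ox == 0 and oy == 0 and oz == 0
                        j = head[(cx * ncy + cy) * ncz + cz] if not same_cell else nxt[i]
                        while j >= 0:
                            if bi != body_id[j]:
                                if i < NB and j < NB:
                                    cl2 = cl2_vv
                                elif i >= NB and j >= NB:
                                    cl2 = cl2_pp
                                else:
                                    cl2 = cl2_pv
                                dx = xi - wpos[j, 0]
                                dy = yi - wpos[j, 1]
                                dz = zi - wpos[j, 2]
                                if dx > 0.5 * Lx:
                                    dx -= Lx
                                elif dx < -0.5 * Lx:
                                    dx += Lx
                                if dz > 0.5 * Lz:
                                    dz -= Lz
                                elif dz < -0.5 * Lz:
                                    dz += Lz
                                if dx * dx + dy * dy + dz * dz <= cl2:
                                    if n_pairs < pair_cap:
                                        pair_i[n_pairs] = i
                                        pair_j[n_pairs] = j
                                        n_pairs += 1
                            j = nxt[j]
            elif rebuild:
                for i in range(N):
                    bi = body_id[i]
                    for j in range(i + 1, N):
                        if bi != body_id[j]:
                            if i < NB and j < NB:
                                cl2 = cl2_vv
                            elif i >= NB and j >= NB:
                                cl2 = cl2_pp
                            else:
                                cl2 = cl2_pv
                            dx = wpos[i, 0] - wpos[j, 0]
                            dy = wpos[i, 1] - wpos[j, 1]
                            dz = wpos[i, 2] - wpos[j, 2]
                            if dx > 0.5 * Lx:
                                dx -= Lx
                            elif dx < -0.5 * Lx:
                                dx += Lx
                            if dz > 0.5 * Lz:
                                dz -= Lz
                            elif dz < -0.5 * Lz:
                                dz += Lz
                            if dx * dx + dy * dy + dz * dz <= cl2:
                                if n_pairs < pair_cap:
                                    pair_i[n_pairs] = i
                                    pair_j[n_pairs] = j
                                    n_pairs += 1

            # physics on the collected pairs
            for ip in range(n_pairs):
                i = pair_i[ip]
                j = pair_j[ip]
                i_is_bead = i < NB
                j_is_bead = j < NB
                if i_is_bead and j_is_bead:
                    sig = sig_vv
                    wcut = wca_vv
                elif (not i_is_bead) and (not j_is_bead):
                    sig = sig_pp
                    wcut = wca_pp
                else:
                    sig = sig_pv
                    wcut = wca_pv
                dx = wpos[i, 0] - wpos[j, 0]
                dy = wpos[i, 1] - wpos[j, 1]
                dz = wpos[i, 2] - wpos[j, 2]
                if dx > 0.5 * Lx:
                    dx -= Lx
                elif dx < -0.5 * Lx:
                    dx += Lx
                if dz > 0.5 * Lz:
                    dz -= Lz
                elif dz < -0.5 * Lz:
                    dz += Lz
                r2 = dx * dx + dy * dy + dz * dz
                if r2 == 0.0:
                    continue
                if r2 < wcut * wcut:
                    inv_r2 = 1.0 / r2
                    inv2 = sig * sig * inv_r2
                    x6 = inv2 * inv2 * inv2
                    fmag = 24.0 * eps_rep * (2.0 * x6 * x6 - x6) * inv_r2
                    fx = fmag * dx; fy = fmag * dy; fz = fmag * dz
                    if i_is_bead:
                        f_bead[i, 0] += fx; f_bead[i, 1] += fy; f_bead[i, 2] += fz
                    else:
                        p = (i - NB) // Nv
                        k = i - NB
                        f_plat[p, 0] += fx; f_plat[p, 1] += fy; f_plat[p, 2] += fz
                        ax = verts[k, 0] - plat_com[p, 0]
                        ay = verts[k, 1] - plat_com[p, 1]
                        az = verts[k, 2] - plat_com[p, 2]
                        tq_plat[p, 0] += ay * fz - az * fy
                        tq_plat[p, 1] += az * fx - ax * fz
                        tq_plat[p, 2] += ax * fy - ay * fx
                    if j_is_bead:
                        f_bead[j, 0] -= fx; f_bead[j, 1] -= fy; f_bead[j, 2] -= fz
                    else:
                        p = (j - NB) // Nv
                        k = j - NB
                        f_plat[p, 0] -= fx; f_plat[p, 1] -= fy; f_plat[p, 2] -= fz
                        ax = verts[k, 0] - plat_com[p, 0]
                        ay = verts[k, 1] - plat_com[p, 1]
                        az = verts[k, 2] - plat_com[p, 2]
                        tq_plat[p, 0] -= ay * fz - az * fy
                        tq_plat[p, 1] -= az * fx - ax * fz
                        tq_plat[p, 2] -= ax * fy - ay * fx
                # association candidate: bead-vertex pair within range + skin
                if i_is_bead != j_is_bead:
                    if i_is_bead:
                        m = i
                        vv = j - NB
                    else:
                        m = j
                        vv = i - NB
                    if (
                        r2 <= (rcut_on + 0.01) * (rcut_on + 0.01)
                        and active[m] == 1
                        and mon_partner[m] < 0
                        and vert_partner[vv] < 0
                        and n_cand < cand_cap
                    ):
                        cand_m[n_cand] = m
                        cand_v[n_cand] = vv
                        n_cand += 1

        # ---- adhesive bond forces -----------------------------------
        for m in range(NB):
            v = mon_partner[m]
            if v >= 0:
                dx = verts[v, 0] - bead_pos[m, 0]
                dy = verts[v, 1] - bead_pos[m, 1]
                dz = verts[v, 2] - bead_pos[m, 2]
                dx -= Lx * round(dx / Lx)
                dz -= Lz * round(dz / Lz)
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r > 0.0:
                    fmag = 2.0 * kb * (r - r0b) / r  # along +d pulls bead to vertex
                    fx = fmag * dx; fy = fmag * dy; fz = fmag * dz
                    f_bead[m, 0] += fx; f_bead[m, 1] += fy; f_bead[m, 2] += fz
                    p = v // Nv
                    f_plat[p, 0] -= fx; f_plat[p, 1] -= fy; f_plat[p, 2] -= fz
                    ax = verts[v, 0] - plat_com[p, 0]
                    ay = verts[v, 1] - plat_com[p, 1]
                    az = verts[v, 2] - plat_com[p, 2]
                    tq_plat[p, 0] += ay * (-fz) - az * (-fy)
                    tq_plat[p, 1] += az * (-fx) - ax * (-fz)
                    tq_plat[p, 2] += ax * (-fy) - ay * (-fx)

        # ---- move beads ---------------------------------------------
        sqb = math.sqrt(2.0 * kT * dt / zeta_b) if kT > 0.0 else 0.0
        sqt = math.sqrt(2.0 * kT * dt / zeta_t) if (kT > 0.0 and P > 0) else 0.0
        sqr = math.sqrt(2.0 * kT * dt / zeta_r) if (kT > 0.0 and P > 0) else 0.0
        dmax = 0.0
        wmax = 0.0
        if kT > 0.0:
            noise_b = np.random.standard_normal(3 * NB)
            noise_p = np.random.standard_normal(6 * P)
        else:
            noise_b = _EMPTY
            noise_p = _EMPTY
        for i in range(NB):
            y = bead_pos[i, 1]
            if flow_kind == 1:
                ux = gdot * (y - Ly / 2.0)
            elif flow_kind == 2:
                ux = pois_coeff * y * (Ly - y)
            else:
                ux = 0.0
            ddx = f_bead[i, 0] / zeta_b * dt
            ddy = f_bead[i, 1] / zeta_b * dt
            ddz = f_bead[i, 2] / zeta_b * dt
            dn = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if dn > max_force_disp:
                s = max_force_disp / dn
                ddx *= s; ddy *= s; ddz *= s
                dn = max_force_disp
            if dn > dmax:
                dmax = dn
            bead_pos[i, 0] += ux * dt + ddx
            bead_pos[i, 1] += ddy
            bead_pos[i, 2] += ddz
            if sqb > 0.0:
                bead_pos[i, 0] += sqb * noise_b[3 * i]
                bead_pos[i, 1] += sqb * noise_b[3 * i + 1]
                bead_pos[i, 2] += sqb * noise_b[3 * i + 2]
            if use_walls:
                if bead_pos[i, 1] < wall_margin_bead:
                    bead_pos[i, 1] = 2.0 * wall_margin_bead - bead_pos[i, 1]
                elif bead_pos[i, 1] > Ly - wall_margin_bead:
                    bead_pos[i, 1] = 2.0 * (Ly - wall_margin_bead) - bead_pos[i, 1]

        # ---- move platelets -----------------------------------------
        for p in range(P):
            y = plat_com[p, 1]
            if flow_kind == 1:
                ux = gdot * (y - Ly / 2.0)
                shear_loc = gdot
            elif flow_kind == 2:
                ux = pois_coeff * y * (Ly - y)
                shear_loc = pois_coeff * (Ly - 2.0 * y)
            else:
                ux = 0.0
                shear_loc = 0.0
            ddx = f_plat[p, 0] / zeta_t * dt
            ddy = f_plat[p, 1] / zeta_t * dt
            ddz = f_plat[p, 2] / zeta_t * dt
            dn = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if dn > max_force_disp:
                s = max_force_disp / dn
                ddx *= s; ddy *= s; ddz *= s
                dn = max_force_disp
            if dn > dmax:
                dmax = dn
            plat_com[p, 0] += ux * dt + ddx
            plat_com[p, 1] += ddy
            plat_com[p, 2] += ddz
            if sqt > 0.0:
                plat_com[p, 0] += sqt * noise_p[6 * p]
                plat_com[p, 1] += sqt * noise_p[6 * p + 1]
                plat_com[p, 2] += sqt * noise_p[6 * p + 2]
            if use_walls:
                if plat_com[p, 1] < wall_margin_plat:
                    plat_com[p, 1] = 2.0 * wall_margin_plat - plat_com[p, 1]
                elif plat_com[p, 1] > Ly - wall_margin_plat:
                    plat_com[p, 1] = 2.0 * (Ly - wall_margin_plat) - plat_com[p, 1]
            # rotation: half local vorticity + torque + noise
            wx = tq_plat[p, 0] / zeta_r * dt
            wy = tq_plat[p, 1] / zeta_r * dt
            wz = (-0.5 * shear_loc + tq_plat[p, 2] / zeta_r) * dt
            ang_det = math.sqrt(wx * wx + wy * wy + wz * wz)
            if ang_det > wmax:
                wmax = ang_det
            if sqr > 0.0:
                wx += sqr * noise_p[6 * p + 3]
                wy += sqr * noise_p[6 * p + 4]
                wz += sqr * noise_p[6 * p + 5]
            ang = math.sqrt(wx * wx + wy * wy + wz * wz)
            if ang > 1e-14:
                sh = math.sin(ang / 2.0) / ang
                dqw = math.cos(ang / 2.0)
                dqx = wx * sh; dqy = wy * sh; dqz = wz * sh
                aw = plat_quat[p, 0]; ax = plat_quat[p, 1]
                ay = plat_quat[p, 2]; az = plat_quat[p, 3]
                plat_quat[p, 0] = dqw * aw - dqx * ax - dqy * ay - dqz * az
                plat_quat[p, 1] = dqw * ax + dqx * aw + dqy * az - dqz * ay
                plat_quat[p, 2] = dqw * ay - dqx * az + dqy * aw + dqz * ax
                plat_quat[p, 3] = dqw * az + dqx * ay - dqy * ax + dqz * aw

        t += dt

        # drift bookkeeping for the Verlet-list skin: deterministic motion
        # bounds add linearly, Brownian ones by variance
        drift_acc += 2.0 * dmax + shear_max * cut_list * dt + 2.0 * wmax * a_max
        sq = sqb if sqb > sqt else sqt
        sqra = sqr * a_max
        if sqra > sq:
            sq = sqra
        nvar_acc += sq * sq

        # ---- activation update --------------------------------------
        _update_activation_kernel(bead_pos, active, C, Nm, cos_thres, Rthres)

        # ---- recompute vertices after the move for kinetics ---------
        for p in range(P):
            w = plat_quat[p, 0]; x = plat_quat[p, 1]
            y = plat_quat[p, 2]; z = plat_quat[p, 3]
            qn = math.sqrt(w * w + x * x + y * y + z * z)
            w /= qn; x /= qn; y /= qn; z /= qn
            plat_quat[p, 0] = w; plat_quat[p, 1] = x
            plat_quat[p, 2] = y; plat_quat[p, 3] = z
            rot[0, 0] = 1 - 2 * (y * y + z * z)
            rot[0, 1] = 2 * (x * y - w * z)
            rot[0, 2] = 2 * (x * z + w * y)
            rot[1, 0] = 2 * (x * y + w * z)
            rot[1, 1] = 1 - 2 * (x * x + z * z)
            rot[1, 2] = 2 * (y * z - w * x)
            rot[2, 0] = 2 * (x * z - w * y)
            rot[2, 1] = 2 * (y * z + w * x)
            rot[2, 2] = 1 - 2 * (x * x + y * y)
            for k in range(Nv):
                gx = rot[0, 0] * template[k, 0] + rot[0, 1] * template[k, 1] + rot[0, 2] * template[k, 2]
                gy = rot[1, 0] * template[k, 0] + rot[1, 1] * template[k, 1] + rot[1, 2] * template[k, 2]
                gz = rot[2, 0] * template[k, 0] + rot[2, 1] * template[k, 1] + rot[2, 2] * template[k, 2]
                verts[p * Nv + k, 0] = plat_com[p, 0] + gx
                verts[p * Nv + k, 1] = plat_com[p, 1] + gy
                verts[p * Nv + k, 2] = plat_com[p, 2] + gz

        # ---- dissociations ------------------------------------------
        for m in range(NB):
            v = mon_partner[m]
            if v >= 0:
                dx = verts[v, 0] - bead_pos[m, 0]
                dy = verts[v, 1] - bead_pos[m, 1]
                dz = verts[v, 2] - bead_pos[m, 2]
                dx -= Lx * round(dx / Lx)
                dz -= Lz * round(dz / Lz)
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r > rcut_off:
                    p_off = 1.0
                else:
                    dr = r - xeq
                    ec = expo_c * dr
                    if ec > 60.0:
                        ec = 60.0
                    elif ec < -60.0:
                        ec = -60.0
                    es = expo_s * dr
                    if es > 60.0:
                        es = 60.0
                    elif es < -60.0:
                        es = -60.0
                    k_off = kc0 * math.exp(ec) + ks0 * math.exp(es)
                    p_off = 1.0 - math.exp(-k_off * dt)
                if p_off >= 1.0 or np.random.random() < p_off:
                    if n_events >= ev_t0.shape[0]:
                        return istep + 1, n_events, ERR_EVENT_OVERFLOW
                    ev_t0[n_events] = bond_t0[m]
                    ev_t1[n_events] = t
                    ev_m[n_events] = m
                    ev_v[n_events] = v
                    ev_r[n_events] = r
                    n_events += 1
                    mon_partner[m] = -1
                    vert_partner[v] = -1

        # ---- associations -------------------------------------------
        if n_cand > 0 and p_on > 0.0:
            # Fisher-Yates shuffle for a seeded random processing order
            for a in range(n_cand - 1, 0, -1):
                b = int(np.random.random() * (a + 1))
                tmpm = cand_m[a]; cand_m[a] = cand_m[b]; cand_m[b] = tmpm
                tmpv = cand_v[a]; cand_v[a] = cand_v[b]; cand_v[b] = tmpv
            for a in range(n_cand):
                m = cand_m[a]
                v = cand_v[a]
                if active[m] == 0:
                    continue
                if mon_partner[m] >= 0 or vert_partner[v] >= 0:
                    continue
                dx = verts[v, 0] - bead_pos[m, 0]
                dy = verts[v, 1] - bead_pos[m, 1]
                dz = verts[v, 2] - bead_pos[m, 2]
                dx -= Lx * round(dx / Lx)
                dz -= Lz * round(dz / Lz)
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r > rcut_on:
                    continue
                if np.random.random() < p_on:
                    mon_partner[m] = v
                    vert_partner[v] = m
                    bond_t0[m] = t

    return n_steps, n_events, ERR_NONE


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

def _pack(state: SimulationState):
    Nm = state.Nm
    C = state.n_chains
    P = state.n_platelets
    Nv = state.Nv
    bead_pos = np.ascontiguousarray(state.bead_positions(), dtype=np.float64)
    active = np.ascontiguousarray(state.active_flags().astype(np.uint8))
    plat_com = (
        np.ascontiguousarray([p.com for p in state.platelets], dtype=np.float64)
        if P
        else np.zeros((0, 3))
    )
    plat_quat = (
        np.ascontiguousarray([p.orientation for p in state.platelets], dtype=np.float64)
        if P
        else np.zeros((0, 4))
    )
    mon_partner = state.registry.monomer_bond.copy()
    vert_partner = state.registry.vertex_bond.copy()
    bond_t0 = np.zeros(max(1, C * Nm))
    for (m, v), t0 in state.registry.t_formed.items():
        bond_t0[m] = t0
    return bead_pos, active, plat_com, plat_quat, mon_partner, vert_partner, bond_t0


def _unpack(state, bead_pos, active, plat_com, plat_quat, mon_partner, vert_partner, bond_t0):
    state.set_bead_positions(bead_pos)
    state.set_active_flags(active)
    for p_idx, p in enumerate(state.platelets):
        p.com = plat_com[p_idx].copy()
        p.orientation = plat_quat[p_idx].copy()
    # rebuild the registry from partner arrays
    reg = state.registry
    reg.t_formed.clear()
    reg.monomer_bond[:] = mon_partner
    reg.vertex_bond[:] = vert_partner
    for m in np.nonzero(mon_partner >= 0)[0]:
        v = int(mon_partner[m])
        reg.t_formed[(int(m), v)] = float(bond_t0[m])
    for p_idx, p in enumerate(state.platelets):
        Nv = state.Nv
        p.occupancy = vert_partner[p_idx * Nv : (p_idx + 1) * Nv] >= 0


def run(
    state: SimulationState,
    n_steps: int,
    record_events: bool = True,
    event_capacity: int = 400_000,
    kT: float = 1.0,
) -> None:
    """Advance the state by ``n_steps`` with the compiled engine.

    On a FENE domain violation the remaining steps are retried once at half
    the timestep, then a hard error is raised.  Rupture events accumulate in
    ``state.events``.
    """
    cfg = state.config
    vwf = cfg.vwf
    bond = cfg.bond()
    rep = cfg.repulsion
    units = state.units
    zeta_b = bead_drag(vwf, cfg.drag_calibration, units)
    zeta_t, zeta_r, r_eff = platelet_drags(state.template, cfg.drag_calibration, units)
    flow = state.flow
    Lx = cfg.domain.Lx_um / (units.Dr_phys * 1e6)
    Lz = cfg.domain.Lz_um / (units.Dr_phys * 1e6)
    Ly = flow.Ly
    kc0, ks0 = bond.kc0, bond.ks0
    expo_c = bond.lambda_c * bond.delta_c  # [1/Dr], kBT=1 in reduced units
    expo_s = bond.lambda_s * bond.delta_s

    packed = _pack(state)
    bead_pos, active, plat_com, plat_quat, mon_partner, vert_partner, bond_t0 = packed
    ev_t0 = np.zeros(event_capacity)
    ev_t1 = np.zeros(event_capacity)
    ev_m = np.zeros(event_capacity, dtype=np.int64)
    ev_v = np.zeros(event_capacity, dtype=np.int64)
    ev_r = np.zeros(event_capacity)

    remaining = n_steps
    dt = state.dt
    halved = False
    while remaining > 0:
        seed = int(state.rng.integers(2**31 - 1))
        done, n_ev, err = _run_kernel(
            bead_pos, active, state.n_chains, state.Nm,
            plat_com, plat_quat, state.template,
            mon_partner, vert_partner, bond_t0,
            vwf.sigma, vwf.ks_red, vwf.rmax, vwf.eps, vwf.r_lj,
            math.cos(math.radians(vwf.theta_thres_deg)), vwf.R_thres,
            rep.vwf_vwf, rep.platelet_vwf, rep.platelet_platelet, rep.eps,
            bond.kb, bond.r0, bond.kon, bond.rcut_on, bond.rcut_off,
            kc0, ks0, expo_c, expo_s, bond.xeq,
            zeta_b, zeta_t, zeta_r, kT,
            dt, remaining, state.t,
            FLOW_KINDS[flow.kind], flow.gdot, flow.pois_coeff, Ly,
            cfg.domain.walls, Lx, Lz,
            vwf.sigma / 2.0, r_eff,
            seed,
            ev_t0, ev_t1, ev_m, ev_v, ev_r,
            MAX_FORCE_DISP,
        )
        state.t += done * dt
        remaining -= done
        if record_events and n_ev > 0:
            for k in range(n_ev):
                state.events.append(
                    dict(
                        t_formed=float(ev_t0[k]),
                        t_ruptured=float(ev_t1[k]),
                        monomer_gid=int(ev_m[k]),
                        vertex_gid=int(ev_v[k]),
                        r_at_rupture=float(ev_r[k]),
                        model_name=bond.name,
                    )
                )
        if err == ERR_FENE:
            if halved:
                raise RuntimeError(
                    "FENE domain violation persisted after halving the timestep; "
                    "reduce dt_tau"
                )
            halved = True
            state.dt_halved = True
            dt = dt / 2.0
            state.dt = dt  # keep the safer step for subsequent blocks
            remaining = 2 * remaining  # same physical duration at half dt
        elif err == ERR_EVENT_OVERFLOW:
            raise RuntimeError("bond event buffer overflow; increase event_capacity")

    _unpack(state, bead_pos, active, plat_com, plat_quat, mon_partner, vert_partner, bond_t0)

    # timestep guidance: warn once if any live bond's off-rate makes the
    # per-step rupture probability exceed 1/2 (dt too coarse for kinetics)
    if not state._warned_fast_rupture and state.registry.n_bonds:
        from .adhesion import koff as _koff

        verts_all = (
            np.concatenate([p.world_vertices() for p in state.platelets])
            if state.platelets
            else np.zeros((0, 3))
        )
        beads_all = state.bead_positions()
        for (m, v) in state.registry.bonds():
            d = verts_all[v] - beads_all[m]
            d[0] -= Lx * round(d[0] / Lx)
            d[2] -= Lz * round(d[2] / Lz)
            r = float(np.linalg.norm(d))
            # warn only in the genuinely under-resolved band: beyond
            # koff*dt ~ 5 the per-step rupture probability is already 1 and
            # the Bernoulli scheme is exact again
            kdt = _koff(r, bond) * state.dt
            if r <= bond.rcut_off and math.log(2.0) < kdt <= 5.0:
                warnings.warn(
                    "a live bond's koff*dt exceeds ln 2; rupture kinetics are "
                    "under-resolved at this timestep",
                    RuntimeWarning,
                )
                state._warned_fast_rupture = True
                break


def step(state: SimulationState, dt: Optional[float] = None) -> SimulationState:
    """Advance the state by a single timestep (move -> activate -> kinetics)."""
    if dt is not None:
        state.dt = dt
    run(state, 1)
    return state
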