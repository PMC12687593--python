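"""Seeded end-to-end protocols: initial configurations, the single-chain
stretch sweep, and the shear-quench reversibility experiment.

The desk-scale defaults (a thin 16x4x6 um Couette slab with a handful of
chains and a few tens of platelets) mirror the calibration geometry of the
full-scale study — pure shear flow over a suspension of only platelets and
VWFs — with the thin wall-normal dimension standing in for the RBC-free
layer in which near-wall aggregation actually happens; without RBCs there
is no cross-streamline migration, so a cubic box would leave each body
stranded in its initial velocity layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adhesion import BondRegistry, mean_bond_lifetime
from .analysis import asphericity, com_wall_distance, find_aggregates
from .dynamics import (
    FlowField,
    SimulationState,
    build_state,
    run,
)
from .io import config_hash, write_events_csv, write_report_json, write_xyz_frame
from .mechanics import PlateletBody, VWFChain, build_chain, make_platelet_template
from .parameters import SimulationConfig, VWFParams, bond_preset
from .units import DEFAULT_UNITS, UnitSystem

__all__ = [
    "equilibrate_globule",
    "generate_initial_configuration",
    "stretch_sweep",
    "reversibility_protocol",
    "run_from_config",
]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def equilibrate_globule(
    vwf: VWFParams,
    seed: int,
    duration_tau: float = 3.0,
    calibration: float = 0.36,
    units: UnitSystem = DEFAULT_UNITS,
) -> VWFChain:
    """Produce an equilibrated VWF globule by a short zero-shear run.

    The self-attraction (eps = 16 kBT) collapses a compact random-walk seed
    into its equilibrium globule; there is no analytic construction for it.
    """
    rng = np.random.default_rng(seed)
    chain = build_chain(vwf.Nm, 0.9 * vwf.sigma, shape="globule-seed", rng=rng, params=vwf)
    cfg = SimulationConfig(
        seed=seed,
        n_vwf=1,
        n_platelet=0,
        duration_tau=duration_tau,
        drag_calibration=calibration,
        vwf=vwf,
        flow={"type": "quiescent"},
        domain={"Lx_um": 40.0, "Ly_um": 40.0, "Lz_um": 40.0, "walls": False},
    )
    center = np.array([3.0, 3.0, 3.0])
    chain.positions = chain.positions - chain.positions.mean(axis=0) + center
    state = build_state(cfg, [chain], [], units)
    n_steps = max(1, int(round(duration_tau / state.dt)))
    run(state, n_steps)
    return state.chains[0]


def generate_initial_configuration(
    config: SimulationConfig,
    units: UnitSystem = DEFAULT_UNITS,
    max_retries: int = 500,
) -> SimulationState:
    """Random non-overlapping suspension of globular chains and platelets.

    Bodies are inserted by random sequential insertion with overlap
    rejection at the per-pair excluded-volume diameters; all chains start
    globular and inactive with an empty bond registry.
    """
    rng = np.random.default_rng(config.seed)
    Dr_um = units.Dr_phys * 1e6
    Lx = config.domain.Lx_um / Dr_um
    Ly = config.domain.Ly_um / Dr_um
    Lz = config.domain.Lz_um / Dr_um
    rep = config.repulsion
    min_vv = rep.cutoff(rep.vwf_vwf)
    min_pv = rep.cutoff(rep.platelet_vwf)
    min_pp = rep.cutoff(rep.platelet_platelet)

    template = make_platelet_template(
        Nv=config.platelet.Nv,
        diameter=config.platelet.diameter_um / Dr_um,
        aspect=config.platelet.aspect,
    )
    a_plat = config.platelet.diameter_um / Dr_um / 2.0

    placed_beads = np.zeros((0, 3))
    placed_verts = np.zeros((0, 3))

    def _min_dist(pts, other):
        if other.shape[0] == 0 or pts.shape[0] == 0:
            return np.inf
        d = np.linalg.norm(pts[:, None, :] - other[None, :, :], axis=2)
        return float(d.min())

    chains: list[VWFChain] = []
    for c in range(config.n_vwf):
        glob = equilibrate_globule(
            config.vwf,
            seed=int(rng.integers(2**31 - 1)),
            calibration=config.drag_calibration,
            units=units,
        )
        local = glob.positions - glob.positions.mean(axis=0)
        radius = float(np.linalg.norm(local, axis=1).max())
        ok = False
        for _ in range(max_retries):
            R = _random_rotation(rng)
            # a globule larger than the half-gap is centered between the
            # walls instead of rejected outright (walls only reflect)
            lo = min(radius + 0.06, Ly / 2.0)
            hi = max(Ly - (radius + 0.06), lo)
            center = np.array(
                [
                    rng.uniform(0, Lx),
                    rng.uniform(lo, hi),
                    rng.uniform(0, Lz),
                ]
            )
            pts = local @ R.T + center
            if _min_dist(pts, placed_beads) < min_vv:
                continue
            if _min_dist(pts, placed_verts) < min_pv:
                continue
            chains.append(VWFChain(pts, np.zeros(glob.Nm, dtype=bool), config.vwf))
            placed_beads = np.vstack([placed_beads, pts])
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"packing failed: placed {len(chains)} of {config.n_vwf} chains "
                f"after {max_retries} tries"
            )

    platelets: list[PlateletBody] = []
    for p in range(config.n_platelet):
        ok = False
        for _ in range(max_retries):
            R = _random_rotation(rng)
            lo = min(a_plat + 0.03, Ly / 2.0)
            hi = max(Ly - (a_plat + 0.03), lo)
            center = np.array(
                [
                    rng.uniform(0, Lx),
                    rng.uniform(lo, hi),
                    rng.uniform(0, Lz),
                ]
            )
            verts = template @ R.T + center
            if _min_dist(verts, placed_beads) < min_pv:
                continue
            if _min_dist(verts, placed_verts) < min_pp:
                continue
            # store orientation as quaternion of R
            q = _matrix_to_quat(R)
            platelets.append(
                PlateletBody(com=center, orientation=q, template=template)
            )
            placed_verts = np.vstack([placed_verts, verts])
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"packing failed: placed {len(platelets)} of {config.n_platelet} "
                f"platelets after {max_retries} tries"
            )

    state = build_state(config, chains, platelets, units)
    return state


def _matrix_to_quat(R: np.ndarray) -> np.ndarray:
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2
        return np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    i = int(np.argmax([R[0, 0], R[1, 1], R[2, 2]]))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = math.sqrt(max(1e-12, 1.0 + R[i, i] - R[j, j] - R[k, k])) * 2
    q = np.zeros(4)
    q[0] = (R[k, j] - R[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (R[j, i] + R[i, j]) / s
    q[1 + k] = (R[k, i] + R[i, k]) / s
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# stretch sweep
# ---------------------------------------------------------------------------

def stretch_sweep(
    shear_rates_per_s=(250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0),
    n_seeds: int = 3,
    duration_tau: float = 40.0,
    seed: int = 0,
    calibration: float = 0.36,
    vwf: VWFParams | None = None,
    extension_threshold: float = 0.3,
    units: UnitSystem = DEFAULT_UNITS,
) -> tuple[pd.DataFrame, float]:
    """Single-chain Couette sweep: mean fractional extension vs shear rate.

    Each replicate starts from an independently equilibrated globule and is
    sheared for ``duration_tau``; the fractional end-to-end extension
    (end-to-end distance over the nominal contour length (Nm-1) sigma) is
    averaged over the final 60% of the run.  Returns the per-shear-rate
    table and the operational critical shear rate: the smallest grid value
    whose seed-mean extension exceeds the threshold (NaN if none does).
    """
    vwf = vwf or VWFParams()
    master = np.random.default_rng(seed)
    rows = []
    contour = vwf.contour_length
    for gdot_s in shear_rates_per_s:
        for rep in range(n_seeds):
            run_seed = int(master.integers(2**31 - 1))
            chain = equilibrate_globule(
                vwf, seed=run_seed, calibration=calibration, units=units
            )
            cfg = SimulationConfig(
                seed=run_seed,
                n_vwf=1,
                n_platelet=0,
                duration_tau=duration_tau,
                drag_calibration=calibration,
                vwf=vwf,
                flow={"type": "couette", "shear_rate_per_s": float(gdot_s)},
                domain={"Lx_um": 40.0, "Ly_um": 26.0, "Lz_um": 26.0, "walls": True},
            )
            Dr_um = units.Dr_phys * 1e6
            center = np.array(
                [cfg.domain.Lx_um, cfg.domain.Ly_um, cfg.domain.Lz_um]
            ) / Dr_um / 2.0
            chain.positions = chain.positions - chain.positions.mean(axis=0) + center
            state = build_state(cfg, [chain], [], units)
            stride = max(1, int(round(0.25 / state.dt)))
            n_blocks = max(1, int(round(duration_tau / 0.25)))
            samples = []
            for b in range(n_blocks):
                run(state, stride, record_events=False)
                samples.append(state.chains[0].end_to_end() / contour)
            samples = np.asarray(samples)
            tail = samples[int(0.4 * len(samples)):]
            half = len(tail) // 2
            drift = abs(tail[half:].mean() - tail[:half].mean())
            converged = bool(drift < max(0.1, 2.0 * tail.std()))
            rows.append(
                dict(
                    shear_rate_per_s=float(gdot_s),
                    replicate=rep,
                    seed=run_seed,
                    extension=float(tail.mean()),
                    extension_sd=float(tail.std()),
                    converged=converged,
                )
            )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("shear_rate_per_s")["extension"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "extension_mean", "std": "extension_sd"})
    )
    crossing = agg[agg["extension_mean"] > extension_threshold]
    gamma_c = float(crossing["shear_rate_per_s"].min()) if len(crossing) else float("nan")
    out = df.merge(agg, on="shear_rate_per_s")
    return out, gamma_c


# ---------------------------------------------------------------------------
# reversibility (shear quench)
# ---------------------------------------------------------------------------

@dataclass
class ReversibilityResult:
    verdict: str  # REVERSIBLE | IRREVERSIBLE | AMBIGUOUS | NO_AGGREGATE
    peak_size: float
    final_size: float
    retention: float
    series: pd.DataFrame = field(repr=False, default=None)
    events: pd.DataFrame = field(repr=False, default=None)


def _largest_cluster(state: SimulationState) -> tuple[int, list[int]]:
    n_bodies = state.n_chains + state.n_platelets
    comps = find_aggregates(state.bond_edges(), n_bodies)
    largest = comps[0]
    return len(largest), largest


def _cluster_points(state: SimulationState, members) -> np.ndarray:
    pts = []
    for b in members:
        if b < state.n_chains:
            pts.append(state.chains[b].positions)
        else:
            pts.append(state.platelets[b - state.n_chains].world_vertices())
    return np.concatenate(pts, axis=0)


def reversibility_protocol(
    model_name: str = "m1",
    high_shear_per_s: float = 4000.0,
    low_shear_per_s: float = 50.0,
    phase1_tau: float = 20.0,
    phase2_tau: float = 80.0,
    n_vwf: int = 4,
    n_platelet: int = 16,
    seed: int = 0,
    calibration: float = 0.36,
    stride_tau: float = 0.5,
    bond_custom=None,
    domain: dict | None = None,
    units: UnitSystem = DEFAULT_UNITS,
) -> ReversibilityResult:
    """Shear-quench experiment: aggregate at high shear, then quench.

    Phase 1 runs Couette flow above the stretching threshold so activated
    chains glue platelets into aggregates; phase 2 drops the shear rate well
    below it.  The verdict compares the largest-cluster size at the end of
    phase 2 (mean over the last 20% of the phase) against the phase-1 peak:
    REVERSIBLE below 10% retention, IRREVERSIBLE at or above 80%.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_vwf=n_vwf,
        n_platelet=n_platelet,
        duration_tau=phase1_tau + phase2_tau,
        drag_calibration=calibration,
        bond_model=model_name,
        bond_custom=bond_custom,
        flow={"type": "couette", "shear_rate_per_s": high_shear_per_s},
        domain=domain or {"Lx_um": 16.0, "Ly_um": 4.0, "Lz_um": 6.0, "walls": True},
    )
    state = generate_initial_configuration(cfg, units)
    stride = max(1, int(round(stride_tau / state.dt)))
    recs = []

    def _observe(phase: str) -> None:
        size, members = _largest_cluster(state)
        y_com = float(_cluster_points(state, members)[:, 1].mean())
        alpha = float("nan")
        if size >= 2:
            try:
                alpha = asphericity(_cluster_points(state, members))
            except ValueError:
                pass
        recs.append(
            dict(
                t=state.t,
                phase=phase,
                largest_size=size,
                n_bonds=state.registry.n_bonds,
                com_wall_distance=com_wall_distance(y_com, state.flow.Ly),
                asphericity=alpha,
            )
        )

    _observe("phase1")
    n_blocks1 = max(1, int(round(phase1_tau / stride_tau)))
    for _ in range(n_blocks1):
        run(state, stride)
        _observe("phase1")

    # quench: swap in the low-shear flow field
    state.flow = FlowField(
        kind="couette",
        Ly=state.flow.Ly,
        gdot=units.shear_rate_to_reduced(low_shear_per_s),
        eta=units.eta_red,
    )
    n_blocks2 = max(1, int(round(phase2_tau / stride_tau)))
    for _ in range(n_blocks2):
        run(state, stride)
        _observe("phase2")

    series = pd.DataFrame(recs)
    events = state.events_dataframe()
    # windowed mean bond lifetime
    lifetimes = []
    for rec in recs:
        w = (rec["t"] - stride_tau, rec["t"])
        lifetimes.append(mean_bond_lifetime(events, w) if len(events) else float("nan"))
    series["mean_bond_lifetime"] = lifetimes

    p1 = series[series["phase"] == "phase1"]
    p2 = series[series["phase"] == "phase2"]
    peak = float(p1["largest_size"].max())
    tail = p2.tail(max(1, int(0.1 * len(p2))))
    final = float(tail["largest_size"].mean())
    if peak < 3.0:
        return ReversibilityResult("NO_AGGREGATE", peak, final, float("nan"), series, events)
    retention = final / peak
    if retention < 0.10:
        verdict = "REVERSIBLE"
    elif retention >= 0.80:
        verdict = "IRREVERSIBLE"
    else:
        verdict = "AMBIGUOUS"
    return ReversibilityResult(verdict, peak, final, retention, series, events)


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------

def run_from_config(path, outdir=".", units: UnitSystem = DEFAULT_UNITS) -> dict:
    """Run one configured simulation and write its artifacts.

    Produces a trajectory (extended XYZ), a bond-event CSV, a JSON report
    and embeds a provenance block (config hash, seed, code version).
    """
    from . import __version__
    from .parameters import load_config

    cfg = load_config(path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = generate_initial_configuration(cfg, units)
    stride_tau = cfg.output.stride_tau
    stride = max(1, int(round(stride_tau / state.dt)))
    n_blocks = max(1, int(round(cfg.duration_tau / stride_tau)))

    traj_path = outdir / "trajectory.xyz"
    series = []
    with open(traj_path, "w") as traj:
        write_xyz_frame(traj, state)
        for b in range(n_blocks):
            run(state, stride)
            size, members = _largest_cluster(state)
            series.append(
                dict(t=state.t, largest_size=size, n_bonds=state.registry.n_bonds)
            )
            if cfg.output.trajectory or b == n_blocks - 1:
                write_xyz_frame(traj, state)

    events = state.events_dataframe()
    events_path = outdir / "bond_events.csv"
    write_events_csv(events, events_path)
    series_path = outdir / "series.csv"
    pd.DataFrame(series).to_csv(series_path, index=False)
    report = dict(
        config=cfg.model_dump(),
        provenance=dict(
            config_hash=config_hash(cfg), seed=cfg.seed, code_version=__version__
        ),
        n_bond_events=len(events),
        final_time_tau=state.t,
        final_largest_cluster=series[-1]["largest_size"] if series else 1,
        artifacts=dict(
            trajectory=str(traj_path), bond_events=str(events_path), series=str(series_path)
        ),
    )
    report_path = outdir / "report.json"
    write_report_json(report, report_path)
    report["artifacts"]["report"] = str(report_path)
    return report
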