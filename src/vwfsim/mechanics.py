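"""Geometry and potentials.

FENE springs along the VWF backbone, full Lennard-Jones self-attraction
within a chain, purely repulsive (WCA) excluded volume between bodies, a
harmonic adhesive bond, and rigid oblate platelet bodies whose 60 surface
vertices act as receptors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .parameters import PlateletParams, VWFParams
from .units import DEFAULT_UNITS, UnitSystem

__all__ = [
    "fene_energy",
    "fene_force_mag",
    "lj_energy",
    "lj_force_mag",
    "wca_energy",
    "wca_force_mag",
    "harmonic_bond_energy",
    "harmonic_bond_force_mag",
    "VWFChain",
    "PlateletBody",
    "build_chain",
    "make_platelet_template",
    "template_area_volume",
    "rigid_transform",
    "quat_to_matrix",
    "quat_multiply",
    "quat_from_rotvec",
    "export_mesh_obj",
]

WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def fene_energy(r, ks: float, rmax: float):
    """FENE bond energy  -(ks/2) rmax^2 ln(1 - (r/rmax)^2).

    ``r`` may be a scalar or array with ``0 <= r < rmax``; ``ks`` in
    energy/length^2.  Raises for any distance at or beyond ``rmax`` — that
    signals an integration blow-up and the caller must reduce the timestep.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("FENE bond length must be non-negative")
    if np.any(r >= rmax):
        raise ValueError(
            f"FENE domain violation: bond length {float(np.max(r)):.6g} >= rmax={rmax:.6g}"
        )
    out = -0.5 * ks * rmax**2 * np.log1p(-((r / rmax) ** 2))
    return float(out) if out.ndim == 0 else out


def fene_force_mag(r, ks: float, rmax: float):
    """Magnitude of the attractive FENE restoring force, ks r / (1-(r/rmax)^2)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("FENE bond length must be non-negative")
    if np.any(r >= rmax):
        raise ValueError(
            f"FENE domain violation: bond length {float(np.max(r)):.6g} >= rmax={rmax:.6g}"
        )
    out = ks * r / (1.0 - (r / rmax) ** 2)
    return float(out) if out.ndim == 0 else out


def lj_energy(r, eps: float, sigma: float, rcut: float | None = None):
    """Full 12-6 Lennard-Jones energy, truncated (not shifted) at ``rcut``.

    Minimum of depth ``-eps`` at ``r = 2^(1/6) sigma``.  ``r = 0`` raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ distance must be strictly positive")
    x6 = (sigma / r) ** 6
    out = 4.0 * eps * (x6 * x6 - x6)
    if rcut is not None:
        out = np.where(r < rcut, out, 0.0)
    return float(out) if out.ndim == 0 else out


def lj_force_mag(r, eps: float, sigma: float, rcut: float | None = None):
    """Radial LJ force magnitude -dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ distance must be strictly positive")
    x6 = (sigma / r) ** 6
    out = 24.0 * eps * (2.0 * x6 * x6 - x6) / r
    if rcut is not None:
        out = np.where(r < rcut, out, 0.0)
    return float(out) if out.ndim == 0 else out


def wca_energy(r, eps: float, sigma: float):
    """Purely repulsive LJ (WCA): truncated at 2^(1/6) sigma and shifted by +eps.

    Energy is >= 0 everywhere and exactly zero at and beyond the cutoff, so
    both energy and force are continuous there.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA distance must be strictly positive")
    rcut = WCA_CUT_FACTOR * sigma
    x6 = (sigma / r) ** 6
    out = np.where(r < rcut, 4.0 * eps * (x6 * x6 - x6) + eps, 0.0)
    return float(out) if out.ndim == 0 else out


def wca_force_mag(r, eps: float, sigma: float):
    """Radial WCA force magnitude (zero at and beyond 2^(1/6) sigma)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA distance must be strictly positive")
    rcut = WCA_CUT_FACTOR * sigma
    x6 = (sigma / r) ** 6
    out = np.where(r < rcut, 24.0 * eps * (2.0 * x6 * x6 - x6) / r, 0.0)
    return float(out) if out.ndim == 0 else out


def harmonic_bond_energy(r, kb: float, r0: float):
    """Adhesive bond energy kb (r - r0)^2 — note: no 1/2 prefactor."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    out = kb * (r - r0) ** 2
    return float(out) if out.ndim == 0 else out


def harmonic_bond_force_mag(r, kb: float, r0: float):
    """Restoring force magnitude 2 kb |r - r0| (toward r0)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * kb * np.abs(r - r0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# bodies
# ---------------------------------------------------------------------------

@dataclass
class VWFChain:
    """A single VWF polymer: bead positions, activation flags, parameters."""

    positions: np.ndarray  # (Nm, 3) [Dr], unwrapped
    active: np.ndarray  # (Nm,) bool
    params: VWFParams

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        n = self.positions.shape[0]
        if n < 3:
            raise ValueError(f"a VWF chain needs at least 3 monomers, got {n}")
        if self.active.shape != (n,):
            raise ValueError("activation flags must match the number of monomers")

    @property
    def Nm(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def radius_of_gyration(self) -> float:
        d = self.positions - self.positions.mean(axis=0)
        return float(np.sqrt((d**2).sum(axis=1).mean()))


@dataclass
class PlateletBody:
    """Rigid oblate platelet: pose plus shared body-frame template vertices."""

    com: np.ndarray  # (3,) [Dr]
    orientation: np.ndarray  # (4,) unit quaternion (w, x, y, z)
    template: np.ndarray  # (Nv, 3) body-frame vertex coordinates [Dr]
    occupancy: np.ndarray = field(default=None)  # (Nv,) bool, bond per vertex

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.template = np.asarray(self.template, dtype=float)
        if self.occupancy is None:
            self.occupancy = np.zeros(self.template.shape[0], dtype=bool)

    @property
    def Nv(self) -> int:
        return self.template.shape[0]

    def world_vertices(self) -> np.ndarray:
        return rigid_transform(self)


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z convention)
# ---------------------------------------------------------------------------

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation vector (axis * angle)."""
    v = np.asarray(v, dtype=float)
    angle = float(np.linalg.norm(v))
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / angle
    s = math.sin(angle / 2.0)
    return np.array([math.cos(angle / 2.0), s * axis[0], s * axis[1], s * axis[2]])


def rigid_transform(body: PlateletBody) -> np.ndarray:
    """World-frame vertices = R(orientation) @ template + com.

    Renormalizes the quaternion, warning if its norm has drifted by more
    than 1e-6 from unity.
    """
    q = body.orientation
    norm = float(np.linalg.norm(q))
    if norm == 0.0:
        raise ValueError("zero quaternion cannot be normalized")
    if abs(norm - 1.0) > 1e-6:
        warnings.warn(
            f"quaternion norm drifted to {norm:.8f}; renormalizing", RuntimeWarning
        )
    qn = q / norm
    body.orientation = qn
    R = quat_to_matrix(qn)
    return body.template @ R.T + body.com


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def build_chain(
    n: int,
    spacing: float,
    shape: str = "straight",
    rng: np.random.Generator | None = None,
    params: VWFParams | None = None,
    max_retries: int = 2000,
) -> VWFChain:
    """Construct a chain of ``n`` beads with the given nominal bond spacing.

    ``shape="straight"`` gives a collinear chain along x with uniform
    spacing.  ``shape="globule-seed"`` gives a compact self-avoiding random
    walk confined to a ball — a starting point for the short zero-shear
    equilibration that produces proper globules (the self-attraction defines
    the globule; there is no closed form for it).
    """
    params = params or VWFParams(Nm=n)
    if n < 3:
        raise ValueError(f"need at least 3 beads, got {n}")
    if spacing >= params.rmax:
        raise ValueError(f"spacing {spacing} must be below rmax={params.rmax}")
    if shape == "straight":
        pos = np.zeros((n, 3))
        pos[:, 0] = spacing * np.arange(n)
    elif shape == "globule-seed":
        if rng is None:
            rng = np.random.default_rng()
        sigma = params.sigma
        min_sep = 0.8 * WCA_CUT_FACTOR * sigma
        ball_radius = 0.75 * sigma * n ** (1.0 / 3.0) + sigma
        pos = np.zeros((n, 3))
        for i in range(1, n):
            placed = False
            for _ in range(max_retries):
                step = rng.normal(size=3)
                step *= spacing / np.linalg.norm(step)
                cand = pos[i - 1] + step
                if np.linalg.norm(cand) > ball_radius:
                    continue
                if i >= 2 and np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) < min_sep:
                    continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"globule seed packing failed at bead {i} after {max_retries} tries"
                )
    else:
        raise ValueError(f"unknown chain shape {shape!r}")
    return VWFChain(positions=pos, active=np.zeros(n, dtype=bool), params=params)


# ---------------------------------------------------------------------------
# platelet template
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron vertices and edges."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1.0, phi)]:
        verts += [
            (-a, b, 0), (a, b, 0), (-a, -b, 0), (a, -b, 0),
            (0, -a, b), (0, a, b), (0, -a, -b), (0, a, -b),
            (b, 0, -a), (b, 0, a), (-b, 0, -a), (-b, 0, a),
        ]
    v = np.array(verts, dtype=float)
    v /= np.linalg.norm(v, axis=1)[:, None]
    # edges = vertex pairs at the minimal distance
    d = np.linalg.norm(v[:, None] - v[None, :], axis=2)
    dmin = np.min(d[d > 1e-9])
    edges = np.argwhere((d < dmin * 1.01) & (d > 1e-9))
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    return v, edges


def _subdivide(verts: np.ndarray, n_target: int) -> np.ndarray:
    """Loop-style subdivision of the icosahedral sphere to 42 or 162 vertices."""
    from scipy.spatial import ConvexHull as _CH

    v = verts.copy()
    while v.shape[0] < n_target:
        hull = _CH(v)
        mids = set()
        for simplex in hull.simplices:
            for i in range(3):
                a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                mids.add((a, b))
        new = [v]
        for a, b in sorted(mids):
            m = v[a] + v[b]
            new.append((m / np.linalg.norm(m))[None, :])
        v = np.vstack(new)
    return v


def make_platelet_template(
    Nv: int = 60,
    diameter: float | None = None,
    aspect: float = 0.3,
) -> np.ndarray:
    """Vertices of an oblate spheroid (semi-axes a, a, c = aspect*a) [Dr].

    Supported vertex counts come from icosahedral triangulations projected to
    the sphere and scaled onto the spheroid: 12 (icosahedron), 42 and 162
    (subdivisions), and 60 (truncated icosahedron, whose vertices are the
    edge-trisection points of the icosahedron).  All vertices satisfy
    (x/a)^2 + (y/a)^2 + (z/c)^2 = 1 exactly.
    """
    if Nv < 12:
        raise ValueError(f"need at least 12 vertices, got {Nv}")
    if diameter is None:
        # 2 um expressed in Dr
        diameter = 2.0 / (DEFAULT_UNITS.Dr_phys * 1e6)
    if Nv in (12, 42, 162):
        v, _ = _icosahedron()
        sphere = _subdivide(v, Nv)
    elif Nv == 60:
        v, edges = _icosahedron()
        pts = []
        for a, b in edges:
            pts.append(v[a] + (v[b] - v[a]) / 3.0)
            pts.append(v[a] + 2.0 * (v[b] - v[a]) / 3.0)
        sphere = np.array(pts)
        sphere /= np.linalg.norm(sphere, axis=1)[:, None]
    else:
        raise ValueError(
            f"no icosahedral triangulation with Nv={Nv}; supported: 12, 42, 60, 162"
        )
    a = diameter / 2.0
    c = aspect * a
    tmpl = sphere * np.array([a, a, c])
    return tmpl - tmpl.mean(axis=0)


def template_area_volume(template: np.ndarray) -> tuple[float, float]:
    """Surface area and volume of the convex hull of the template vertices."""
    hull = ConvexHull(template)
    return float(hull.area), float(hull.volume)


def export_mesh_obj(template: np.ndarray, path) -> None:
    """Write the template triangulation as a Wavefront OBJ text file."""
    hull = ConvexHull(template)
    with open(path, "w") as fh:
        fh.write("# vwfsim platelet template mesh\n")
        for v in template:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for s in hull.simplices:
            fh.write(f"f {s[0] + 1} {s[1] + 1} {s[2] + 1}\n")
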