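"""Quantitative observables: aggregates, shapes, stretching, positions.

Aggregates are connected components of the body-level bond graph — nodes are
whole bodies (a chain or a platelet), with an edge wherever at least one
live adhesive bond connects them — found with a union-find structure.
Shape is characterized by the gyration tensor of all member particles with
equal weights: a platelet contributes its Nv vertices, a chain its Nm beads.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DisjointSet",
    "find_aggregates",
    "gyration_eigenvalues",
    "asphericity",
    "com_wall_distance",
    "end_to_end_distribution",
    "aggregation_phase_map",
]


class DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def components(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            groups.setdefault(self.find(i), []).append(i)
        return sorted(groups.values(), key=len, reverse=True)


def find_aggregates(edges, n_bodies: int) -> list[list[int]]:
    """Connected components of the body bond graph, largest first.

    ``edges`` is an iterable of (body_i, body_j) pairs; singletons are
    included, so cluster sizes always sum to ``n_bodies``.
    """
    dsu = DisjointSet(n_bodies)
    for a, b in edges:
        dsu.union(int(a), int(b))
    return dsu.components()


def gyration_eigenvalues(points: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the mass-uniform gyration tensor."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need an (M, 3) array with M >= 2")
    d = pts - pts.mean(axis=0)
    g = d.T @ d / pts.shape[0]
    ev = np.linalg.eigvalsh(g)[::-1]
    return np.clip(ev, 0.0, None)


def asphericity(points: np.ndarray) -> float:
    """Gyration-tensor asphericity.

    alpha = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / (2 Rg^4) with
    Rg^2 = l1 + l2 + l3; 0 for an isotropic point set, 1 for a rod.
    Raises for coincident points (Rg = 0).
    """
    l1, l2, l3 = gyration_eigenvalues(points)
    rg2 = l1 + l2 + l3
    if rg2 == 0.0:
        raise ValueError("asphericity undefined: all points coincide (Rg = 0)")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    return float(num / (2.0 * rg2**2))


def com_wall_distance(y_com: float, Ly: float) -> float:
    """Distance of a centre of mass to the nearest wall (walls at y=0, Ly)."""
    return float(min(y_com, Ly - y_com))


def end_to_end_distribution(
    e2e_values: np.ndarray,
    in_aggregate: np.ndarray,
    bins=30,
    range_=None,
) -> dict:
    """Normalized end-to-end histograms for free vs in-aggregate chains.

    ``e2e_values`` are per-(chain, frame) end-to-end distances and
    ``in_aggregate`` the matching boolean membership flags; the two
    populations are disjoint and exhaustive by construction.  Empty
    populations are flagged rather than raising.
    """
    e2e = np.asarray(e2e_values, dtype=float)
    mask = np.asarray(in_aggregate, dtype=bool)
    if e2e.shape != mask.shape:
        raise ValueError("values and membership flags must align")
    if range_ is None:
        range_ = (0.0, float(e2e.max()) if e2e.size else 1.0)
    out = {}
    for label, sel in (("free", ~mask), ("in_aggregate", mask)):
        vals = e2e[sel]
        if vals.size == 0:
            out[label] = dict(counts=np.zeros(0), edges=np.zeros(0), empty=True)
            continue
        counts, edges = np.histogram(vals, bins=bins, range=range_, density=True)
        out[label] = dict(counts=counts, edges=edges, empty=False)
    return out


def aggregation_phase_map(
    shear_rates: np.ndarray,
    lifetimes: np.ndarray,
    gamma_c: float = 2000.0,
    tl_star: float = 1.0,
) -> np.ndarray:
    """Boolean aggregation-condition map over a (shear rate, lifetime) grid.

    Aggregation is expected iff the shear rate is high enough to stretch and
    activate VWF (gdot >= gamma_c) *and* bonds live long enough to stabilize
    an aggregate (tl >= tl_star); boundary points count as aggregating.
    """
    if gamma_c <= 0 or tl_star <= 0:
        raise ValueError("thresholds must be positive")
    g = np.asarray(shear_rates, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    return (g[:, None] >= gamma_c) & (t[None, :] >= tl_star)
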