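"""Geometric shear-activation of VWF monomers.

A monomer may form adhesive bonds only while the chain is locally stretched
around it.  Two purely geometric criteria are evaluated every step:

* angle criterion — the angle between the two backbone bonds meeting at
  monomer ``i`` satisfies ``theta >= theta_thres`` (180 deg = straight);
  the first/last bead and the second/penultimate bead are exempt, since the
  angle test is defined only for strictly interior monomers;
* neighbor criterion — no *same-chain*, non-bonded monomer
  (``j != i, i±1``) lies within ``R_thres``; this prohibits activation
  inside a collapsed globule.

A monomer is active iff both hold; flags are recomputed idempotently from
geometry, so deactivation happens as soon as either criterion fails.
Activation gates bond *formation* only — rupture of an existing bond remains
governed by the off-rate law.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .mechanics import VWFChain

__all__ = ["bond_angle", "update_activation", "activation_flags"]


def bond_angle(p_a, p_b, p_c) -> float:
    """Angle at ``p_b`` between segments (b->a) and (b->c), in degrees.

    180 deg means collinear (locally straight); 0 deg means folded back.
    Raises if either segment has zero length.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    u = p_a - p_b
    v = p_c - p_b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("undefined angle: zero-length bond vector")
    c = float(np.dot(u, v) / (nu * nv))
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def activation_flags(
    positions: np.ndarray,
    theta_thres_deg: float,
    R_thres: float,
) -> np.ndarray:
    """Pure function: activation flags for one chain's bead positions.

    Degenerate geometry (a zero-length backbone bond makes the angle
    undefined) marks the affected monomer inactive with a warning.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 3:
        raise ValueError("activation needs at least 3 beads")
    flags = np.ones(n, dtype=bool)

    # angle criterion for strictly interior monomers (index 2 .. n-3, 0-based)
    cos_thres = math.cos(math.radians(theta_thres_deg))
    bonds = np.diff(pos, axis=0)  # (n-1, 3), bond i connects bead i and i+1
    blen = np.linalg.norm(bonds, axis=1)
    degenerate = blen == 0.0
    if np.any(degenerate):
        warnings.warn("zero-length backbone bond: affected monomers deactivated")
    for i in range(2, n - 2):
        u = -bonds[i - 1]
        v = bonds[i]
        if blen[i - 1] == 0.0 or blen[i] == 0.0:
            flags[i] = False
            continue
        cos_angle = float(np.dot(u, v)) / (blen[i - 1] * blen[i])
        # theta >= theta_thres  <=>  cos(theta) <= cos(theta_thres)
        if cos_angle > cos_thres:
            flags[i] = False
    # beads adjacent to a degenerate bond are also geometrically ill-defined
    for k in np.nonzero(degenerate)[0]:
        flags[k] = False
        flags[k + 1] = False

    # neighbor criterion: any same-chain monomer with |i-j| > 1 within R_thres
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    idx = np.arange(n)
    nonbonded = np.abs(idx[:, None] - idx[None, :]) > 1
    close = (d <= R_thres) & nonbonded
    flags &= ~close.any(axis=1)
    return flags


def update_activation(chain: VWFChain) -> np.ndarray:
    """Recompute and store the chain's activation flags from its geometry."""
    flags = activation_flags(
        chain.positions,
        chain.params.theta_thres_deg,
        chain.params.R_thres,
    )
    chain.active = flags
    return flags
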