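"""Trajectory, event-log and report output.

Trajectories use extended-XYZ text frames with per-particle columns
(species, body id, active flag, x, y, z); bond events go to CSV; per-run
reports to JSON with a provenance block (config hash, seed, code version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_xyz_frame",
    "read_xyz",
    "write_events_csv",
    "write_report_json",
    "config_hash",
]


def write_xyz_frame(fh, state, comment_extra: str = "") -> None:
    """Append one extended-XYZ frame for the current state."""
    rows = []
    for ci, chain in enumerate(state.chains):
        for k in range(chain.Nm):
            p = chain.positions[k]
            rows.append(("VWF", ci, int(chain.active[k]), p[0], p[1], p[2]))
    for pi, plat in enumerate(state.platelets):
        verts = plat.world_vertices()
        body = state.n_chains + pi
        for k in range(verts.shape[0]):
            v = verts[k]
            rows.append(("PLT", body, int(plat.occupancy[k]), v[0], v[1], v[2]))
    fh.write(f"{len(rows)}\n")
    fh.write(
        'Properties=species:S:1:body:I:1:active:I:1:pos:R:3 '
        f"Time={state.t:.9g} {comment_extra}".rstrip() + "\n"
    )
    for sp, body, act, x, y, z in rows:
        fh.write(f"{sp} {body} {act} {x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path) -> list[pd.DataFrame]:
    """Read an extended-XYZ trajectory back as one DataFrame per frame."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            t = np.nan
            for tok in comment.split():
                if tok.startswith("Time="):
                    t = float(tok[5:])
            recs = []
            for _ in range(n):
                parts = fh.readline().split()
                recs.append(
                    (parts[0], int(parts[1]), int(parts[2]),
                     float(parts[3]), float(parts[4]), float(parts[5]))
                )
            df = pd.DataFrame(recs, columns=["species", "body", "active", "x", "y", "z"])
            df.attrs["time"] = t
            frames.append(df)
    return frames


def write_events_csv(events: pd.DataFrame, path) -> None:
    cols = ["t_formed", "t_ruptured", "monomer_gid", "vertex_gid", "r_at_rupture", "model_name"]
    events.reindex(columns=cols).to_csv(path, index=False)


def config_hash(config) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
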