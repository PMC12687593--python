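"""Canonical model parameters and validated configuration schema.

All lengths are in units of the effective RBC diameter ``Dr``, energies in
``kBT`` and rates in ``1/tau`` unless a field name says otherwise.  The
defaults reproduce the published parameterization of the VWF bead-spring
chain, the rigid oblate platelet, the excluded-volume table and the five
adhesive bond models (catch-slip M1/M2/M3, pure slip, fixed off-rate).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "VWFParams",
    "PlateletParams",
    "RepulsionTable",
    "BondModel",
    "BOND_PRESETS",
    "bond_preset",
    "FlowParams",
    "DomainParams",
    "OutputParams",
    "SimulationConfig",
    "load_config",
]


class VWFParams(BaseModel):
    """Self-attractive, shear-activated bead-spring chain."""

    Nm: int = Field(30, ge=3, description="monomers per chain")
    sigma: float = Field(0.077, gt=0, description="bead diameter [Dr]")
    ks: float = Field(25_000.0, gt=0, description="FENE stiffness [kBT/sigma^2]")
    rmax_factor: float = Field(2.0, gt=1, description="FENE max extension [sigma]")
    eps: float = Field(16.0, ge=0, description="LJ self-attraction depth [kBT]")
    r_lj_factor: float = Field(2.5, gt=1, description="intra-chain LJ cutoff [sigma]")
    theta_thres_deg: float = Field(150.0, ge=0, le=180, description="activation angle threshold")
    R_thres_factor: float = Field(1.2, gt=0, description="activation neighbor radius [sigma]")

    @property
    def rmax(self) -> float:
        """FENE maximum extension [Dr]."""
        return self.rmax_factor * self.sigma

    @property
    def r_lj(self) -> float:
        """Intra-chain LJ cutoff [Dr]."""
        return self.r_lj_factor * self.sigma

    @property
    def R_thres(self) -> float:
        """Activation neighbor radius [Dr]."""
        return self.R_thres_factor * self.sigma

    @property
    def ks_red(self) -> float:
        """FENE stiffness in [kBT/Dr^2]."""
        return self.ks / self.sigma**2

    @property
    def contour_length(self) -> float:
        """Nominal contour length (Nm-1) * sigma [Dr]."""
        return (self.Nm - 1) * self.sigma


class PlateletParams(BaseModel):
    """Rigid oblate colloid with surface receptor vertices."""

    Nv: int = Field(60, ge=12, description="receptor vertices")
    diameter_um: float = Field(2.0, gt=0, description="oblate diameter [um]")
    aspect: float = Field(0.3, gt=0, le=1, description="aspect ratio c/a")
    area_Dr2: float = Field(0.162, gt=0, description="reference surface area [Dr^2]")
    volume_Dr3: float = Field(0.0041, gt=0, description="reference volume [Dr^3]")


class RepulsionTable(BaseModel):
    """Per-pair excluded-volume (purely repulsive LJ) diameters [Dr]."""

    vwf_vwf: float = Field(0.077, gt=0)
    platelet_vwf: float = Field(0.062, gt=0)
    platelet_platelet: float = Field(0.046, gt=0)
    eps: float = Field(16.0, gt=0, description="repulsion strength [kBT]")

    def cutoff(self, sigma: float) -> float:
        """WCA cutoff 2^(1/6) sigma for a pair diameter."""
        return 2.0 ** (1.0 / 6.0) * sigma

    @property
    def max_cutoff(self) -> float:
        return self.cutoff(max(self.vwf_vwf, self.platelet_vwf, self.platelet_platelet))


class BondModel(BaseModel):
    """Two-pathway (catch + slip) dissociation law and harmonic bond.

    The off-rate is ``koff(r) = kc0 exp(lc (r-xeq) dc / kBT)
    + ks0 exp(ls (r-xeq) ds / kBT)`` with ``dc = xc - xeq <= 0`` and
    ``ds = xs - xeq >= 0``; lengths in Dr, rates in 1/tau, spring-like
    strengths ``lc, ls`` in kBT/Dr^2 (so the exponents are dimensionless
    with kBT = 1 in reduced units).
    """

    name: str = "custom"
    kc0: float = Field(..., ge=0, description="catch equilibrium off-rate [1/tau]")
    ks0: float = Field(..., ge=0, description="slip equilibrium off-rate [1/tau]")
    xc: float = Field(..., ge=0, description="catch characteristic length [Dr]")
    xeq: float = Field(..., ge=0, description="equilibrium characteristic length [Dr]")
    xs: float = Field(..., ge=0, description="slip characteristic length [Dr]")
    lambda_c: float = Field(1.06e5, ge=0, description="catch strength [kBT/Dr^2]")
    lambda_s: float = Field(1.06e5, ge=0, description="slip strength [kBT/Dr^2]")
    kon: float = Field(5760.0, ge=0, description="association rate [1/tau]")
    rcut_on: float = Field(0.068, gt=0, description="association cutoff [Dr]")
    rcut_off: float = Field(0.23, gt=0, description="dissociation cutoff [Dr]")
    kb: float = Field(8.45e6, gt=0, description="harmonic bond strength [kBT/Dr^2]")
    r0: float = Field(0.062, gt=0, description="harmonic bond rest length [Dr]")

    @model_validator(mode="after")
    def _check_ordering(self) -> "BondModel":
        if not (self.xc <= self.xeq <= self.xs):
            raise ValueError(
                f"bond model requires xc <= xeq <= xs, got "
                f"xc={self.xc}, xeq={self.xeq}, xs={self.xs}"
            )
        return self

    @property
    def delta_c(self) -> float:
        """Catch length offset xc - xeq [Dr] (non-positive)."""
        return self.xc - self.xeq

    @property
    def delta_s(self) -> float:
        """Slip length offset xs - xeq [Dr] (non-negative)."""
        return self.xs - self.xeq


#: Published bond-model presets; lengths in Dr, rates in 1/tau.
BOND_PRESETS: dict[str, dict] = {
    "m1": dict(name="m1", kc0=5.76e-1, xc=0.0385, xeq=0.062, ks0=5.76e-4, xs=0.067),
    "m2": dict(name="m2", kc0=1.73e-2, xc=0.0517, xeq=0.054, ks0=1.73e-5, xs=0.059),
    "m3": dict(name="m3", kc0=3.46e-3, xc=0.05098, xeq=0.051, ks0=3.46e-6, xs=0.056),
    "slip": dict(name="slip", kc0=0.0, xc=0.062, xeq=0.062, ks0=5.76e-4, xs=0.067),
    "fixed": dict(name="fixed", kc0=5.77e-1, xc=0.062, xeq=0.062, ks0=0.0, xs=0.062),
}


def bond_preset(name: str) -> BondModel:
    """Return one of the published bond models by name (m1, m2, m3, slip, fixed)."""
    key = name.lower()
    if key not in BOND_PRESETS:
        raise KeyError(f"unknown bond preset {name!r}; choose from {sorted(BOND_PRESETS)}")
    return BondModel(**BOND_PRESETS[key])


class FlowParams(BaseModel):
    """Prescribed background flow between walls at y=0 and y=Ly."""

    type: Literal["couette", "poiseuille", "quiescent"] = "couette"
    shear_rate_per_s: Optional[float] = Field(
        None, description="couette shear rate [1/s] (physical units)"
    )
    fn: Optional[float] = Field(
        None, description="poiseuille driving force density [kBT/rc^4]"
    )
    rc_Dr: float = Field(0.23, gt=0, description="fluid cutoff used to express fn [Dr]")

    @model_validator(mode="after")
    def _check_drive(self) -> "FlowParams":
        if self.type == "couette" and self.shear_rate_per_s is None:
            raise ValueError("couette flow requires shear_rate_per_s")
        if self.type == "poiseuille" and self.fn is None:
            raise ValueError("poiseuille flow requires fn")
        return self


class DomainParams(BaseModel):
    """Rectangular domain; periodic in x and z, walls in y."""

    Lx_um: float = Field(10.0, gt=0)
    Ly_um: float = Field(10.0, gt=0)
    Lz_um: float = Field(10.0, gt=0)
    walls: bool = True


class OutputParams(BaseModel):
    stride_tau: float = Field(0.5, gt=0, description="observable stride [tau]")
    trajectory: bool = False
    trajectory_stride_tau: float = Field(2.0, gt=0)


class SimulationConfig(BaseModel):
    """Complete, schema-validated description of one simulation run."""

    seed: int = Field(..., ge=0)
    n_vwf: int = Field(4, ge=0)
    n_platelet: int = Field(16, ge=0)
    duration_tau: float = Field(50.0, gt=0)
    dt_tau: Optional[float] = Field(
        None, gt=0, description="timestep [tau]; default from stability rule"
    )
    drag_calibration: float = Field(
        0.36,
        gt=0,
        description=(
            "dimensionless multiplier on the Stokes bead drag; calibrated once "
            "so the single-chain globule-stretch threshold sits near 2000 1/s"
        ),
    )
    bond_model: str = "m1"
    bond_custom: Optional[BondModel] = Field(
        None, description="overrides bond_model with explicit parameters"
    )
    vwf: VWFParams = VWFParams()
    platelet: PlateletParams = PlateletParams()
    repulsion: RepulsionTable = RepulsionTable()
    flow: FlowParams = FlowParams(shear_rate_per_s=4000.0)
    domain: DomainParams = DomainParams()
    output: OutputParams = OutputParams()

    def bond(self) -> BondModel:
        if self.bond_custom is not None:
            return self.bond_custom
        return bond_preset(self.bond_model)


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return SimulationConfig(**raw)
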