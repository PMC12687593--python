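"""Unit systems and closed-form setup arithmetic.

The simulation engine works throughout in *reduced units*:

* length  — the effective red-blood-cell diameter ``Dr`` (with membrane area
  ``Ar`` the defining quantity, ``Dr = sqrt(Ar/pi)``),
* energy  — the thermal energy ``kBT`` at body temperature (310 K),
* time    — the viscous-elastic scale ``tau = eta * Dr / mu_r`` built from the
  plasma viscosity and the RBC membrane shear modulus.

The native units of the underlying mesoscale fluid model (in which, e.g., the
viscosity is quoted as ``eta = 100`` and ``kBT = 0.1``) are retained only for
bookkeeping of printed setup numbers such as the wall shear rate and the fluid
particle budget; everything downstream of this module uses reduced units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "UnitSystem",
    "DEFAULT_UNITS",
    "effective_rbc_diameter",
    "time_scale",
    "wall_shear_rate",
    "domain_budget",
    "parse_dims",
]

#: Boltzmann constant [J/K] (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


def effective_rbc_diameter(area: float) -> float:
    """Effective RBC diameter ``Dr = sqrt(Ar/pi)`` from the membrane area.

    Works in any consistent unit system: an area in ``m^2`` yields a length in
    metres, an area in simulation units yields a simulation length.
    """
    if not (area > 0.0) or not math.isfinite(area):
        raise ValueError(f"membrane area must be positive and finite, got {area!r}")
    return math.sqrt(area / math.pi)


def time_scale(eta: float, Dr: float, mu_r: float) -> float:
    """Viscous-elastic time scale ``tau = eta * Dr / mu_r``.

    Parameters must share a consistent unit system (all physical or all
    simulation units); the result then carries that system's time unit.
    """
    for name, v in (("eta", eta), ("Dr", Dr), ("mu_r", mu_r)):
        if not (v > 0.0) or not math.isfinite(v):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    return eta * Dr / mu_r


@dataclass(frozen=True)
class UnitSystem:
    """Maps between simulation and physical units.

    Attributes
    ----------
    Ar_sim:
        RBC membrane area in native simulation length units squared.
    kBT_sim:
        Thermal energy in native simulation energy units.
    eta_plasma:
        Blood-plasma viscosity [Pa s].
    mu_rbc_phys:
        RBC membrane shear modulus [N/m].
    T:
        Temperature [K].
    eta_sim:
        Fluid viscosity in native simulation units.
    mu_rbc_red:
        RBC membrane shear modulus in reduced units [kBT/Dr^2].
    """

    Ar_sim: float = 132.83
    kBT_sim: float = 0.1
    eta_plasma: float = 1.2e-3
    mu_rbc_phys: float = 4.83e-6
    T: float = 310.0
    eta_sim: float = 100.0
    mu_rbc_red: float = 4.77e4

    # ---- derived scales -------------------------------------------------

    @property
    def Dr_sim(self) -> float:
        """Effective RBC diameter in native simulation length units."""
        return effective_rbc_diameter(self.Ar_sim)

    @property
    def kBT_phys(self) -> float:
        """Thermal energy [J]."""
        return BOLTZMANN_J_PER_K * self.T

    @property
    def Dr_phys(self) -> float:
        """Effective RBC diameter [m].

        The membrane area that defines ``Dr`` is ``Ar_sim`` read in 1e-12 m^2,
        so one native simulation length unit corresponds to one micrometre.
        """
        return effective_rbc_diameter(self.Ar_sim * 1e-12)

    @property
    def tau_phys(self) -> float:
        """Reduced time unit [s], ``tau = eta_plasma * Dr / mu_rbc``."""
        return time_scale(self.eta_plasma, self.Dr_phys, self.mu_rbc_phys)

    @property
    def tau_sim(self) -> float:
        """Reduced time unit expressed in native simulation time units."""
        mu_native = self.mu_rbc_red * self.kBT_sim / self.Dr_sim**2
        return time_scale(self.eta_sim, self.Dr_sim, mu_native)

    @property
    def t0_phys(self) -> float:
        """One native simulation time unit in seconds."""
        return self.tau_phys / self.tau_sim

    @property
    def length_scale_m(self) -> float:
        """Metres per native simulation length unit (1e-6 by construction)."""
        return self.Dr_phys / self.Dr_sim

    @property
    def eta_red(self) -> float:
        """Fluid viscosity in reduced units [kBT tau / Dr^3].

        From ``tau = eta * Dr / mu_r`` with ``Dr = tau = 1`` in reduced units,
        the reduced viscosity equals the reduced membrane shear modulus.
        """
        return self.mu_rbc_red

    # ---- conversions ----------------------------------------------------

    def scale_factor(self, length: int = 0, energy: int = 0, time: int = 0) -> float:
        """Physical value of one reduced unit of dimension Dr^a kBT^b tau^c."""
        return self.Dr_phys**length * self.kBT_phys**energy * self.tau_phys**time

    def to_physical(self, value: float, length: int = 0, energy: int = 0, time: int = 0) -> float:
        """Convert a quantity from reduced units (Dr, kBT, tau) to SI."""
        return value * self.scale_factor(length, energy, time)

    def to_reduced(self, value: float, length: int = 0, energy: int = 0, time: int = 0) -> float:
        """Convert a quantity from SI to reduced units (Dr, kBT, tau)."""
        return value / self.scale_factor(length, energy, time)

    def convert(self, value: float, dims: str | dict[str, int], direction: str = "to_physical") -> float:
        """Convert ``value`` with dimension signature ``dims``.

        ``dims`` is either a mapping ``{"length": a, "energy": b, "time": c}``
        or a compact string such as ``"E/L2"``, ``"L3"`` or ``"1/T"`` where
        ``L``, ``E`` and ``T`` denote length, energy and time.
        """
        powers = parse_dims(dims) if isinstance(dims, str) else dict(dims)
        unknown = set(powers) - {"length", "energy", "time"}
        if unknown:
            raise ValueError(f"unknown dimension(s): {sorted(unknown)}")
        kw = {k: int(powers.get(k, 0)) for k in ("length", "energy", "time")}
        if direction in ("to_physical", "sim_to_physical"):
            return self.to_physical(value, **kw)
        if direction in ("to_reduced", "physical_to_sim"):
            return self.to_reduced(value, **kw)
        raise ValueError(f"unknown conversion direction {direction!r}")

    def shear_rate_to_reduced(self, gamma_dot_per_s: float) -> float:
        """Physical shear rate [1/s] to reduced units [1/tau]."""
        return gamma_dot_per_s * self.tau_phys

    def shear_rate_to_physical(self, gamma_dot_red: float) -> float:
        """Reduced shear rate [1/tau] to physical units [1/s]."""
        return gamma_dot_red / self.tau_phys


DEFAULT_UNITS = UnitSystem()


_DIM_LETTERS = {"L": "length", "E": "energy", "T": "time"}


def parse_dims(signature: str) -> dict[str, int]:
    """Parse a compact dimension signature like ``"E/L2"`` or ``"L-2 E"``.

    Letters ``L``/``E``/``T`` may be followed by an optional signed integer
    exponent; everything after a single ``/`` has its exponents negated.
    ``"1"`` denotes a dimensionless factor.
    """
    powers: dict[str, int] = {"length": 0, "energy": 0, "time": 0}
    parts = signature.replace("*", " ").split("/")
    if len(parts) > 2:
        raise ValueError(f"at most one '/' allowed in dimension signature {signature!r}")
    for sign, part in zip((1, -1), parts):
        i = 0
        s = part.strip()
        while i < len(s):
            ch = s[i]
            if ch.isspace():
                i += 1
                continue
            if ch == "1":
                i += 1
                continue
            if ch.upper() not in _DIM_LETTERS:
                raise ValueError(f"unknown dimension symbol {ch!r} in {signature!r}")
            dim = _DIM_LETTERS[ch.upper()]
            i += 1
            j = i
            if j < len(s) and s[j] in "+-":
                j += 1
            while j < len(s) and s[j].isdigit():
                j += 1
            exp = int(s[i:j]) if j > i and s[i:j] not in ("+", "-") else 1
            powers[dim] += sign * exp
            i = j
    return powers


def wall_shear_rate(
    fn: float = 81.0,
    Ly_um: float = 40.0,
    eta_sim: float = 100.0,
    rc_Dr: float = 0.23,
    units: UnitSystem = DEFAULT_UNITS,
) -> float:
    """Wall shear rate of the driven channel flow, ``gdot_w = f n Ly / (2 eta)``.

    Parameters
    ----------
    fn:
        Driving force per unit volume (pressure gradient) in units of
        ``kBT / rc^4`` as printed, with ``rc`` the fluid interaction cutoff.
    Ly_um:
        Wall separation [micrometres].
    eta_sim:
        Fluid viscosity in native simulation units.
    rc_Dr:
        Fluid cutoff radius in units of Dr.

    Returns
    -------
    float
        Wall shear rate in physical units [1/s].
    """
    for name, v in (("fn", fn), ("Ly_um", Ly_um), ("eta_sim", eta_sim), ("rc_Dr", rc_Dr)):
        if v < 0 or (name != "fn" and v == 0):
            raise ValueError(f"{name} must be positive (fn may be zero), got {v!r}")
    rc_native = rc_Dr * units.Dr_sim
    fn_native = fn * units.kBT_sim / rc_native**4
    Ly_native = Ly_um * 1e-6 / units.length_scale_m
    gdot_native = fn_native * Ly_native / (2.0 * eta_sim)
    return gdot_native / units.t0_phys


def domain_budget(
    Lx_um: float = 80.0,
    Ly_um: float = 40.0,
    Lz_um: float = 30.0,
    n_per_rc3: float = 16.875,
    rc_Dr: float = 0.23,
    n_rbc: int = 360,
    n_platelet: int = 768,
    n_vwf: int = 384,
    units: UnitSystem = DEFAULT_UNITS,
) -> dict:
    """Fluid-particle budget and naive body volume fractions of the full setup.

    The fluid particle count is ``n * V`` with the number density quoted per
    fluid cutoff volume ``rc^3``.  Volume fractions are computed from the
    printed body volumes (RBC 0.336 Dr^3, platelet 0.0041 Dr^3) and, for a
    polymer, the total excluded volume of its beads; they are the *naive*
    body-volume counts without any effective/excluded-volume convention.
    """
    if min(Lx_um, Ly_um, Lz_um) < 0 or n_per_rc3 <= 0 or rc_Dr <= 0:
        raise ValueError("box dimensions must be non-negative and densities positive")
    V_um3 = Lx_um * Ly_um * Lz_um
    rc_um = rc_Dr * units.Dr_sim  # one native length unit == 1 um
    n_per_um3 = n_per_rc3 / rc_um**3
    fluid_particles = int(round(n_per_um3 * V_um3))

    Dr3_um3 = units.Dr_sim**3
    v_rbc_um3 = 0.336 * Dr3_um3
    v_platelet_um3 = 0.0041 * Dr3_um3
    # 30 beads of diameter 0.077 Dr treated as solid spheres
    v_vwf_um3 = 30 * (math.pi / 6.0) * (0.077 * units.Dr_sim) ** 3
    frac = {
        "rbc": n_rbc * v_rbc_um3 / V_um3 if V_um3 > 0 else 0.0,
        "platelet": n_platelet * v_platelet_um3 / V_um3 if V_um3 > 0 else 0.0,
        "vwf": n_vwf * v_vwf_um3 / V_um3 if V_um3 > 0 else 0.0,
    }
    return {
        "fluid_particles": fluid_particles,
        "volume_fractions": frac,
        "box_volume_um3": V_um3,
    }
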