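"""Svedberg-level analysis of sedimentation-velocity summaries.

Operates on scalar outputs of a boundary-fitting program (sedimentation
coefficient, buffer properties, partial specific volume): corrects s to
standard conditions (water, 20 degC), computes the frictional ratio against
an anhydrous sphere of the same mass, and interconverts (s20w, R_S, MM)
through the Svedberg relation

    MM = s * N_A * 6*pi*eta * R_S / (1 - vbar*rho).

Units: s in Svedberg (1e-13 s), eta in poise, rho in g/ml, vbar in ml/g,
R_S in Å, MM in Da.  Hydration is ignored in the frictional reference
(anhydrous sphere), a deliberate approximation documented in the methods
note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import config

_REF = config.REFERENCE_BUFFER


@dataclass(frozen=True)
class BufferConditions:
    """Solvent state relevant to sedimentation."""

    temperature: float = _REF["temperature"]  # degC
    density: float = _REF["density"]          # g/ml
    viscosity: float = _REF["viscosity"]      # poise
    vbar: float = _REF["vbar"]                # ml/g

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")
        if not (0 < self.vbar < 1.2):
            raise ValueError(f"implausible vbar {self.vbar} ml/g")

    @property
    def buoyancy(self) -> float:
        """(1 - vbar * rho); must be positive for a sedimenting particle."""
        return 1.0 - self.vbar * self.density


WATER_20C = BufferConditions()


@dataclass(frozen=True)
class SVResult:
    """Summary of one sedimentation-velocity run after Svedberg analysis."""

    s_obs: float       # Svedberg
    s20w: float        # Svedberg
    f_over_f0: float
    rs: float          # Å
    app_mm: float      # Da
    shape_call: str    # "globular" | "IDP-like" | "intermediate"

    def to_dict(self) -> dict:
        return {
            "s_obs_svedberg": self.s_obs,
            "s20w_svedberg": self.s20w,
            "f_over_f0": self.f_over_f0,
            "rs_angstrom": self.rs,
            "app_mm_da": self.app_mm,
            "shape_call": self.shape_call,
        }


def _check_buoyant(buf: BufferConditions) -> None:
    if buf.buoyancy <= 0:
        raise ValueError(
            "neutral or floating particle: (1 - vbar*rho) <= 0 "
            f"(vbar={buf.vbar}, rho={buf.density})"
        )


def correct_to_s20w(
    s_obs: float,
    buf: BufferConditions,
    ref: BufferConditions = WATER_20C,
) -> float:
    """Correct an observed s to standard conditions.

    s20w = s_obs * (eta_buf/eta_ref) * (buoyancy_ref/buoyancy_buf).
    """
    _check_buoyant(buf)
    _check_buoyant(ref)
    return s_obs * (buf.viscosity / ref.viscosity) * (ref.buoyancy / buf.buoyancy)


def minimal_sphere_radius(mm: float, vbar: float) -> float:
    """Radius (Å) of the anhydrous sphere of mass mm (Da) and volume mm*vbar."""
    if mm <= 0 or vbar <= 0:
        raise ValueError("mass and vbar must be positive")
    r0_cm = (3.0 * mm * vbar / (4.0 * math.pi * config.AVOGADRO)) ** (1.0 / 3.0)
    return r0_cm * 1e8


def frictional_ratio(mm: float, rs: float, vbar: float = _REF["vbar"]) -> float:
    """f/f0 = R_S / r0 against the anhydrous minimal sphere."""
    if rs <= 0:
        raise ValueError("Stokes radius must be positive")
    return rs / minimal_sphere_radius(mm, vbar)


def classify_frictional_ratio(ff0: float) -> str:
    """Interpret f/f0: ~1.05-1.30 globular, ~1.75-3.0 IDP-like."""
    if ff0 <= config.FF0_GLOBULAR[1]:
        return "globular"
    if ff0 >= config.FF0_IDP[0]:
        return "IDP-like"
    return "intermediate"


def apparent_mass(
    s20w: float, rs: float, buf_ref: BufferConditions = WATER_20C
) -> float:
    """Apparent molecular mass (Da) from the Svedberg relation."""
    if s20w < 0 or rs <= 0:
        raise ValueError("s20w must be >= 0 and rs > 0")
    _check_buoyant(buf_ref)
    s_seconds = s20w * config.SVEDBERG
    rs_cm = rs * 1e-8
    friction = 6.0 * math.pi * buf_ref.viscosity * rs_cm
    return s_seconds * config.AVOGADRO * friction / buf_ref.buoyancy


def rs_from_svedberg(
    s20w: float, mm: float, buf_ref: BufferConditions = WATER_20C
) -> float:
    """Stokes radius (Å) from (s20w, MM); exact inverse of apparent_mass."""
    if s20w <= 0:
        raise ValueError("s20w must be positive")
    if mm <= 0:
        raise ValueError("mass must be positive")
    _check_buoyant(buf_ref)
    s_seconds = s20w * config.SVEDBERG
    rs_cm = mm * buf_ref.buoyancy / (
        config.AVOGADRO * 6.0 * math.pi * buf_ref.viscosity * s_seconds
    )
    return rs_cm * 1e8


def analyze_sv(
    s_obs: float,
    f_over_f0: float,
    buf: BufferConditions,
    ref: BufferConditions = WATER_20C,
) -> SVResult:
    """Full Svedberg chain for one run given (s_obs, f/f0).

    The pair (s, f/f0) determines both the apparent mass and the Stokes
    radius: combining the Svedberg relation with R_S = (f/f0) * r0(MM)
    gives MM^(2/3) = s * N_A * 6*pi*eta * (f/f0) * (3*vbar/(4*pi*N_A))^(1/3)
    / (1 - vbar*rho), evaluated at standard conditions.  This is how a
    boundary-fit (s, f/f0) table is converted to R_S and apparent-MM
    columns.
    """
    if f_over_f0 < 1.0:
        raise ValueError("f/f0 cannot be below 1 for a rigid particle")
    s20w = correct_to_s20w(s_obs, buf, ref)
    _check_buoyant(ref)
    s_seconds = s20w * config.SVEDBERG
    c_cm = (3.0 * ref.vbar / (4.0 * math.pi * config.AVOGADRO)) ** (1.0 / 3.0)
    mm = (
        s_seconds
        * config.AVOGADRO
        * 6.0
        * math.pi
        * ref.viscosity
        * f_over_f0
        * c_cm
        / ref.buoyancy
    ) ** 1.5
    rs = f_over_f0 * minimal_sphere_radius(mm, ref.vbar)
    return SVResult(
        s_obs=s_obs,
        s20w=s20w,
        f_over_f0=f_over_f0,
        rs=rs,
        app_mm=mm,
        shape_call=classify_frictional_ratio(f_over_f0),
    )
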