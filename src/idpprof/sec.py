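"""Size-exclusion chromatography hydrodynamics.

Calibrates a gel-filtration column with standards of known Stokes radius,
converts elution volumes to Stokes radii, and places a (MM, R_S) point among
the compaction states of the protein hydrodynamics literature: native (N),
molten globule (MG), pre-molten globule (PMG), chemically unfolded coil, and
the two natively unfolded IDP states (coil-like and PMG-like).  Each state
obeys a power law R_S = 10^(a + b*log10 MM) with state-specific (a, b);
classification is by nearest law in log10(R_S).

Also provides the equivalent-sphere packing volume V_S = (4/3)*pi*R_S^3 and
density MM/V_S used to argue how loosely a chain fills its hydrodynamic
envelope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import config

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SECColumn:
    """Void and total volume of a gel-filtration column, in ml."""

    v0: float
    vt: float

    def __post_init__(self) -> None:
        if not (0 < self.v0 < self.vt):
            raise ValueError(f"need 0 < v0 < vt, got v0={self.v0}, vt={self.vt}")


@dataclass(frozen=True)
class SECStandard:
    """A calibration standard: molecular mass, Stokes radius, elution volume."""

    name: str
    mm: float                 # Da
    rs: float | None = None   # Å; may be predicted from the native law
    ve: float | None = None   # ml

    def __post_init__(self) -> None:
        if self.mm <= 0:
            raise ValueError(f"{self.name}: mm must be positive")
        if self.rs is not None and self.rs <= 0:
            raise ValueError(f"{self.name}: rs must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line K_AV = intercept + slope * log10(R_S [Å])."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = float("nan")
    kav_range: tuple[float, float] = (float("-inf"), float("inf"))


@dataclass(frozen=True)
class ScalingLawSet:
    """Per-state (a, b) pairs for log10(R_S) = a + b*log10(MM)."""

    laws: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(config.SCALING_LAWS)
    )

    def __post_init__(self) -> None:
        for state, (_, b) in self.laws.items():
            if b <= 0:
                raise ValueError(f"scaling exponent for {state!r} must be > 0")

    def states(self) -> list[str]:
        return list(self.laws)


@dataclass(frozen=True)
class HydroProfile:
    """Hydrodynamic characterization of one (MM, R_S) point."""

    mm: float                 # Da
    rs: float                 # Å
    vs: float                 # Å^3
    density: float            # kDa / Å^3
    state_label: str          # compaction family, e.g. "coil-like"
    nearest_state: str        # the single nearest scaling state
    distances_to_states: dict[str, float]  # |Δ log10 R_S| per state

    def to_dict(self) -> dict:
        return {
            "mm_da": self.mm,
            "rs_angstrom": self.rs,
            "vs_cubic_angstrom": self.vs,
            "density_kda_per_cubic_angstrom": self.density,
            "state_label": self.state_label,
            "nearest_state": self.nearest_state,
            "distances_to_states": dict(self.distances_to_states),
        }


# The six standards used to calibrate a Superdex200-class column, with their
# literature Stokes radii (reproduced exactly by the native scaling law).
DEFAULT_STANDARDS: tuple[SECStandard, ...] = (
    SECStandard("thyroglobulin", 669_000, 75.1),
    SECStandard("apoferritin", 443_000, 64.8),
    SECStandard("beta-amylase", 200_000, 48.8),
    SECStandard("alcohol dehydrogenase", 150_000, 44.0),
    SECStandard("albumin", 66_000, 32.9),
    SECStandard("carbonic anhydrase", 29_000, 24.5),
)


def kav(ve: float, column: SECColumn) -> float:
    """Gel-phase distribution coefficient K_AV = (V_E - V_0)/(V_T - V_0)."""
    if ve < 0:
        raise ValueError("elution volume must be non-negative")
    return (ve - column.v0) / (column.vt - column.v0)


def rs_scaling_predict(
    mm: float, state: str = "native", laws: ScalingLawSet | None = None
) -> float:
    """Predicted Stokes radius (Å) for a mass in a given compaction state."""
    laws = laws or ScalingLawSet()
    if mm <= 0:
        raise ValueError("molecular mass must be positive")
    if state not in laws.laws:
        raise ValueError(
            f"unknown state {state!r}; available: {sorted(laws.laws)}"
        )
    a, b = laws.laws[state]
    return 10.0 ** (a + b * math.log10(mm))


def fit_calibration(
    standards: list[SECStandard], column: SECColumn
) -> CalibrationCurve:
    """Least-squares line of K_AV against log10(R_S) over the standards.

    Standards missing either rs or ve are ignored; at least three usable
    points are required.
    """
    usable = [s for s in standards if s.rs is not None and s.ve is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 standards with both rs and ve, got {len(usable)}"
        )
    log_rs = np.array([math.log10(s.rs) for s in usable])
    kavs = np.array([kav(s.ve, column) for s in usable])
    if np.ptp(log_rs) == 0:
        raise ValueError("standards have zero variance in R_S")
    fit = stats.linregress(log_rs, kavs)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_stderr=float(fit.stderr),
        kav_range=(float(kavs.min()), float(kavs.max())),
    )


def rs_from_elution(
    ve: float, column: SECColumn, curve: CalibrationCurve
) -> float:
    """Invert the calibration line at K_AV(ve) to obtain R_S in Å."""
    k = kav(ve, column)
    lo, hi = curve.kav_range
    if not (lo <= k <= hi):
        log.warning(
            "K_AV=%.3f outside the calibrated range [%.3f, %.3f]; "
            "extrapolating", k, lo, hi,
        )
    if curve.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    rs = 10.0 ** ((k - curve.intercept) / curve.slope)
    if not np.isfinite(rs) or rs <= 0:
        raise ValueError(f"non-physical Stokes radius {rs} from K_AV={k}")
    return rs


def sphere_volume_density(mm: float, rs: float) -> tuple[float, float]:
    """Equivalent-sphere volume (Å^3) and packing density (kDa/Å^3)."""
    if mm <= 0 or rs <= 0:
        raise ValueError("mass and radius must be positive")
    vs = (4.0 / 3.0) * math.pi * rs**3
    return vs, (mm / 1000.0) / vs


def classify_compaction_state(
    mm: float, rs: float, laws: ScalingLawSet | None = None
) -> HydroProfile:
    """Assign a (MM, R_S) point to the nearest compaction-state scaling law.

    The distance to each state is |log10(rs) - (a + b*log10(mm))|; the
    reported label is the compaction *family* of the winning state (PMG and
    natively-unfolded PMG both map to "PMG-like"; the two coil states map to
    "coil-like"), which is how such plots are read in practice.
    """
    laws = laws or ScalingLawSet()
    log_rs = math.log10(rs)
    log_mm = math.log10(mm)
    distances = {
        state: abs(log_rs - (a + b * log_mm))
        for state, (a, b) in laws.laws.items()
    }
    nearest = min(distances, key=distances.get)
    family = config.STATE_FAMILIES.get(nearest, nearest)
    vs, density = sphere_volume_density(mm, rs)
    return HydroProfile(
        mm=mm,
        rs=rs,
        vs=vs,
        density=density,
        state_label=family,
        nearest_state=nearest,
        distances_to_states=distances,
    )


def read_standards_csv(path: str | Path) -> list[SECStandard]:
    """Read a standards table (columns: name, mm_da, rs_angstrom, ve_ml).

    rs_angstrom and ve_ml may be blank; a blank rs is filled in from the
    native scaling law, matching how such tables are assembled in practice.
    """
    df = pd.read_csv(path)
    required = {"name", "mm_da"}
    if not required.issubset(df.columns):
        raise ValueError(f"standards CSV must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        mm = float(row["mm_da"])
        rs = row.get("rs_angstrom")
        rs = None if pd.isna(rs) else float(rs)
        if rs is None:
            rs = rs_scaling_predict(mm, "native")
        ve = row.get("ve_ml")
        ve = None if pd.isna(ve) else float(ve)
        out.append(SECStandard(str(row["name"]), mm, rs, ve))
    return out
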