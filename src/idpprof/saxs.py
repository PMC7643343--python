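"""Small-angle X-ray scattering analysis for flexible proteins.

The module covers the standard model-free SAXS chain used to characterize
a disordered chain in solution:

* Guinier analysis -- weighted fit of ln I vs s^2 over a low-angle window
  selected self-consistently so that s*R_g stays below a cutoff, giving
  R_g and I(0);
* Kratky transform s^2*I(s)/I(0) with an operational fold-state call
  (interior peak that decays -> globular; monotone rise to a plateau ->
  disordered);
* regularized indirect Fourier transform of I(s) into the pair distance
  distribution p(r) with endpoint constraints p(0)=p(Dmax)=0 and a
  second-difference smoothness penalty, plus a D_max scan;
* the R_g/R_S shape ratio (0.778 for a hard sphere, ~1.36-2.24 prolate).

The scattering vector is s = 4*pi*sin(theta)/lambda in 1/Å throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SAXSCurve:
    """A background-subtracted scattering profile (s, I, sigma)."""

    s: np.ndarray      # 1/Å, strictly increasing, > 0
    i: np.ndarray      # arbitrary units
    sigma: np.ndarray  # per-point uncertainty, > 0

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        i = np.asarray(self.i, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (len(s) == len(i) == len(sigma)):
            raise ValueError("s, i, sigma must have equal lengths")
        if len(s) < 10:
            raise ValueError("need at least 10 points")
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("s must be strictly increasing and positive")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.s)

    def truncated(self, s_min: float = 0.0, s_max: float = np.inf) -> "SAXSCurve":
        m = (self.s >= s_min) & (self.s <= s_max)
        return SAXSCurve(self.s[m], self.i[m], self.sigma[m])


@dataclass(frozen=True)
class GuinierFit:
    rg: float          # Å
    i0: float
    s_min: float       # 1/Å
    s_max: float       # 1/Å
    srg_max: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PrDistribution:
    """p(r) on an r-grid from 0 to dmax with derived invariants."""

    r: np.ndarray      # Å
    p: np.ndarray
    dmax: float        # Å
    rg: float          # Å, second moment of p(r)
    i0: float
    alpha: float
    chi2: float
    negative_mass_fraction: float = 0.0


@dataclass(frozen=True)
class ShapeClassification:
    ratio: float
    label: str
    intervals: dict = field(default_factory=lambda: dict(config.SHAPE_RATIO_INTERVALS))


def read_dat(path: str | Path) -> SAXSCurve:
    """Read a 3-column ASCII profile (s, I, sigma); '#' lines are comments.

    A header comment containing '1/nm' or 'nm^-1' flags nm^-1 input, which
    is converted to 1/Å.
    """
    path = Path(path)
    in_nm = False
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                if "1/nm" in line or "nm^-1" in line:
                    in_nm = True
                continue
            parts = line.split()
            if len(parts) >= 3:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.array(rows)
    s = arr[:, 0] / 10.0 if in_nm else arr[:, 0]
    return SAXSCurve(s, arr[:, 1], arr[:, 2])


def write_dat(curve: SAXSCurve, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# s[1/A]  I  sigma\n")
        for s, i, sig in zip(curve.s, curve.i, curve.sigma):
            fh.write(f"{s:.6e} {i:.6e} {sig:.6e}\n")


# ---------------------------------------------------------------- Guinier

def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b*x; returns (a, b, r2)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    cov = np.sum(w * (x - xm) * (y - ym))
    var = np.sum(w * (x - xm) ** 2)
    b = cov / var
    a = ym - b * xm
    ss_res = np.sum(w * (y - a - b * x) ** 2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def guinier_fit(
    curve: SAXSCurve,
    srg_cutoff: float = config.GUINIER_SRG_CUTOFF,
    first_point: int = 0,
    min_points: int = config.GUINIER_MIN_POINTS,
    max_iter: int = 50,
) -> GuinierFit:
    """Self-consistent Guinier fit: ln I = ln I0 - (R_g^2/3) s^2.

    Starting from all points below the cutoff assuming a generous initial
    window, the fit iterates until the window implied by s*R_g <= cutoff
    stabilizes.  Points with non-positive intensity are dropped with a
    warning.  `first_point` mimics beamstop trimming.
    """
    s = curve.s[first_point:]
    i = curve.i[first_point:]
    sigma = curve.sigma[first_point:]
    pos = i > 0
    if not np.all(pos):
        warnings.warn(
            f"{np.sum(~pos)} non-positive intensities dropped from Guinier window",
            stacklevel=2,
        )
        s, i, sigma = s[pos], i[pos], sigma[pos]
    if len(s) < min_points:
        raise ValueError("too few positive points for a Guinier fit")

    def fit_window(n_window: int):
        sw = s[:n_window]
        iw = i[:n_window]
        sigw = sigma[:n_window]
        x = sw**2
        y = np.log(iw)
        w = (iw / sigw) ** 2  # sigma_lnI = sigma/I
        return _weighted_line(x, y, w)

    n_window = max(min_points, len(s) // 4)
    seen: set[int] = set()
    for _ in range(max_iter):
        a, b, r2 = fit_window(n_window)
        if b >= 0:
            # no decay in window: widen and retry
            if n_window >= len(s):
                raise ValueError("no decaying Guinier region found")
            n_window = min(len(s), n_window * 2)
            continue
        rg = float(np.sqrt(-3.0 * b))
        n_new = int(np.searchsorted(s * rg, srg_cutoff, side="right"))
        n_new = max(min_points, min(n_new, len(s)))
        if n_new == n_window:
            break
        if n_new in seen:
            # window oscillates between two sizes: settle on the smaller
            n_window = min(n_new, n_window)
            a, b, r2 = fit_window(n_window)
            rg = float(np.sqrt(-3.0 * b))
            break
        seen.add(n_window)
        n_window = n_new
    else:
        raise ValueError("Guinier window iteration did not converge")
    sw = s[:n_window]
    return GuinierFit(
        rg=rg,
        i0=float(np.exp(a)),
        s_min=float(sw[0]),
        s_max=float(sw[-1]),
        srg_max=float(sw[-1] * rg),
        r_squared=float(r2),
        n_points=n_window,
    )


# ----------------------------------------------------------------- Kratky

def kratky_transform(
    curve: SAXSCurve,
    i0: float,
    decay_fraction: float = config.KRATKY_DECAY_FRACTION,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Return (s, s^2*I/I0) plus a fold-state label.

    "globular" requires an interior maximum after which the transform drops
    below `decay_fraction` of the peak before the end of the measured
    range; a transform that climbs to a plateau (or keeps rising) is
    "disordered".
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    y = curve.s**2 * curve.i / i0
    peak = int(np.argmax(y))
    interior = 0 < peak < len(y) - 1
    decays = interior and float(np.min(y[peak:])) < decay_fraction * float(y[peak])
    label = "globular" if decays else "disordered"
    return curve.s, y, label


def dimensionless_kratky(
    curve: SAXSCurve, rg: float, i0: float
) -> tuple[np.ndarray, np.ndarray]:
    """(s*Rg, (s*Rg)^2 * I/I0): the normalized variant of the Kratky plot."""
    x = curve.s * rg
    return x, x**2 * curve.i / i0


# ---------------------------------------------------- indirect transform

def _ift_design(s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Quadrature matrix K with I(s) = K @ p on the r-grid (trapezoid rule)."""
    dr = r[1] - r[0]
    weights = np.full(len(r), dr)
    weights[0] = weights[-1] = dr / 2.0
    sr = np.outer(s, r)
    kernel = np.sinc(sr / np.pi)  # sin(x)/x with the x=0 limit
    return 4.0 * np.pi * kernel * weights[None, :]


def pr_moments(r: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """(I0, Rg) from p(r): I0 = 4*pi*Int p dr; Rg^2 = Int p r^2 dr / (2 Int p dr)."""
    m0 = np.trapezoid(p, r)
    m2 = np.trapezoid(p * r**2, r)
    if m0 <= 0:
        raise ValueError("p(r) has non-positive total mass")
    return float(4.0 * np.pi * m0), float(np.sqrt(m2 / (2.0 * m0)))


def ift_pr(
    curve: SAXSCurve,
    dmax: float,
    alpha: float = config.IFT_ALPHA,
    n_grid: int = config.IFT_N_GRID,
    rg_hint: float | None = None,
) -> PrDistribution:
    """Regularized indirect Fourier transform of I(s) into p(r).

    Solves min || (I - K p)/sigma ||^2 + alpha * || D2 p ||^2 over the
    interior grid values, with p(0) = p(dmax) = 0 hard-coded; D2 is the
    second-difference operator (smoothness prior).  Reported chi2 is the
    reduced residual (1/(N-k)) * sum(((I - Ihat)/sigma)^2) with k the
    number of free grid values (capped so the denominator stays positive).

    Negative excursions of p(r) are allowed by the solver (soft
    positivity); their mass fraction is reported so callers can reject
    implausible solutions.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if rg_hint is not None and dmax < 2.0 * rg_hint:
        log.warning("dmax=%.1f Å is below 2*Rg=%.1f Å; likely too small",
                    dmax, 2.0 * rg_hint)
    r = np.linspace(0.0, dmax, n_grid)
    K = _ift_design(curve.s, r)[:, 1:-1]  # endpoints fixed at zero
    A = K / curve.sigma[:, None]
    y = curve.i / curve.sigma
    k_free = K.shape[1]

    # second differences over the full grid including the clamped endpoints
    n_int = k_free
    D = np.zeros((n_int, n_int))
    for j in range(n_int):
        D[j, j] = -2.0
        if j > 0:
            D[j, j - 1] = 1.0
        if j + 1 < n_int:
            D[j, j + 1] = 1.0
    # scale the penalty relative to the data block so alpha is dimensionless
    norm = np.linalg.norm(A) / max(np.linalg.norm(D), 1e-300)
    aug = np.vstack([A, np.sqrt(alpha) * norm * D])
    rhs = np.concatenate([y, np.zeros(n_int)])
    if alpha == 0:
        cond = np.linalg.cond(A)
        if cond > 1e10:
            raise ValueError(
                f"ill-conditioned system (cond={cond:.2e}) at alpha=0; "
                "use alpha > 0"
            )
    p_int, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    p = np.zeros(n_grid)
    p[1:-1] = p_int

    i_hat = K @ p_int
    resid = (curve.i - i_hat) / curve.sigma
    dof = max(len(curve) - k_free, 1)
    chi2 = float(np.sum(resid**2) / dof)
    mass = np.trapezoid(np.abs(p), r)
    neg = np.trapezoid(np.clip(-p, 0.0, None), r)
    i0, rg = pr_moments(r, np.clip(p, 0.0, None))
    return PrDistribution(
        r=r,
        p=p,
        dmax=dmax,
        rg=rg,
        i0=i0,
        alpha=alpha,
        chi2=chi2,
        negative_mass_fraction=float(neg / mass) if mass > 0 else 0.0,
    )


def scan_dmax(
    curve: SAXSCurve,
    dmax_grid: list[float] | np.ndarray,
    alpha: float = config.IFT_ALPHA,
    n_grid: int = config.IFT_N_GRID,
    chi2_slack: float = config.IFT_CHI2_SLACK,
    positivity_mass: float = config.IFT_POSITIVITY_MASS,
) -> PrDistribution:
    """Pick the smallest plausible D_max from a candidate grid.

    Each candidate is solved by ift_pr; the selected D_max is the smallest
    whose chi2 is within `chi2_slack` of the grid minimum -- or already
    below 1, i.e. fitting within the stated uncertainties, where further
    chi2 differences carry no information -- and whose p(r) is non-negative
    over at least `positivity_mass` of its absolute mass.  If no candidate
    passes positivity the minimum-chi2 one is returned with a warning.
    """
    candidates = sorted(float(d) for d in np.atleast_1d(dmax_grid))
    if not candidates:
        raise ValueError("empty dmax grid")
    solutions = [ift_pr(curve, d, alpha=alpha, n_grid=n_grid) for d in candidates]
    chi2_min = min(sol.chi2 for sol in solutions)
    chi2_ok = max(chi2_min * (1.0 + chi2_slack), 1.0)
    for sol in solutions:
        ok_chi2 = sol.chi2 <= chi2_ok
        ok_pos = (1.0 - sol.negative_mass_fraction) >= positivity_mass
        if ok_chi2 and ok_pos:
            return sol
    warnings.warn(
        "no D_max candidate satisfied the positivity criterion; "
        "returning the minimum-chi2 solution",
        stacklevel=2,
    )
    return min(solutions, key=lambda sol: sol.chi2)


# -------------------------------------------------------------- shape call

def rg_rs_shape_ratio(rg: float, rs: float) -> ShapeClassification:
    """Classify molecular shape from R_g/R_S.

    <= 0.80 sphere-like; (0.80, 0.875) and (0.987, 1.36) intermediate;
    [0.875, 0.987] oblate; [1.36, 2.24] prolate; > 2.24 extended.
    """
    if rg <= 0 or rs <= 0:
        raise ValueError("radii must be positive")
    ratio = rg / rs
    iv = config.SHAPE_RATIO_INTERVALS
    if ratio <= iv["sphere-like"][1]:
        label = "sphere-like"
    elif iv["oblate"][0] <= ratio <= iv["oblate"][1]:
        label = "oblate"
    elif iv["prolate"][0] <= ratio <= iv["prolate"][1]:
        label = "prolate"
    elif ratio > iv["prolate"][1]:
        label = "extended"
    else:
        label = "intermediate"
    return ShapeClassification(ratio=float(ratio), label=label)
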