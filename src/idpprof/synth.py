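"""Synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised without any external
measurement: these generators produce SAXS curves of known analytic shape
(solid sphere, Gaussian chain, prolate ellipsoid, conformer-ensemble
mixtures), SEC calibration tables from a known line, sequences with
prescribed composition statistics, and linear or sigmoidal CD melts.  Each
generator is bit-reproducible under a fixed seed and returns a truth record
holding the analytic quantities the analysis stage is supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import config
from .cd import MeltSeries
from .ensemble import ConformerPool, generate_pool
from .saxs import SAXSCurve
from .sec import DEFAULT_STANDARDS, SECColumn, SECStandard, kav
from .sequence import CANONICAL, ProteinSequence, rescaled_kd


@dataclass(frozen=True)
class SynthesisRecipe:
    """What to synthesize: model, parameters, noise, grid, seed."""

    model: str  # sphere | debye_chain | prolate_ellipsoid | ensemble_mixture
    parameters: dict[str, Any] = field(default_factory=dict)
    noise_fraction: float = 0.0
    seed: int = 0
    s_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        grid = self.s_grid
        if grid is None:
            # the s-range of a typical laboratory IDP measurement
            grid = np.linspace(0.010, 0.213, 200)
        object.__setattr__(self, "s_grid", np.asarray(grid, dtype=float))


def sphere_intensity(s: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Solid-sphere form factor, I(0) = i0."""
    x = s * radius
    amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return i0 * amp**2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a uniform sphere (unit mass)."""
    u = np.clip(r / radius, 0.0, 2.0)
    p = 3.0 * u**2 * (1.0 - 0.75 * u + u**3 / 16.0) / radius
    return np.where(r <= 2.0 * radius, p, 0.0)


def debye_chain_intensity(s: np.ndarray, rg: float, i0: float = 1.0) -> np.ndarray:
    """Debye function of an ideal Gaussian chain with radius of gyration rg."""
    x = (s * rg) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        y = 2.0 * (np.exp(-x) + x - 1.0) / x**2
    return i0 * np.where(x < 1e-8, 1.0 - x / 3.0, y)


def prolate_ellipsoid_intensity(
    s: np.ndarray, a: float, b: float, i0: float = 1.0, n_quad: int = 128
) -> np.ndarray:
    """Orientationally averaged form factor of a prolate ellipsoid.

    Semi-axes (a, b, b) with a > b; averaged by Gauss-Legendre quadrature
    over the angle between s and the long axis.
    """
    x_nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    mu = 0.5 * (x_nodes + 1.0)       # cos(angle) in [0, 1]
    w = 0.5 * weights
    r_eff = np.sqrt(a**2 * mu**2 + b**2 * (1.0 - mu**2))
    x = np.outer(s, r_eff)
    amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return i0 * (amp**2 @ w)


def ellipsoid_rg(a: float, b: float) -> float:
    """R_g of a uniform ellipsoid with semi-axes (a, b, b)."""
    return float(np.sqrt((a**2 + 2.0 * b**2) / 5.0))


def synth_saxs(recipe: SynthesisRecipe) -> tuple[SAXSCurve, dict]:
    """Synthesize a SAXS curve plus a truth record (analytic Rg, Dmax, I0).

    Noise is relative Gaussian (sigma = noise_fraction * I) by default;
    parameters={"poisson_counts": N} switches to Poisson counting noise
    with N expected counts at I(0).  The sigma column always carries the
    true per-point uncertainty; for noiseless curves a nominal 1% sigma is
    written so downstream weighted fits stay defined.
    """
    s = recipe.s_grid
    p = recipe.parameters
    i0 = float(p.get("i0", 1.0))
    if recipe.model == "sphere":
        radius = float(p["radius"])
        intensity = sphere_intensity(s, radius, i0)
        truth = {"rg": np.sqrt(3.0 / 5.0) * radius, "dmax": 2.0 * radius, "i0": i0}
    elif recipe.model == "debye_chain":
        rg = float(p["rg"])
        intensity = debye_chain_intensity(s, rg, i0)
        truth = {"rg": rg, "dmax": None, "i0": i0}
    elif recipe.model == "prolate_ellipsoid":
        a, b = float(p["a"]), float(p["b"])
        intensity = prolate_ellipsoid_intensity(s, a, b, i0)
        truth = {"rg": ellipsoid_rg(a, b), "dmax": 2.0 * max(a, b), "i0": i0}
    elif recipe.model == "ensemble_mixture":
        profiles = np.asarray(p["profiles"], dtype=float)
        intensity = profiles.mean(axis=0)
        intensity = i0 * intensity / intensity[0]
        truth = {"rg": p.get("rg"), "dmax": None, "i0": i0}
    else:
        raise ValueError(f"unknown model {recipe.model!r}")

    rng = np.random.default_rng(recipe.seed)
    if "poisson_counts" in p:
        scale = float(p["poisson_counts"]) / i0
        counts = rng.poisson(np.clip(intensity * scale, 0.0, None))
        noisy = counts / scale
        sigma = np.sqrt(np.clip(intensity * scale, 1.0, None)) / scale
    elif recipe.noise_fraction > 0:
        sigma = recipe.noise_fraction * np.abs(intensity)
        noisy = intensity + rng.normal(0.0, sigma)
    else:
        sigma = 0.01 * np.abs(intensity)  # nominal weights for exact curves
        noisy = intensity
    truth["model"] = recipe.model
    return SAXSCurve(s=s, i=noisy, sigma=sigma), truth


def synth_sec_standards(
    true_line: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    column: SECColumn | None = None,
    standards: tuple[SECStandard, ...] = DEFAULT_STANDARDS,
) -> tuple[list[SECStandard], dict]:
    """Emulate a column calibration from a known K_AV vs log10(R_S) line.

    `true_line` is (slope, intercept); K_AV values are generated from the
    line at each standard's R_S plus seeded Gaussian noise, then converted
    back to elution volumes for the given column.
    """
    slope, intercept = true_line
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    column = column or SECColumn(v0=8.54, vt=24.0)
    rng = np.random.default_rng(seed)
    out = []
    for std in standards:
        k_true = intercept + slope * np.log10(std.rs)
        k_obs = k_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        ve = column.v0 + k_obs * (column.vt - column.v0)
        out.append(SECStandard(std.name, std.mm, std.rs, float(ve)))
    truth = {"slope": slope, "intercept": intercept, "column": column}
    return out, truth


_NEUTRAL_PALETTE = sorted(
    (r for r in CANONICAL if r not in set("KRDE")),
    key=rescaled_kd,
)


def synth_sequence(
    length: int,
    target_charge: float,
    target_hydropathy: float,
    seed: int = 0,
) -> ProteinSequence:
    """Sequence with prescribed mean net charge and mean hydropathy.

    Composition search: the net-charge excess is set exactly by K/R vs D/E
    counts (realized charge within 1/length of the target by rounding);
    the remaining positions are filled from two neutral residues bracketing
    the required per-residue hydropathy, achieving the window-1 mean within
    0.02.  The arrangement is a seeded shuffle, so composition statistics
    are exact while the ordering is random.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= target_charge <= 1.0):
        raise ValueError(f"unreachable target charge {target_charge}")
    if not (0.0 <= target_hydropathy <= 1.0):
        raise ValueError(f"target hydropathy {target_hydropathy} outside [0, 1]")
    n_excess = round(target_charge * length)
    if n_excess > length:
        raise ValueError("charge target exceeds sequence capacity")

    residues: list[str] = ["K"] * n_excess  # uncompensated positive excess
    remaining = length - n_excess
    # the charged residues contribute their own hydropathy
    h_needed = target_hydropathy * length - sum(rescaled_kd(r) for r in residues)
    if remaining > 0:
        m = h_needed / remaining
        palette_vals = [rescaled_kd(r) for r in _NEUTRAL_PALETTE]
        m = min(max(m, palette_vals[0]), palette_vals[-1])
        # two bracketing neutral residues, counts by linear interpolation
        hi_idx = next(
            i for i, v in enumerate(palette_vals) if v >= m - 1e-12
        )
        lo_idx = max(hi_idx - 1, 0)
        lo_res, hi_res = _NEUTRAL_PALETTE[lo_idx], _NEUTRAL_PALETTE[hi_idx]
        lo_v, hi_v = palette_vals[lo_idx], palette_vals[hi_idx]
        if hi_v == lo_v:
            n_hi = 0
        else:
            n_hi = round(remaining * (m - lo_v) / (hi_v - lo_v))
        residues += [hi_res] * n_hi + [lo_res] * (remaining - n_hi)

    rng = np.random.default_rng(seed)
    order = rng.permutation(length)
    shuffled = "".join(residues[j] for j in order)
    return ProteinSequence(id=f"synthetic_L{length}", residues=shuffled)


#: Named compactness presets for mixture components.  A preset scales both
#: the bond-angle prior (stiff, near-straight angles extend the chain) and
#: the sequence-distant excluded-volume diameter (a collapsed sub-state
#: tolerates closer contacts, emulating net intra-chain attraction).
COMPACTNESS_PRESETS: dict[str, dict] = {
    "compact": {"cos_range": (-0.9, 0.5), "excluded": 3.8},
    "coil": {"cos_range": config.CHAIN_COS_RANGE,
             "excluded": config.CHAIN_EXCLUDED_DIAMETER},
    "extended": {"cos_range": (0.83, 0.975),
                 "excluded": config.CHAIN_EXCLUDED_DIAMETER},
}


def synth_ensemble_mixture(
    n_res: int,
    fractions: tuple[float, ...],
    compactness_levels: tuple,
    n_conf: int,
    seed: int = 0,
) -> tuple[ConformerPool, dict]:
    """Conformer pool drawn from sub-pools with distinct chain priors.

    Each component k contributes round(fractions[k] * n_conf) chains built
    with the prior named (or given as a dict with cos_range / excluded) in
    compactness_levels[k]; see COMPACTNESS_PRESETS.  The truth record
    carries each component's R_g sample and mean.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != len(compactness_levels):
        raise ValueError("one compactness level per fraction is required")
    counts = [round(f * n_conf) for f in fractions]
    counts[-1] = n_conf - sum(counts[:-1])
    conformers = []
    component_rgs = []
    labels = []
    for k, (count, level) in enumerate(zip(counts, compactness_levels)):
        preset = COMPACTNESS_PRESETS[level] if isinstance(level, str) else dict(level)
        sub = generate_pool(
            n_res,
            count,
            seed=seed + 7919 * k,
            cos_range=tuple(preset["cos_range"]),
            excluded=float(preset.get("excluded", config.CHAIN_EXCLUDED_DIAMETER)),
        )
        conformers.extend(sub.conformers)
        component_rgs.append(sub.rgs)
        labels.extend([k] * count)
    pool = ConformerPool(conformers)
    truth = {
        "fractions": list(fractions),
        "counts": counts,
        "component_labels": np.array(labels),
        "component_mean_rg": [float(r.mean()) for r in component_rgs],
        "component_rgs": component_rgs,
    }
    return pool, truth


def synth_melt(
    kind: str,
    params: dict | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[MeltSeries, dict]:
    """Linear or two-state-sigmoid CD melt at 222 nm with seeded noise.

    linear:  mre = a + b*T               (params a, b)
    sigmoid: two-state with baseline, amplitude, midpoint, width

    `noise` is the Gaussian sigma as a fraction of the series' range.
    """
    params = dict(params or {})
    t = np.asarray(
        params.pop("temperatures", np.arange(20.0, 81.0, 5.0)), dtype=float
    )
    if len(t) < 6:
        raise ValueError("need >= 6 temperatures")
    if kind == "linear":
        a = float(params.get("a", -4000.0))
        b = float(params.get("b", 25.0))
        mre = a + b * t
        truth = {"kind": "linear", "a": a, "b": b}
    elif kind == "sigmoid":
        base = float(params.get("base", -8000.0))
        amplitude = float(params.get("amplitude", 6000.0))
        midpoint = float(params.get("midpoint", 50.0))
        width = float(params.get("width", 4.0))
        mre = base + amplitude / (1.0 + np.exp(-(t - midpoint) / width))
        truth = {
            "kind": "sigmoid",
            "base": base,
            "amplitude": amplitude,
            "midpoint": midpoint,
            "width": width,
        }
    else:
        raise ValueError(f"unknown melt kind {kind!r}")
    if noise > 0:
        rng = np.random.default_rng(seed)
        span = float(np.ptp(mre)) or 1.0
        mre = mre + rng.normal(0.0, noise * span, size=len(t))
    return MeltSeries(temperature=t, mre222=mre), truth
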