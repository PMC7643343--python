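"""Circular-dichroism utilities for disordered-protein work.

Two small tools: conversion of machine ellipticity to molar residual
ellipticity (MRE), and a cooperativity test for thermal melts followed at
222 nm.  A folded protein melts through a cooperative two-state transition
(sigmoidal MRE-vs-T); a coil-like IDP drifts linearly with temperature with
no transition between extreme conformational states.  The call is made by
information-criterion comparison of a linear against a two-state sigmoid
fit rather than by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Model

from . import config


@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV CD spectrum with the parameters needed for normalization."""

    wavelength: np.ndarray   # nm
    theta: np.ndarray        # machine ellipticity, mdeg
    concentration: float     # mol/l
    n_residues: int
    path_length: float       # cm

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        if len(wl) != len(th):
            raise ValueError("wavelength and theta lengths differ")
        if len(wl) > 1 and not (
            np.all(np.diff(wl) > 0) or np.all(np.diff(wl) < 0)
        ):
            raise ValueError("wavelengths must be strictly monotone")
        if self.concentration <= 0 or self.path_length <= 0:
            raise ValueError("concentration and path length must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "theta", th)


@dataclass(frozen=True)
class MeltSeries:
    """MRE at 222 nm as a function of temperature."""

    temperature: np.ndarray  # degC, strictly increasing
    mre222: np.ndarray       # deg cm^2 / dmol

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        m = np.asarray(self.mre222, dtype=float)
        if len(t) != len(m) or len(t) < 4:
            raise ValueError("need equal-length series of >= 4 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "mre222", m)

    def __len__(self) -> int:
        return len(self.temperature)


def to_mre(spec: CDSpectrum) -> np.ndarray:
    """Molar residual ellipticity, deg cm^2/dmol, per wavelength.

    [theta] = theta_mdeg / (10 * l[cm] * c[mol/l] * n_residues): the
    per-residue molar normalization.
    """
    return spec.theta / (
        10.0 * spec.path_length * spec.concentration * spec.n_residues
    )


def _sigmoid(t, base, amplitude, midpoint, width):
    return base + amplitude / (1.0 + np.exp(-(t - midpoint) / width))


def _aic(n: int, rss: float, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def melt_cooperativity(
    series: MeltSeries, aic_margin: float = config.MELT_AIC_MARGIN
) -> dict:
    """Test a 222 nm melt for a cooperative two-state transition.

    Fits a line and a two-state sigmoid to MRE(T) and compares them by
    AIC.  The melt is called "cooperative" only when the sigmoid improves
    AIC beyond the margin (delta_aic = AIC_sigmoid - AIC_line <= margin);
    otherwise "non-cooperative" -- the IDP-typical linear drift.
    """
    if len(series) < 6:
        raise ValueError("need >= 6 points to compare melt models")
    t = series.temperature
    y = series.mre222

    slope, intercept = np.polyfit(t, y, 1)
    rss_line = float(np.sum((y - (slope * t + intercept)) ** 2))
    aic_line = _aic(len(t), rss_line, 2)
    span = float(np.ptp(y))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_line = 1.0 - rss_line / ss_tot if ss_tot > 0 else 1.0

    # a (numerically) perfect line needs no model comparison
    scale = max(1.0, float(np.max(np.abs(y))))
    if rss_line <= len(t) * (1e-8 * scale) ** 2:
        return {
            "label": "non-cooperative",
            "slope": float(slope),
            "linear_r2": float(r2_line),
            "delta_aic": float("inf"),
        }

    try:
        model = Model(_sigmoid)
        params = model.make_params(
            base=float(y[0]),
            amplitude=float(y[-1] - y[0]),
            midpoint=float(np.median(t)),
            width=max(float(np.ptp(t)) / 10.0, 1.0),
        )
        params["width"].set(min=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(y, params, t=t)
        rss_sig = float(np.sum(fit.residual**2))
        aic_sig = _aic(len(t), rss_sig, 4)
    except Exception:
        warnings.warn(
            "sigmoid melt fit failed; labelling from linear fit alone",
            stacklevel=2,
        )
        label = "non-cooperative" if r2_line > 0.9 or span == 0 else "cooperative"
        return {
            "label": label,
            "slope": float(slope),
            "linear_r2": float(r2_line),
            "delta_aic": float("nan"),
        }

    delta_aic = aic_sig - aic_line
    label = "cooperative" if delta_aic <= aic_margin else "non-cooperative"
    return {
        "label": label,
        "slope": float(slope),
        "linear_r2": float(r2_line),
        "delta_aic": float(delta_aic),
    }


def read_melt_csv(
    path: str | Path,
    concentration: float | None = None,
    n_residues: int | None = None,
    path_length: float | None = None,
) -> MeltSeries:
    """Read a melt series (columns: temperature_c, mre222 or theta_mdeg).

    When only machine ellipticity is present the normalization parameters
    must be supplied to convert it.
    """
    df = pd.read_csv(path)
    if "temperature_c" not in df.columns:
        raise ValueError("melt CSV needs a temperature_c column")
    t = df["temperature_c"].to_numpy(dtype=float)
    if "mre222" in df.columns:
        m = df["mre222"].to_numpy(dtype=float)
    elif "theta_mdeg" in df.columns:
        if None in (concentration, n_residues, path_length):
            raise ValueError(
                "theta_mdeg input needs concentration, n_residues and "
                "path_length for MRE conversion"
            )
        m = df["theta_mdeg"].to_numpy(dtype=float) / (
            10.0 * path_length * concentration * n_residues
        )
    else:
        raise ValueError("melt CSV needs an mre222 or theta_mdeg column")
    return MeltSeries(temperature=t, mre222=m)


def nnls_deconvolution(
    spectrum: np.ndarray, basis: np.ndarray
) -> np.ndarray:
    """Non-negative least-squares secondary-structure hook.

    Decomposes a spectrum onto a user-supplied reference basis (one column
    per structure class) with non-negative weights normalized to 1.  No
    reference basis ships with the package.
    """
    from scipy.optimize import nnls

    weights, _ = nnls(np.asarray(basis, float), np.asarray(spectrum, float))
    total = weights.sum()
    return weights / total if total > 0 else weights
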