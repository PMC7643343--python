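"""Package-wide default constants.

Every empirically sourced coefficient used by the analysis modules lives here,
so that a single YAML file can override any of them.  Values fall into three
groups:

* the native-state Stokes-radius scaling law and the charge-hydropathy
  boundary, which are standard literature relations;
* non-native compaction-state scaling laws (molten globule, pre-molten
  globule, chemically unfolded coil, and the two natively-unfolded IDP
  states), transcribed from the Uversky/Tcherkasskaya hydrodynamic
  compilations -- externally sourced and overridable;
* numerical defaults of this package's own algorithms (Guinier cutoff,
  IFT regularization, chain-generator geometry, GA hyperparameters).
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

#: log10(R_S [Å]) = a + b * log10(MM [Da]) per compaction state.
#: "native" reproduces the six SEC calibration standards exactly; the other
#: entries are transcribed from published hydrodynamic compilations and are
#: meant to be overridden when better column- or study-specific values exist.
SCALING_LAWS: dict[str, tuple[float, float]] = {
    "native": (-0.204, 0.357),
    "molten_globule": (-0.053, 0.334),
    "pre_molten_globule": (-0.210, 0.392),
    "gdmcl_coil": (-0.723, 0.543),
    "nu_coil": (-0.551, 0.493),
    "nu_pmg": (-0.239, 0.403),
}

#: Compaction *family* each scaling state belongs to.  The IDP literature
#: groups pre-molten-globule-like states (globular PMG and natively unfolded
#: PMG) and coil-like states (GdmCl coil and natively unfolded coil) when
#: calling a protein "PMG-like" or "coil-like".
STATE_FAMILIES: dict[str, str] = {
    "native": "native",
    "molten_globule": "MG",
    "pre_molten_globule": "PMG-like",
    "nu_pmg": "PMG-like",
    "gdmcl_coil": "coil-like",
    "nu_coil": "coil-like",
}

#: Charge-hydropathy boundary <R> = CH_SLOPE * <H> + CH_INTERCEPT separating
#: natively unfolded from ordered proteins on the Uversky plane.
CH_SLOPE: float = 2.785
CH_INTERCEPT: float = -1.151

#: Frictional-ratio interpretation bands (anhydrous-sphere reference).
FF0_GLOBULAR: tuple[float, float] = (1.05, 1.30)
FF0_IDP: tuple[float, float] = (1.75, 3.0)

#: R_g/R_S shape-ratio intervals.  0.778 is the hard-sphere value; the
#: oblate and prolate bands follow the ellipsoid tabulation cited in the
#: hydrodynamics literature.
SHAPE_RATIO_INTERVALS: dict[str, tuple[float, float]] = {
    "sphere-like": (0.0, 0.80),
    "oblate": (0.875, 0.987),
    "prolate": (1.36, 2.24),
}

#: Reference (standard) sedimentation conditions: water at 20 degC.
REFERENCE_BUFFER: dict[str, float] = {
    "temperature": 20.0,   # degC
    "density": 0.99823,    # g/ml
    "viscosity": 0.010016, # poise
    "vbar": 0.730,         # ml/g, generic protein partial specific volume
}

#: Guinier analysis defaults.
GUINIER_SRG_CUTOFF: float = 1.3
GUINIER_MIN_POINTS: int = 5

#: Indirect Fourier transform defaults.
IFT_N_GRID: int = 101
IFT_ALPHA: float = 1.0e-5
IFT_CHI2_SLACK: float = 0.05      # D_max scan: accept chi2 within 5% of min
IFT_POSITIVITY_MASS: float = 0.99 # fraction of |p| mass that must be >= 0

#: Kratky fold-state call: "globular" requires an interior maximum whose
#: transform later falls below this fraction of the peak.
KRATKY_DECAY_FRACTION: float = 0.5

#: Coarse-grained chain generator (coil prior, not a rotamer library).
#: Excluded volume is two-tier: 1-3 neighbours may approach to the chain
#: cutoff, while sequence-distant residues carry the full effective
#: residue diameter (side chains included) -- the size needed for the
#: chain to show good-solvent self-avoiding statistics at protein lengths.
CHAIN_BOND_LENGTH: float = 3.8    # Å, virtual C-alpha bond
CHAIN_COS_RANGE: tuple[float, float] = (-0.5, 0.9)  # uniform cos(bond angle)
CHAIN_CLASH_CUTOFF: float = 3.3   # Å, 1-3 neighbours (|i-j| == 2)
CHAIN_EXCLUDED_DIAMETER: float = 8.0  # Å, |i-j| >= 3
CHAIN_PIVOT_MOVES: int = 40       # equilibration proposals per chain
CHAIN_MAX_STEP_RETRIES: int = 50
CHAIN_MAX_RESTARTS: int = 200

#: Debye profile distance-binning width (Å); None disables binning.
DEBYE_BIN_WIDTH: float = 0.5

#: Genetic-algorithm defaults for sub-ensemble selection.
GA_ENSEMBLE_SIZE: int = 20
GA_POPULATION: int = 50
GA_GENERATIONS: int = 100
GA_CROSSOVER_PROB: float = 0.5
GA_MUTATION_PROB: float = 0.1
GA_ELITE: int = 1

#: CD melt cooperativity: the line wins unless the sigmoid improves AIC by
#: more than this margin (AIC_sigmoid - AIC_line <= margin -> cooperative).
MELT_AIC_MARGIN: float = -2.0

AVOGADRO: float = 6.02214076e23   # 1/mol
SVEDBERG: float = 1.0e-13         # s


def defaults() -> dict[str, Any]:
    """Return a deep copy of all defaults as a nested dict (YAML-shaped)."""
    return copy.deepcopy(
        {
            "scaling_laws": {k: list(v) for k, v in SCALING_LAWS.items()},
            "state_families": dict(STATE_FAMILIES),
            "ch_boundary": {"slope": CH_SLOPE, "intercept": CH_INTERCEPT},
            "reference_buffer": dict(REFERENCE_BUFFER),
            "guinier": {
                "srg_cutoff": GUINIER_SRG_CUTOFF,
                "min_points": GUINIER_MIN_POINTS,
            },
            "ift": {
                "n_grid": IFT_N_GRID,
                "alpha": IFT_ALPHA,
                "chi2_slack": IFT_CHI2_SLACK,
                "positivity_mass": IFT_POSITIVITY_MASS,
            },
            "chain": {
                "bond_length": CHAIN_BOND_LENGTH,
                "cos_range": list(CHAIN_COS_RANGE),
                "clash_cutoff": CHAIN_CLASH_CUTOFF,
                "excluded_diameter": CHAIN_EXCLUDED_DIAMETER,
                "pivot_moves": CHAIN_PIVOT_MOVES,
            },
            "ga": {
                "ensemble_size": GA_ENSEMBLE_SIZE,
                "population": GA_POPULATION,
                "generations": GA_GENERATIONS,
                "crossover_prob": GA_CROSSOVER_PROB,
                "mutation_prob": GA_MUTATION_PROB,
                "elite": GA_ELITE,
            },
            "melt": {"aic_margin": MELT_AIC_MARGIN},
        }
    )


def load_config(path: str | None = None) -> dict[str, Any]:
    """Merge a YAML override file (may be partial) onto the defaults."""
    cfg = defaults()
    if path is None:
        return cfg
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}

    def merge(base: dict, over: dict) -> dict:
        for key, val in over.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                merge(base[key], val)
            else:
                base[key] = val
        return base

    return merge(cfg, override)
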