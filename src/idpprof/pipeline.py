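"""Orchestration: run every available evidence line and assemble a report.

The characterization of a disordered protein is a conjunction of
independent observations -- sequence composition, SEC hydrodynamics,
sedimentation, SAXS shape analysis, ensemble modelling, CD melts.  The
pipeline runs whichever stages the configuration provides inputs for,
never letting one stage's failure block another, and emits a single JSON
report whose verdict lists the per-stage labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import cd as cd_mod
from . import ensemble as eom
from . import saxs as saxs_mod
from . import sec as sec_mod
from . import sedimentation as sv_mod
from . import sequence as seq_mod

log = logging.getLogger(__name__)

STAGES = ("sequence", "sec", "sv", "saxs", "eom", "cd")


@dataclass
class CharacterizationReport:
    """Aggregated stage outputs; only stages actually run are present."""

    stages: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    verdict: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "errors": self.errors, "verdict": self.verdict}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)

    def summary_text(self) -> str:
        lines = ["Characterization summary", "========================"]
        for stage in STAGES:
            if stage in self.stages:
                lines.append(f"[{stage}] {_stage_line(stage, self.stages[stage])}")
            elif stage in self.errors:
                lines.append(f"[{stage}] FAILED: {self.errors[stage]}")
        lines.append("verdict: " + ("; ".join(self.verdict) or "no stages run"))
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_line(stage: str, payload: dict) -> str:
    if stage == "sequence":
        return (
            f"<H>={payload['mean_hydropathy']:.4f} "
            f"<R>={payload['mean_net_charge']:.4f} -> {payload['label']}"
        )
    if stage == "sec":
        return (
            f"Rs={payload['rs_angstrom']:.1f} Å -> {payload['state_label']}"
        )
    if stage == "sv":
        rows = payload["runs"]
        ff0 = ", ".join(f"{r['f_over_f0']:.2f}" for r in rows)
        return f"f/f0 = {ff0} -> {rows[0]['shape_call']}"
    if stage == "saxs":
        return (
            f"Guinier Rg={payload['guinier']['rg_angstrom']:.1f} Å; "
            f"Kratky -> {payload['kratky_label']}; "
            f"p(r): Dmax={payload['pr']['dmax_angstrom']:.0f} Å, "
            f"Rg={payload['pr']['rg_angstrom']:.1f} Å"
            + (
                f"; Rg/Rs={payload['shape']['ratio']:.2f} "
                f"({payload['shape']['label']})"
                if "shape" in payload
                else ""
            )
        )
    if stage == "eom":
        return (
            f"chi2={payload['chi2']:.3f}; pool mean Rg="
            f"{payload['pool']['mean']:.1f} Å, selected mean Rg="
            f"{payload['selected']['mean']:.1f} Å (shift {payload['shift']:+.1f})"
        )
    if stage == "cd":
        return f"melt -> {payload['label']} (delta AIC {payload['delta_aic']:.1f})"
    return str(payload)


def _run_sequence(cfg: dict) -> dict:
    window = int(cfg.get("window", 5))
    if "fasta" in cfg:
        seq = seq_mod.read_fasta(cfg["fasta"])[0]
    else:
        seq = seq_mod.clean_sequence(cfg.get("id", "input"), cfg["residues"])
    res = seq_mod.profile_sequence(seq, window=window)
    out = res.to_dict()
    out["id"] = seq.id
    out["length"] = len(seq)
    return out


def _run_sec(cfg: dict) -> dict:
    column = sec_mod.SECColumn(v0=float(cfg["v0"]), vt=float(cfg["vt"]))
    mm = float(cfg["mm"])
    if "rs" in cfg:
        rs = float(cfg["rs"])
    else:
        standards = sec_mod.read_standards_csv(cfg["standards"])
        curve = sec_mod.fit_calibration(standards, column)
        rs = sec_mod.rs_from_elution(float(cfg["ve"]), column, curve)
    profile = sec_mod.classify_compaction_state(mm, rs)
    out = profile.to_dict()
    out["rs_theoretical_native"] = sec_mod.rs_scaling_predict(mm, "native")
    return out


def _run_sv(cfg: dict) -> dict:
    buf = sv_mod.BufferConditions(
        temperature=float(cfg.get("temperature", 20.0)),
        density=float(cfg.get("density", sv_mod.WATER_20C.density)),
        viscosity=float(cfg.get("viscosity", sv_mod.WATER_20C.viscosity)),
        vbar=float(cfg.get("vbar", sv_mod.WATER_20C.vbar)),
    )
    runs = []
    for row in cfg["runs"]:
        res = sv_mod.analyze_sv(
            s_obs=float(row["s_obs"]), f_over_f0=float(row["f_over_f0"]), buf=buf
        )
        runs.append(res.to_dict())
    return {"runs": runs}


def _run_saxs(cfg: dict, report: CharacterizationReport) -> dict:
    curve = saxs_mod.read_dat(cfg["data"])
    gf = saxs_mod.guinier_fit(
        curve,
        srg_cutoff=float(cfg.get("srg_cutoff", 1.3)),
        first_point=int(cfg.get("first_point", 0)),
    )
    _, _, kratky_label = saxs_mod.kratky_transform(curve, gf.i0)
    dmax_grid = cfg.get("dmax_grid")
    alpha = float(cfg.get("alpha", saxs_mod.config.IFT_ALPHA))
    if dmax_grid:
        pr = saxs_mod.scan_dmax(curve, [float(d) for d in dmax_grid], alpha=alpha)
    else:
        pr = saxs_mod.ift_pr(curve, float(cfg["dmax"]), alpha=alpha, rg_hint=gf.rg)
    out = {
        "guinier": {
            "rg_angstrom": gf.rg,
            "i0": gf.i0,
            "srg_max": gf.srg_max,
            "n_points": gf.n_points,
        },
        "kratky_label": kratky_label,
        "pr": {
            "dmax_angstrom": pr.dmax,
            "rg_angstrom": pr.rg,
            "chi2": pr.chi2,
            "alpha": pr.alpha,
        },
    }
    rs = cfg.get("rs")
    if rs is None and "sec" in report.stages:
        rs = report.stages["sec"]["rs_angstrom"]
    if rs is not None:
        shape = saxs_mod.rg_rs_shape_ratio(pr.rg, float(rs))
        out["shape"] = {"ratio": shape.ratio, "label": shape.label}
    return out


def _run_eom(cfg: dict) -> dict:
    curve = saxs_mod.read_dat(cfg["data"])
    n_res = int(cfg["n_res"])
    pool = eom.generate_pool(
        n_res, int(cfg.get("pool", 1000)), seed=int(cfg.get("seed", 1))
    ).with_profiles(curve.s)
    sel = eom.select_subensemble_ga(
        pool,
        curve,
        ensemble_size=int(cfg.get("ensemble", eom.config.GA_ENSEMBLE_SIZE)),
        generations=int(cfg.get("generations", eom.config.GA_GENERATIONS)),
        seed=int(cfg.get("seed", 1)),
    )
    return eom.rg_distribution_summary(pool, sel)


def _run_cd(cfg: dict) -> dict:
    series = cd_mod.read_melt_csv(
        cfg["melt"],
        concentration=cfg.get("concentration"),
        n_residues=cfg.get("n_residues"),
        path_length=cfg.get("path_length"),
    )
    return cd_mod.melt_cooperativity(series)


_RUNNERS = {
    "sequence": lambda cfg, report: _run_sequence(cfg),
    "sec": lambda cfg, report: _run_sec(cfg),
    "sv": lambda cfg, report: _run_sv(cfg),
    "saxs": _run_saxs,
    "eom": lambda cfg, report: _run_eom(cfg),
    "cd": lambda cfg, report: _run_cd(cfg),
}

_VERDICT = {
    "sequence": lambda p: f"sequence: {p['label']}",
    "sec": lambda p: f"SEC: {p['state_label']}",
    "sv": lambda p: f"AUC: {p['runs'][0]['shape_call']}",
    "saxs": lambda p: f"Kratky: {p['kratky_label']}"
    + (f"; shape: {p['shape']['label']}" if "shape" in p else ""),
    "eom": lambda p: f"EOM: Rg shift {p['shift']:+.1f} Å"
    + (", bimodal" if p.get("bimodal") else ""),
    "cd": lambda p: f"CD melt: {p['label']}",
}


def run_profile(config_path: str | Path | dict) -> CharacterizationReport:
    """Run all configured stages and return the aggregated report.

    `config_path` may be a YAML file or an already-parsed mapping whose
    keys are stage names (sequence, sec, sv, saxs, eom, cd), each holding
    that stage's inputs.  Missing stages are skipped with a log notice;
    failing stages are recorded and do not block the others.
    """
    if isinstance(config_path, (str, Path)):
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config_path)
    if not cfg or not any(stage in cfg for stage in STAGES):
        raise ValueError(
            f"configuration names no known stage; expected one of {STAGES}"
        )
    unknown = set(cfg) - set(STAGES) - {"output"}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    report = CharacterizationReport()
    for stage in STAGES:
        if stage not in cfg:
            log.info("stage %s not configured; skipped", stage)
            continue
        try:
            payload = _RUNNERS[stage](cfg[stage], report)
        except Exception as exc:  # stage independence: record and continue
            log.error("stage %s failed: %s", stage, exc)
            report.errors[stage] = str(exc)
            continue
        report.stages[stage] = payload
        report.verdict.append(_VERDICT[stage](payload))
    out = cfg.get("output")
    if out:
        report.to_json(out)
    return report
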