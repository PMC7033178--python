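"""End-to-end report pipeline tying the analysis stages together.

Two canonical workflows, selectable per run: the trajectory mobility
comparison (simulate two cohorts, compute linear efficiencies, decompose the
log-efficiency histograms, compare mobile fractions) and the structure / QC /
escape report (SAXS d-spacing and Guinier radius, encapsulation efficiency,
per-cell endosomal-escape ratio).  A run is fully described by a RunConfig
and one seed; the emitted JSON report embeds both (seed and a config hash) so
any number in it can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import formqc, imaging_quant, saxs, synthdata, trajmetrics
from ._utils import ValidationError, require
from .io import write_json_report

__all__ = ["RunConfig", "StageError", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

KNOWN_STAGES = ("trajectories", "saxs", "qc", "escape")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline run description.

    Stage parameter blocks mirror the generator configs of
    :mod:`nanotraffic.synthdata`; unknown keys anywhere are rejected.
    """

    stages: tuple = KNOWN_STAGES
    seed: int = 0
    trajectories: dict = field(default_factory=dict)
    saxs: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    escape: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        require(not unknown, f"unknown stages {unknown}; allowed: {KNOWN_STAGES}")
        object.__setattr__(self, "stages", tuple(self.stages))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        _check_block(cfg.trajectories,
                     set(_fields(synthdata.TrajectorySimConfig))
                     | {"groups", "window", "n_boot", "n_bins"}, "trajectories")
        for label, block in cfg.trajectories.get("groups", {}).items():
            _check_block(block, _fields(synthdata.TrajectorySimConfig),
                         f"trajectories.groups.{label}")
        _check_block(cfg.saxs, set(_fields(synthdata.ScatteringSimConfig))
                     | {"samples", "q_window"}, "saxs")
        for label, block in cfg.saxs.get("samples", {}).items():
            _check_block(block, _fields(synthdata.ScatteringSimConfig),
                         f"saxs.samples.{label}")
        _check_block(cfg.qc, _fields(synthdata.PlateSim), "qc")
        _check_block(cfg.escape, set(_fields(synthdata.SpotFieldSim)) | {"k_sigma"},
                     "escape")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def _check_block(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys in {where}: {sorted(unknown)}")


def _sub_seed(seed: int, offset: int) -> int:
    return (int(seed) + 1000003 * offset) % (2 ** 31)


def _stage_trajectories(cfg: RunConfig) -> dict:
    params = dict(cfg.trajectories)
    groups = params.pop("groups", None) or {
        "LNP-like": {"mobile_fraction": 0.3},
        "eLNP-like": {"mobile_fraction": 0.6},
    }
    window = float(params.pop("window", 10.0))
    n_boot = int(params.pop("n_boot", 200))
    n_bins = params.pop("n_bins", None)

    e_means: dict[str, list] = {}
    skipped: dict[str, list] = {}
    for offset, (label, overrides) in enumerate(sorted(groups.items())):
        sim_cfg = synthdata.TrajectorySimConfig(
            **{**params, **overrides,
               "seed": _sub_seed(overrides.get("seed", cfg.seed), offset)})
        traj_set = synthdata.simulate_trajectories(sim_cfg)
        results, skip = trajmetrics.analyze_trajectories(traj_set.trajectories, window)
        e_means[label] = [r.E_mean for r in results]
        skipped[label] = skip

    comparison = trajmetrics.compare_groups(e_means, n_boot=n_boot,
                                            seed=cfg.seed, n_bins=n_bins)
    return {
        "window_s": window,
        "groups": {
            label: {
                "n_trajectories": comparison.n_per_group[label],
                "n_skipped_short": len(skipped[label]),
                "mobile_fraction": comparison.mobile_fractions[label],
                "stationary_fraction":
                    comparison.decompositions[label].stationary_fraction,
                "bootstrap_se": comparison.bootstrap_se[label],
            }
            for label in comparison.labels
        },
        "t_statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "method": comparison.method,
    }


def _stage_saxs(cfg: RunConfig) -> dict:
    params = dict(cfg.saxs)
    samples = params.pop("samples", None) or {
        "eLNP-like": {"peak_q": 0.9462},
        "LNP-like": {"peak_q": 0.8702},
    }
    q_window = tuple(params.pop("q_window", (0.5, 1.5)))
    out: dict = {"d_spacing_table": {}}
    for offset, (label, overrides) in enumerate(sorted(samples.items())):
        sim_cfg = synthdata.ScatteringSimConfig(
            **{**params, **overrides,
               "seed": _sub_seed(overrides.get("seed", cfg.seed), offset)})
        profile = synthdata.simulate_scattering(sim_cfg)
        peak = saxs.find_lamellar_peak(profile, q_window=q_window)
        entry: dict = {"peak_found": peak is not None}
        if peak is not None:
            entry.update(q_peak_nm_inv=peak.q_peak, d_spacing_nm=peak.d_spacing_nm,
                         width_nm_inv=peak.width_nm_inv)
        try:
            fit = saxs.guinier_fit(profile)
            entry.update(Rg_nm=fit.Rg_nm, guinier_qmax_Rg=fit.qmax_Rg, guinier_r2=fit.r2)
        except saxs.GuinierError as exc:
            entry["guinier_error"] = str(exc)
        out["d_spacing_table"][label] = entry
    return out


def _stage_qc(cfg: RunConfig) -> dict:
    sim_cfg = synthdata.PlateSim(**{"seed": cfg.seed, **cfg.qc})
    wells = synthdata.simulate_plate(sim_cfg)
    result = formqc.encapsulation_efficiency(wells)
    return {
        "true_ee_percent": sim_cfg.true_ee,
        "ee_percent": result.ee_percent,
        "ee_sd": result.sd,
        "n_replicates": sim_cfg.n_replicates,
    }


def _stage_escape(cfg: RunConfig) -> dict:
    params = dict(cfg.escape)
    k_sigma = float(params.pop("k_sigma", 3.0))
    sim_cfg = synthdata.SpotFieldSim(**{"seed": cfg.seed, **params})
    objects, truth = synthdata.simulate_spot_field(sim_cfg)
    cal = imaging_quant.calibrate_single_mrna(objects)
    cyt = imaging_quant.count_cytosolic(objects, cal, k_sigma=k_sigma)
    lnp = imaging_quant.count_lnp(objects, sim_cfg.lnp_unit_intensity)
    cells = truth["cell_id"]
    result = imaging_quant.escape_ratio(cyt.loc[cells], lnp.loc[cells])
    return {
        "n_cells": result.n_cells,
        "n_excluded_zero_lnp": result.n_excluded_zero_lnp,
        "mean_escape_ratio": result.mean_ratio,
        "sd_escape_ratio": result.sd_ratio,
        "mean_cytosolic_per_cell": float(cyt.loc[cells].mean()),
        "mean_lnp_per_cell": float(lnp.loc[cells].mean()),
        "truth_mean_cytosolic_per_cell": float(truth["n_cytosolic_mrna"].mean()),
        "truth_mean_lnp_per_cell": float(truth["n_lnp"].mean()),
        "single_mrna_unit_intensity": cal.unit_intensity,
    }


_STAGE_RUNNERS = {
    "trajectories": _stage_trajectories,
    "saxs": _stage_saxs,
    "qc": _stage_qc,
    "escape": _stage_escape,
}


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the report dict.

    When ``outdir`` is given the report is written to ``report.json``; if a
    stage fails, the stages completed so far are written to
    ``report.json.partial`` and a :class:`StageError` naming the failing
    stage is raised.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    outpath = Path(outdir) / "report.json" if outdir is not None else None
    for stage in config.stages:
        try:
            report["stages"][stage] = _STAGE_RUNNERS[stage](config)
        except Exception as exc:
            if outpath is not None:
                outpath.parent.mkdir(parents=True, exist_ok=True)
                write_json_report(str(outpath) + ".partial", report)
            raise StageError(stage, exc) from exc
    if outpath is not None:
        outpath.parent.mkdir(parents=True, exist_ok=True)
        write_json_report(outpath, report)
    return report
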