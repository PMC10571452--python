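"""Configuration-driven analysis pipeline with a reproducible manifest.

Stages: simulate -> explore -> fit-lmm -> fit-cox -> fit-joint -> report.
A run is described by one YAML config (unknown keys are errors); every file
written is listed in the manifest with its SHA-256 checksum, and rerunning
the same config and seed reproduces the checksums of deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import defaults
from .cohort import Cohort, read_cohort, validate_cohort, write_cohort
from .cox import fit_cox
from .design import CovariateDesign
from .explore import (
    descriptive_table,
    empirical_correlation_profile,
    kaplan_meier,
    logrank_test,
    marginal_correlation_profile,
    median_survival,
    profiles,
    restricted_mean_survival,
)
from .joint import JointSpec, association_summary, fit_joint, information_criteria
from .lmm import LmmSpec, fit_lmm
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "report"]

ALL_STAGES = ("simulate", "explore", "fit-lmm", "fit-cox", "fit-joint", "report")

_SIM_KEYS = {
    "n_subjects",
    "seed",
    "association",
    "alpha",
    "alpha_slope",
    "assoc_center",
    "censoring_time",
    "dropout_rate",
}
_JOINT_KEYS = {"association", "n_pieces", "n_nodes", "fix_alpha_zero"}
_TOP_KEYS = {
    "seed",
    "output_dir",
    "stages",
    "simulate",
    "inputs",
    "joint",
    "verbose",
}

log = logging.getLogger("jointvitals")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved run configuration.

    Exactly one of ``inputs`` (paths to long/surv CSVs + optional design
    YAML) and ``simulate`` (generator overrides) must be present.
    """

    output_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    simulate: dict | None = None
    inputs: dict | None = None
    joint: dict = field(default_factory=dict)
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' is required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if self.simulate is not None:
            bad = set(self.simulate) - _SIM_KEYS
            if bad:
                raise ConfigError(f"unknown simulate key(s): {sorted(bad)}")
        if self.inputs is not None:
            bad = set(self.inputs) - {"long", "surv", "design"}
            if bad:
                raise ConfigError(f"unknown inputs key(s): {sorted(bad)}")
        bad = set(self.joint) - _JOINT_KEYS
        if bad:
            raise ConfigError(f"unknown joint key(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bad = set(raw) - _TOP_KEYS
        if bad:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        raw.update(overrides)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "stages": list(self.stages),
            "simulate": self.simulate,
            "inputs": self.inputs,
            "joint": dict(self.joint),
            "verbose": self.verbose,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(outdir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s  %(levelname)-7s %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setLevel(logging.INFO if verbose else logging.WARNING)
    sh.setFormatter(fmt)
    log.addHandler(sh)


def _load_cohort(config: RunConfig) -> Cohort:
    paths = config.inputs
    design = (
        CovariateDesign.from_yaml(paths["design"])
        if paths.get("design")
        else defaults.study_design()
    )
    return read_cohort(paths["long"], paths["surv"], design)


def _simulated_cohort(config: RunConfig, outdir: Path, artifacts: list) -> Cohort:
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    for key in ("alpha", "alpha_slope", "assoc_center"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    sim = SimulationConfig(**overrides)
    cohort, truth = simulate_cohort(sim)
    write_cohort(cohort, outdir / "long.csv", outdir / "surv.csv")
    (outdir / "truth.json").write_text(json.dumps(truth.values, indent=1))
    artifacts += [outdir / "long.csv", outdir / "surv.csv", outdir / "truth.json"]
    log.info(
        "simulated %d subjects, %d longitudinal rows",
        cohort.n_subjects,
        len(cohort.long),
    )
    return cohort


def _stage_explore(cohort: Cohort, outdir: Path, artifacts: list) -> None:
    desc = descriptive_table(cohort)
    desc.to_csv(outdir / "descriptives.csv", index=False)
    artifacts.append(outdir / "descriptives.csv")

    km = kaplan_meier(cohort.surv["event_time_h"], cohort.surv["status"])
    pd.DataFrame(
        {
            "time_h": km.times,
            "survival": km.survival,
            "at_risk": km.at_risk,
            "events": km.events,
        }
    ).to_csv(outdir / "km_curve.csv", index=False)
    artifacts.append(outdir / "km_curve.csv")

    med = median_survival(km)
    rmean = restricted_mean_survival(km)
    lr = {}
    for cov in cohort.design.covariates:
        if cohort.surv[cov.name].nunique() >= 2:
            res = logrank_test(
                cohort.surv["event_time_h"], cohort.surv["status"], cohort.surv[cov.name]
            )
            lr[cov.name] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
    summary = {
        "median_survival_h": med,
        "restricted_mean_survival_h": rmean,
        "logrank": lr,
    }
    (outdir / "survival_summary.json").write_text(json.dumps(summary, indent=1))
    artifacts.append(outdir / "survival_summary.json")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(np.concatenate([[0], km.times]), np.concatenate([[1], km.survival]),
            where="post")
    ax.set(xlabel="hours since admission", ylabel="P(not yet recovered)",
           title="Kaplan-Meier time to recovery")
    fig.tight_layout()
    fig.savefig(outdir / "km_curve.png", dpi=100)
    plt.close(fig)
    artifacts.append(outdir / "km_curve.png")

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, k in zip(axes, cohort.design.outcomes):
        indiv, mean = profiles(cohort, k)
        for _, grp in indiv.groupby("subject_id"):
            ax.plot(grp["time_h"], grp["value"], color="0.8", lw=0.5)
        ax.plot(mean["time_h"], mean["mean"], color="C3", lw=2)
        ax.set(xlabel="hours", ylabel=k, title=f"{k} profiles")
    fig.tight_layout()
    fig.savefig(outdir / "profiles.png", dpi=100)
    plt.close(fig)
    artifacts.append(outdir / "profiles.png")

    emp = empirical_correlation_profile(cohort)
    emp.to_csv(outdir / "empirical_correlation.csv", index=False)
    artifacts.append(outdir / "empirical_correlation.csv")
    log.info("explore stage done (median survival %s h)", med)


def _fit_table_json(fit, path: Path) -> None:
    payload = {
        "loglik": fit.loglik,
        "n_params": getattr(fit, "n_params", None),
        "converged": fit.converged,
        "parameters": fit.parameter_values() if hasattr(fit, "parameter_values") else None,
    }
    path.write_text(json.dumps(payload, indent=1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write ``manifest.json``.

    Returns the manifest; on a stage failure the manifest records partial
    completion and the failing stage's error, then the exception is
    re-raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.verbose)
    artifacts: list[Path] = []
    manifest = {
        "config": config.to_dict(),
        "stages_completed": [],
        "error": None,
    }
    cohort = None
    lmm_fit = None
    cox_fit = None
    joint_fit = None
    t_start = time.time()
    try:
        for stage in config.stages:
            log.info("stage %s", stage)
            if stage == "simulate":
                if config.simulate is None:
                    raise ConfigError("simulate stage requires a simulate config")
                cohort = _simulated_cohort(config, outdir, artifacts)
            else:
                if cohort is None:
                    cohort = (
                        _load_cohort(config)
                        if config.inputs is not None
                        else _simulated_cohort(config, outdir, artifacts)
                    )
                    validate_cohort(cohort)
            if stage == "explore":
                _stage_explore(cohort, outdir, artifacts)
            elif stage == "fit-lmm":
                lmm_fit = fit_lmm(LmmSpec(), cohort)
                lmm_fit.params.to_csv(outdir / "lmm_coefficients.csv", index=False)
                _fit_table_json(lmm_fit, outdir / "lmm_fit.json")
                artifacts += [outdir / "lmm_coefficients.csv", outdir / "lmm_fit.json"]
                grid = np.asarray(defaults.VISIT_GRID)
                marginal_correlation_profile(lmm_fit, grid).to_csv(
                    outdir / "marginal_correlation.csv", index=False
                )
                artifacts.append(outdir / "marginal_correlation.csv")
            elif stage == "fit-cox":
                from .cohort import build_design

                dm = build_design(cohort)
                cox_fit = fit_cox(
                    cohort.surv["event_time_h"],
                    cohort.surv["status"],
                    dm.W,
                    dm.w_columns,
                )
                cox_fit.params.to_csv(outdir / "cox_coefficients.csv", index=False)
                artifacts.append(outdir / "cox_coefficients.csv")
            elif stage == "fit-joint":
                spec = JointSpec(**config.joint)
                joint_fit = fit_joint(spec, cohort)
                joint_fit.params.to_csv(outdir / "joint_coefficients.csv", index=False)
                _fit_table_json(joint_fit, outdir / "joint_fit.json")
                association_summary(joint_fit).to_csv(
                    outdir / "association_summary.csv", index=False
                )
                artifacts += [
                    outdir / "joint_coefficients.csv",
                    outdir / "joint_fit.json",
                    outdir / "association_summary.csv",
                ]
            elif stage == "report":
                text = report(
                    lmm_fit=lmm_fit, cox_fit=cox_fit, joint_fit=joint_fit
                )
                (outdir / "report.txt").write_text(text)
                artifacts.append(outdir / "report.txt")
            manifest["stages_completed"].append(stage)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        manifest["runtime_s"] = round(time.time() - t_start, 3)
        manifest["artifacts"] = {
            str(p.relative_to(outdir)): _sha256(p) for p in artifacts if p.exists()
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _fmt_table(df: pd.DataFrame) -> str:
    with pd.option_context("display.width", 120, "display.float_format",
                           lambda v: f"{v:.4f}"):
        return df.to_string(index=False)


def report(lmm_fit=None, cox_fit=None, joint_fit=None) -> str:
    """Human-readable side-by-side summary of the available fits."""
    if lmm_fit is None and cox_fit is None and joint_fit is None:
        raise ValueError("no fit artifacts to report")
    lines = ["jointvitals model report", "=" * 60]
    if lmm_fit is not None:
        lines += ["", "Bivariate linear mixed sub-model (separate fit)",
                  "-" * 60, _fmt_table(lmm_fit.params)]
        lines += [f"log-likelihood {lmm_fit.loglik:.4f}   AIC {lmm_fit.aic:.4f}   "
                  f"BIC {lmm_fit.bic:.4f}"]
    if cox_fit is not None:
        lines += ["", "Cox proportional-hazards sub-model (separate fit)",
                  "-" * 60]
        if len(cox_fit.params):
            lines.append(_fmt_table(cox_fit.params))
        lines.append(f"partial log-likelihood {cox_fit.partial_loglik:.4f}")
    if joint_fit is not None:
        lines += ["", "Joint model", "-" * 60, _fmt_table(joint_fit.params)]
        lines += ["", "Association summary", _fmt_table(association_summary(joint_fit))]
        ic = information_criteria(joint_fit)
        lines += [
            "",
            f"log-likelihood {ic['loglik']:.4f}   AIC {ic['aic']:.4f}   "
            f"BIC {ic['bic']:.4f}",
            f"  AIC decomposition: longitudinal {ic['aic_longitudinal']:.4f}"
            f" + survival {ic['aic_survival']:.4f}",
        ]
        if lmm_fit is not None:
            sep = lmm_fit.aic
            lines += [
                "",
                "Separate vs joint (longitudinal side):",
                f"  separate LMM AIC {sep:.4f} | joint total AIC {ic['aic']:.4f}",
            ]
    return "\n".join(lines) + "\n"
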