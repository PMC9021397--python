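"""End-to-end orchestration: simulate/load -> bin -> PQN -> classify ->
risk-stratify -> survival analysis -> feature screen, with a JSON report.

Every random quantity in the report is reproducible from (config, seed);
stage outputs are plain CSV/JSON so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import featstats, risk, spectra, synthetic
from .plsda import VoteEnsemble
from .survival import CoxPH, km_estimate, logrank_test

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline",
           "REPORT_SCHEMA", "validate_report"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Single-file configuration for a full pipeline run."""

    mode: str = "synthetic"              # synthetic | spectra_dir | binned_csv
    input_path: str | None = None        # spectra dir or binned CSV
    cohort_path: str | None = None       # cohort CSV for non-synthetic modes
    output_dir: str = "nmrfp_out"
    # synthetic cohort
    n_patients: int = 106
    prop_deceased: float = 26 / 106
    hazard_ratio: float = 5.71
    baseline_hazard: float = 0.04
    censor_time: float = 8.0
    dilution_cv: float = 0.15
    noise_sd: float = 0.02
    # spectral processing
    calibrate: bool = True
    bin_width: float = 0.02
    ppm_min: float = 0.2
    ppm_max: float = 10.0
    exclusions: list = field(
        default_factory=lambda: [list(r) for r in spectra.DEFAULT_EXCLUSIONS])
    # classifier
    n_components: int = 7
    n_iter: int = 100
    per_class: int = 25
    gray_threshold: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("synthetic", "spectra_dir", "binned_csv"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode != "synthetic" and self.cohort_path is None:
            raise ValueError(f"mode {self.mode!r} requires cohort_path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


REPORT_SCHEMA = {
    "seed": int, "config_hash": str, "n_patients": int,
    "classifier": dict, "survival": dict, "feature_screen": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the published key/type schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")


def _km_hr_logrank(times, events, high_mask, tie_method="breslow") -> dict:
    """Two-group KM + log-rank + univariate Cox HR for a binary risk class."""
    high_mask = np.asarray(high_mask, dtype=bool)
    out: dict = {"n_high": int(high_mask.sum()),
                 "n_low": int((~high_mask).sum())}
    if out["n_high"] == 0 or out["n_low"] == 0:
        out.update({"hr": None, "logrank_p": None})
        return out
    lr = logrank_test(times, events, high_mask.astype(int))
    cox = CoxPH(pd.DataFrame({"high_risk": high_mask.astype(float)}),
                times, events, tie_method=tie_method).fit()
    ci = cox.ci95
    out.update({
        "logrank_statistic": lr.statistic, "logrank_p": lr.p_value,
        "hr": float(cox.hr.iloc[0]),
        "hr_ci95": [float(ci.iloc[0, 0]), float(ci.iloc[0, 1])],
        "cox_lrt_p": cox.lrt_p,
    })
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; writes stage outputs and returns the report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = synthetic.SimConfig(
        n_patients=config.n_patients, prop_deceased=config.prop_deceased,
        hazard_ratio=config.hazard_ratio,
        baseline_hazard=config.baseline_hazard,
        censor_time=config.censor_time, dilution_cv=config.dilution_cv,
        noise_sd=config.noise_sd, seed=config.seed)

    # --- stage: load or simulate -----------------------------------------
    stage = "input"
    try:
        if config.mode == "synthetic":
            cohort = synthetic.generate_cohort(sim)
            specs, dilutions = synthetic.generate_cohort_spectra(cohort, sim)
            synthetic.write_cohort_csv(cohort, out_dir / "cohort.csv")
            matrix = None
        elif config.mode == "spectra_dir":
            cohort = synthetic.read_cohort_csv(config.cohort_path)
            specs = spectra.read_spectra_dir(config.input_path)
            dilutions = None
            matrix = None
        else:
            cohort = synthetic.read_cohort_csv(config.cohort_path)
            matrix = spectra.read_binned_csv(config.input_path)
            specs, dilutions = None, None
    except Exception as exc:  # noqa: BLE001 - stage name matters downstream
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: calibrate + bin + normalize -------------------------------
    try:
        if matrix is None:
            stage = "calibrate"
            if config.calibrate:
                specs = [spectra.calibrate_ppm(s) for s in specs]
            stage = "bin"
            matrix = spectra.bin_spectra(
                specs, bin_width=config.bin_width,
                ppm_range=(config.ppm_min, config.ppm_max),
                exclusions=[tuple(r) for r in config.exclusions])
        stage = "pqn"
        if matrix.normalization != "pqn":
            matrix = spectra.pqn_normalize(matrix)
        spectra.write_binned_csv(matrix, out_dir / "binned_pqn.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: ensemble classification -----------------------------------
    stage = "ensemble"
    try:
        truth = cohort["true_class"].to_numpy() if "true_class" in cohort \
            else None
        if truth is None:
            raise ValueError("cohort lacks a class column to train against")
        ens = VoteEnsemble(matrix.values, truth,
                           sample_ids=list(cohort["patient_id"]),
                           n_components=config.n_components,
                           n_iter=config.n_iter, per_class=config.per_class,
                           gray_threshold=config.gray_threshold
                           ).fit(seed=config.seed)
        ens.votes.to_csv(out_dir / "votes.csv", index=False)
        from .plsda import fit_pls, vip_scores
        full_model = fit_pls(matrix.values, truth, config.n_components)
        vip, selected = vip_scores(full_model)
        pd.DataFrame({"bin_start_ppm": matrix.bin_starts, "VIP": vip,
                      "selected": selected}
                     ).to_csv(out_dir / "vip.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: risk stratification ---------------------------------------
    stage = "risk"
    try:
        risk_df = risk.risk_table(cohort, ens.predicted_class)
        risk_df.to_csv(out_dir / "risk_classes.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: survival ---------------------------------------------------
    stage = "survival"
    try:
        t = cohort["survival_time"].to_numpy(dtype=float)
        e = cohort["event"].to_numpy(dtype=int)
        surv_report = {
            "metabolomics": _km_hr_logrank(
                t, e, risk_df["metabolomics"] == "high"),
            "ntprobnp": _km_hr_logrank(t, e, risk_df["ntprobnp"] == "high"),
            "combined_met_lvef": _km_hr_logrank(
                t, e, risk_df["combined_met_lvef"] == "high"),
        }
        km_rows = []
        for grp, mask in (("high", risk_df["metabolomics"] == "high"),
                          ("low", risk_df["metabolomics"] == "low")):
            if mask.sum() == 0:
                continue
            curve = km_estimate(t[mask.to_numpy()], e[mask.to_numpy()])
            df = curve.to_dataframe()
            df.insert(0, "group", grp)
            km_rows.append(df)
        if km_rows:
            pd.concat(km_rows).to_csv(out_dir / "km_metabolomics.csv",
                                      index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: feature screen --------------------------------------------
    stage = "screen"
    try:
        effects = {p.metabolite_name: p.class_effect
                   for p in synthetic.DEFAULT_PEAKS}
        if config.mode == "synthetic":
            feats = synthetic.generate_feature_table(cohort, effects,
                                                     seed=config.seed)
            screen = featstats.wilcoxon_screen(feats,
                                               cohort["true_class"].to_numpy())
            screen.to_csv(out_dir / "feature_screen.csv", index=False)
            n_sig = int((screen["p_fdr"] < 0.05).sum())
            screen_report = {"n_features": int(len(screen)),
                             "n_fdr_significant": n_sig}
        else:
            screen_report = {"n_features": 0, "n_fdr_significant": 0}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    metrics = ens.metrics()
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_patients": int(len(cohort)),
        "classifier": {
            "accuracy": metrics.accuracy,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "n_gray_zone": int(ens.gray_zone.sum()),
            "mean_loocv_accuracy":
                float(ens.iteration_metrics["accuracy"].mean()),
            "n_vip_selected": int(np.sum(selected)),
            "mean_squared_vip": float(np.mean(vip**2)),
        },
        "survival": surv_report,
        "feature_screen": screen_report,
    }
    if dilutions is not None and matrix.quotients is not None:
        corr = float(np.corrcoef(dilutions, matrix.quotients)[0, 1])
        report["classifier"]["pqn_dilution_correlation"] = corr
    validate_report(report)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    (out_dir / "run_log.txt").write_text(
        f"seed={config.seed}\nconfig_hash={config.config_hash()}\n"
        f"mode={config.mode}\nn_patients={len(cohort)}\n")
    return report
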