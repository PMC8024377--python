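"""End-to-end orchestration: simulate -> z-score -> fit/cv -> stage ->
endpoints, as a reproducible seeded run with a manifest.

The pipeline mirrors the train/validate design of multi-trial subtyping
studies: datasets may be split into a training set (model fitting and
leave-one-dataset-out subtype-count selection) and a held-out validation
set that is staged with the frozen model, never refitted.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endpoints as ep
from .io import read_cohort, write_cohort, write_report
from .normative import compute_zscores, fit_normative, select_features
from .selection import cv_select_subtypes, split_by_dataset
from .simulate import GroundTruthConfig, generate_controls, generate_patients
from .sustain import SustainOptions, assign, build_event_grid, fit_sustain

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

PROFILES = {
    # scaled-down profile used by the test suite and examples
    "test": {"n_controls": 300, "n_patients": 500, "n_datasets": 3,
             "n_visits": 3, "starts": 3, "mcmc_iterations": 10_000,
             "max_subtypes": 3},
    # the full-scale configuration
    "full": {"n_controls": 500, "n_patients": 2000, "n_datasets": 3,
             "n_visits": 3, "starts": 25, "mcmc_iterations": 100_000,
             "max_subtypes": 4},
}


@dataclass
class PipelineConfig:
    """Flat configuration for a pipeline run."""

    out_dir: str = "runs/latest"
    profile: str = "test"
    seed: int = 0
    cohen_d_threshold: float = 0.5
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    confirm_weeks: float = 24.0
    # emission scale of the z-score event model; simulated cohorts have a
    # known measurement dispersion (GroundTruthConfig.noise_scale), so the
    # pipeline default matches it
    sigma: float = 0.5
    n_subtypes: int | None = None  # None -> select by CV
    candidates: tuple[int, ...] = (1, 2, 3, 4)
    validation_datasets: tuple[str, ...] = ()
    controls_csv: str | None = None  # simulate when None
    patients_csv: str | None = None
    placebo_only_endpoints: bool = True

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError("profile must be 'test' or 'full'")
        if self.cohen_d_threshold <= 0 or self.z_max <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("thresholds", "candidates", "validation_datasets"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    seed_trail: dict[str, int] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all pipeline stages in order; idempotent given (config, seed).

    Writes, under ``config.out_dir``: the cohort CSVs (when simulated), the
    normative model, the z-score table, the feature selection, the fitted
    subtype model, per-visit assignments, the endpoint report, and a
    manifest listing every output with its checksum.
    """
    from . import __version__

    prof = PROFILES[config.profile]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           software_version=__version__)
    timers: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timers[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _T()

    def emit(name: str, path: Path):
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    # --- simulate or load ------------------------------------------------
    with stage("simulate"):
        if config.controls_csv and config.patients_csv:
            controls = read_cohort(config.controls_csv)
            patients = read_cohort(config.patients_csv)
        else:
            sim = GroundTruthConfig(seed=config.seed,
                                    thresholds=config.thresholds,
                                    z_max=config.z_max)
            manifest.seed_trail["simulate"] = config.seed
            controls = generate_controls(sim, prof["n_controls"])
            patients = generate_patients(sim, prof["n_patients"],
                                         prof["n_datasets"], prof["n_visits"])
            sim.save(out / "ground_truth.json")
            emit("ground_truth", out / "ground_truth.json")
        write_cohort(controls, out / "controls.csv")
        write_cohort(patients, out / "patients.csv")
        emit("controls", out / "controls.csv")
        emit("patients", out / "patients.csv")

    val_ids = set(map(str, config.validation_datasets))
    is_val = patients["dataset_id"].astype(str).isin(val_ids)
    train_pat = patients[~is_val]

    # --- normative model, z-scores, feature selection --------------------
    with stage("zscore"):
        norm = fit_normative(controls)
        norm.save(out / "normative_model.json")
        emit("normative_model", out / "normative_model.json")
        sel = select_features(controls, train_pat,
                              threshold=config.cohen_d_threshold, model=norm)
        sel.save(out / "feature_selection.json")
        emit("feature_selection", out / "feature_selection.json")
        Z = compute_zscores(patients, norm, features=list(sel.retained))
        Z.to_csv(out / "zscores.csv", index=False)
        emit("zscores", out / "zscores.csv")

    grid = build_event_grid(sel.retained, config.thresholds, config.z_max)
    Z_train = Z[~is_val.to_numpy()]

    # --- fit / cross-validate -------------------------------------------
    opts = SustainOptions(starts=prof["starts"], seed=config.seed,
                          sigma=config.sigma, split_starts=2,
                          em_max_iter=15, em_tol=0.01)
    with stage("fit"):
        if config.n_subtypes is not None:
            model = fit_sustain(Z_train, grid, config.n_subtypes, opts)
            cv_table = None
        else:
            cands = [c for c in config.candidates
                     if c <= prof["max_subtypes"]]
            cv = cv_select_subtypes(Z_train, grid, candidates=cands, opts=opts)
            model = cv.final_model
            cv_table = cv.table
            cv.table.to_csv(out / "cv_table.csv")
            emit("cv_table", out / "cv_table.csv")
        model.save(out / "subtype_model.json")
        emit("subtype_model", out / "subtype_model.json")

    # --- stage every visit (frozen model; validation never refits) -------
    with stage("stage"):
        model_checksum = _sha256(out / "subtype_model.json")
        asg = assign(Z, model)
        asg.table.to_csv(out / "assignments.csv", index=False)
        emit("assignments", out / "assignments.csv")
        assert _sha256(out / "subtype_model.json") == model_checksum

    # --- clinical endpoints ----------------------------------------------
    with stage("endpoints"):
        joined = patients.merge(
            asg.table, on=[c for c in ("subject_id", "dataset_id",
                                       "visit_time", "arm")
                           if c in asg.table.columns])
        report = _endpoint_report(joined, config)
        write_report(report, out / "endpoint_report.json")
        emit("endpoint_report", out / "endpoint_report.json")

    manifest.stage_seconds = timers
    manifest.save(out / "manifest.json")
    return manifest


def _endpoint_report(joined: pd.DataFrame, config: PipelineConfig) -> dict:
    """Survival, relapse, stage-slope and stability summaries by subtype."""
    confirm_days = config.confirm_weeks * 7.0
    scope = joined[joined["arm"] == "placebo"] if config.placebo_only_endpoints \
        else joined
    base = scope.sort_values("visit_time").groupby("subject_id").first()
    subtype_of = base["modal_subtype"]
    report: dict = {"n_subjects": int(joined["subject_id"].nunique()),
                    "n_visits": int(len(joined))}

    surv = ep.cdp_survival_table(scope, confirm_days=confirm_days,
                                 groups=subtype_of)
    if len(surv) and surv["event"].sum() > 0 and surv["group"].nunique() > 1:
        chi2, p = ep.logrank_compare(surv)
        report["cdp_logrank"] = {"chi2": chi2, "p": p}
        ref = int(surv["group"].value_counts().idxmax())
        hc = ep.hazard_contrast(surv, reference_group=ref)
        report["cdp_hazard_vs_largest_subtype"] = {
            str(g): dict(row) for g, row in hc.iterrows()}
    arr = ep.annualized_relapse_rate(scope, subtype_of)
    report["annualized_relapse_rate"] = {
        str(g): dict(row) for g, row in arr.iterrows()}
    slopes = ep.annual_stage_change(scope, subtype_of)
    report["annual_stage_change"] = {
        str(g): dict(row) for g, row in slopes.iterrows()}
    report["subtype_stability"] = ep.subtype_stability(joined)
    report["gad_count_mean_by_subtype"] = {
        str(g): float(v) for g, v in
        scope.groupby(scope["subject_id"].map(subtype_of))["gad_count"]
        .mean().items()}
    return report
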