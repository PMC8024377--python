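"""Control-referenced normative modelling and z-scoring of MRI features.

Each MRI variable is regressed on total intracranial volume, sex, age and
age squared in healthy controls (flat-prior posterior mean, i.e. least
squares); patient visits are converted to z-scores by subtracting the
normative prediction and the mean control residual and dividing by the
control residual standard deviation.  Because lower volumes and lower
NAWM T1/T2 ratios mean worse disease, their z-scores are sign-flipped so
that higher z always represents worsening; lesion volume is not flipped.
Features are then screened by patient-versus-control Cohen's D (|D| > 0.5
retained by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FEATURES, FLIPPED_FEATURES

__all__ = [
    "NormativeModel",
    "FeatureSelection",
    "COVARIATE_COLUMNS",
    "fit_normative",
    "compute_zscores",
    "cohen_d",
    "select_features",
    "adjusted_values",
]

COVARIATE_COLUMNS = ("tiv", "sex", "age")

_DEFAULT_REGION_CLASS = {
    f.name: (f.region, f.tissue, f.modality) for f in FEATURES
}


def _design_matrix(df: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    age = df["age"].to_numpy(dtype=float)
    return np.column_stack([
        np.ones(len(df)),
        df["tiv"].to_numpy(dtype=float),
        df["sex"].to_numpy(dtype=float),
        age,
        age**2,
    ])


@dataclass
class NormativeModel:
    """Per-feature least-squares fit on controls.

    coefs: (F, 5) array, columns (intercept, tiv, sex, age, age^2).
    resid_sd: control residual SD, denominator n - 5.
    resid_mean: mean control residual (exactly 0 for a fit with intercept,
    stored for the z-score definition).
    """

    features: tuple[str, ...]
    coefs: np.ndarray
    resid_sd: np.ndarray
    resid_mean: np.ndarray

    def __post_init__(self):
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.resid_sd = np.asarray(self.resid_sd, dtype=float)
        self.resid_mean = np.asarray(self.resid_mean, dtype=float)
        if not np.all(np.isfinite(self.coefs)):
            raise ValueError("non-finite coefficients")
        if np.any(self.resid_sd <= 0):
            raise ValueError("residual SD must be positive for every feature")

    def predict(self, df: pd.DataFrame) -> pd.DataFrame:
        X = _design_matrix(df)
        return pd.DataFrame(X @ self.coefs.T, columns=list(self.features),
                            index=df.index)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefs": self.coefs.tolist(),
            "resid_sd": self.resid_sd.tolist(),
            "resid_mean": self.resid_mean.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(tuple(d["features"]), np.asarray(d["coefs"]),
                   np.asarray(d["resid_sd"]), np.asarray(d["resid_mean"]))

    @classmethod
    def load(cls, path) -> "NormativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_normative(controls: pd.DataFrame, features=None) -> NormativeModel:
    """Fit the covariate model on healthy-control visits only.

    Requires at least 10 control visits and a full-rank design (constant
    age or single-sex samples are rejected).
    """
    if features is None:
        features = [f for f in (s.name for s in FEATURES) if f in controls.columns]
        if not features:
            raise ValueError("no known feature columns in control table")
    X = _design_matrix(controls)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 control visits")
    if n <= X.shape[1]:
        raise ValueError("fewer controls than regression parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design matrix (degenerate covariates, e.g. "
            "constant age or single-sex controls)")
    Y = controls[list(features)].to_numpy(dtype=float)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    sd = resid.std(axis=0, ddof=X.shape[1])
    if np.any(sd <= 0):
        bad = [f for f, s in zip(features, sd) if s <= 0]
        raise ValueError(f"zero control residual SD for features: {bad}")
    return NormativeModel(
        features=tuple(features),
        coefs=B.T,
        resid_sd=sd,
        resid_mean=resid.mean(axis=0),
    )


def adjusted_values(df: pd.DataFrame, model: NormativeModel,
                    features=None) -> pd.DataFrame:
    """Observed minus normative prediction (the 'adjusted' values)."""
    features = list(features or model.features)
    missing = [f for f in features if f not in model.features]
    if missing:
        raise ValueError(f"features absent from normative model: {missing}")
    pred = model.predict(df)[features]
    return df[features].astype(float) - pred


def compute_zscores(
    cohort: pd.DataFrame,
    model: NormativeModel,
    features=None,
    flip=FLIPPED_FEATURES,
    key_columns=("subject_id", "dataset_id", "arm", "visit_time"),
) -> pd.DataFrame:
    """Sign-corrected z-score table for the requested features.

    z = (residual - mean control residual) / control residual SD, then
    negated for features in ``flip`` so that higher z = worse disease.
    The returned frame carries the key columns plus one z column per
    feature; ``attrs['flipped']`` records the applied sign convention.
    """
    features = list(features or model.features)
    adj = adjusted_values(cohort, model, features)
    idx = [model.features.index(f) for f in features]
    z = (adj.to_numpy() - model.resid_mean[idx][None, :]) / model.resid_sd[idx][None, :]
    flipped = [f for f in features if f in flip]
    for j, f in enumerate(features):
        if f in flip:
            z[:, j] = -z[:, j]
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores produced")
    keys = [c for c in key_columns if c in cohort.columns]
    out = cohort[keys].copy().reset_index(drop=True)
    for j, f in enumerate(features):
        out[f] = z[:, j]
    out.attrs["flipped"] = sorted(flipped)
    out.attrs["features"] = features
    return out


def cohen_d(group_a, group_b) -> float:
    """Standardized mean difference (mean_b - mean_a) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    return float((b.mean() - a.mean()) / np.sqrt(sp2))


@dataclass
class FeatureSelection:
    """Effect-size screening result: per-feature Cohen's D (patients vs
    controls on adjusted values) and the retained feature list."""

    effect_sizes: dict[str, float]
    retained: tuple[str, ...]
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "effect_sizes": self.effect_sizes,
            "retained": list(self.retained),
            "threshold": self.threshold,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureSelection":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["effect_sizes"], tuple(d["retained"]), d["threshold"])


def _baseline(patients: pd.DataFrame) -> pd.DataFrame:
    """Earliest visit per subject; ties broken by row order."""
    if "visit_time" not in patients.columns:
        return patients
    idx = patients.groupby("subject_id", sort=False)["visit_time"].idxmin()
    return patients.loc[idx]


def select_features(
    controls: pd.DataFrame,
    patients_baseline: pd.DataFrame,
    threshold: float = 0.5,
    model: NormativeModel | None = None,
    region_class: dict | None = None,
) -> FeatureSelection:
    """Retain features whose patient-versus-control |Cohen's D| exceeds the
    threshold, computed on covariate-adjusted values.

    When a region contributes both a passing volume and a passing T1/T2
    measure, the volume is kept for grey-matter regions and the T1/T2 for
    white-matter regions (the two are strongly correlated within region).
    """
    if model is None:
        model = fit_normative(controls)
    patients_baseline = _baseline(patients_baseline)
    adj_c = adjusted_values(controls, model)
    adj_p = adjusted_values(patients_baseline, model)
    D = {f: cohen_d(adj_c[f], adj_p[f]) for f in model.features}
    passing = [f for f in model.features if abs(D[f]) > threshold]

    region_class = region_class or _DEFAULT_REGION_CLASS
    by_region: dict[str, list[str]] = {}
    for f in passing:
        region = region_class.get(f, (f, None, None))[0]
        by_region.setdefault(region, []).append(f)
    retained = []
    for f in passing:
        region, tissue, modality = region_class.get(f, (f, None, None))
        group = by_region[region]
        if len(group) > 1 and modality is not None:
            modalities = {region_class[g][2] for g in group}
            if modalities == {"volume", "t1t2"}:
                want = "volume" if tissue == "gm" else "t1t2"
                if modality != want:
                    continue
        retained.append(f)
    if not retained:
        detail = ", ".join(f"{f}: D={D[f]:+.3f}" for f in model.features)
        raise ValueError(
            f"no feature passed |D| > {threshold}; effect sizes: {detail}")
    return FeatureSelection(effect_sizes=D, retained=tuple(retained),
                            threshold=threshold)
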