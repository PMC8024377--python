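"""Synthetic multi-trial MS cohort generator.

Real MRI-feature trial data of the kind this pipeline analyses are held by
pharmaceutical data controllers, so the package ships a simulator whose
statistical structure matches everything downstream modules assume: a
healthy-control stratum whose 18 MRI features depend on intracranial
volume, sex, age and age squared; a patient stratum drawn from C latent
subtypes, each with its own event sequence over the affected features and a
truncated-geometric baseline stage distribution; dataset-level offsets
across pseudo-trials; longitudinal visits with advancing stage; and
clinical outcomes (EDSS trajectories, relapses, contrast-enhancing lesion
counts) coupled to subtype, stage, and treatment arm.

The default configuration ``G1`` (see :func:`default_fixture`) plants three
subtypes qualitatively matching the cortex-led / NAWM-led / lesion-led
orderings with mixture fractions 0.43/0.32/0.25, annual stage-progression
rates 0.2/0.3/0.65, relapse rates 0.25/0.25/0.55, a 1.3 disability-
progression hazard ratio for the lesion-led subtype, and a 0.34 treatment
multiplier (a −66% EDSS-slope treatment response) in the lesion-led
subtype.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sustain import EventGrid, build_event_grid, expected_values, is_valid_sequence

__all__ = [
    "FeatureSpec",
    "FEATURES",
    "FEATURE_NAMES",
    "AFFECTED_FEATURES",
    "FLIPPED_FEATURES",
    "ClinicalCoupling",
    "GroundTruthConfig",
    "generate_controls",
    "generate_patients",
    "default_fixture",
    "default_config",
    "planted_model",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One MRI-derived variable: region, modality, control distribution and
    covariate coefficients (intercept-free; order tiv, sex, age, age^2)."""

    name: str
    region: str
    modality: str  # "volume" | "t1t2"
    tissue: str  # "gm" | "wm" | "lesion"
    control_mean: float
    control_sd: float
    coefs: tuple[float, float, float, float]


def _vol(name, region, tissue, mean, sd, age_slope):
    # Volumes scale with head size; mild atrophy with age, accelerating late.
    return FeatureSpec(
        name, region, "volume", tissue, mean, sd,
        (0.8 * mean / 1500.0, -0.02 * mean, age_slope, -0.0002 * mean / 10.0),
    )


def _t1t2(name, region, mean=1.40, sd=0.06):
    return FeatureSpec(
        name, region, "t1t2", "wm", mean, sd, (0.0, 0.005, -0.0008, -2e-6)
    )


#: The 18 variables the pipeline expects: 10 regional volumes, 7 regional
#: NAWM T1/T2 ratios, and total T2 lesion volume.  Control means/SDs are
#: plausible adult values (documented constants, not claims about any
#: specific population).
FEATURES: tuple[FeatureSpec, ...] = (
    _vol("frontal_gm", "frontal", "gm", 160.0, 12.0, -0.30),
    _vol("parietal_gm", "parietal", "gm", 120.0, 10.0, -0.25),
    _vol("temporal_gm", "temporal", "gm", 130.0, 10.0, -0.22),
    _vol("occipital_gm", "occipital", "gm", 70.0, 7.0, -0.12),
    _vol("limbic_gm", "limbic", "gm", 45.0, 5.0, -0.08),
    _vol("deep_gm", "deep", "gm", 31.0, 2.5, -0.05),
    _vol("cerebellar_gm", "cerebellum", "gm", 105.0, 9.0, -0.15),
    _vol("cerebellar_wm", "cerebellum_wm", "wm", 25.0, 3.0, -0.03),
    _vol("brainstem", "brainstem", "wm", 22.0, 2.5, -0.02),
    _vol("cerebral_wm", "cerebrum_wm", "wm", 470.0, 35.0, -0.50),
    _t1t2("t1t2_cc", "cc_nawm"),
    _t1t2("t1t2_cingulate", "cingulate_nawm"),
    _t1t2("t1t2_frontal", "frontal_nawm"),
    _t1t2("t1t2_parietal", "parietal_nawm"),
    _t1t2("t1t2_temporal", "temporal_nawm"),
    _t1t2("t1t2_occipital", "occipital_nawm"),
    _t1t2("t1t2_cerebellum", "cerebellum_nawm"),
    FeatureSpec("lesion_volume", "whole_brain", "volume", "lesion",
                2.0, 1.5, (0.0, 0.0, 0.0, 0.0)),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
_SPEC_BY_NAME = {f.name: f for f in FEATURES}

#: The 13 features planted as abnormal in patients: six grey-matter
#: volumes, six NAWM T1/T2 ratios, and lesion volume.
AFFECTED_FEATURES: tuple[str, ...] = (
    "frontal_gm", "parietal_gm", "temporal_gm", "occipital_gm", "limbic_gm",
    "deep_gm",
    "t1t2_cc", "t1t2_cingulate", "t1t2_frontal", "t1t2_parietal",
    "t1t2_temporal", "t1t2_cerebellum",
    "lesion_volume",
)

#: Features where *lower* raw values mean worse disease; their z-scores are
#: sign-flipped so that higher z always means worse.  Lesion volume grows
#: with disease and is not flipped.
FLIPPED_FEATURES: frozenset[str] = frozenset(
    f.name for f in FEATURES if f.name != "lesion_volume"
)

COVARIATE_NAMES = ("tiv", "sex", "age", "age2")


def _schedule_sequence(grid: EventGrid, priority: list[str], spread: float = 4.3
                       ) -> np.ndarray:
    """Deterministic valid sequence from a feature priority order.

    Event (feature, threshold r) gets key rank(feature) + spread*(r-1);
    sorting the keys staggers the thresholds so early features reach z=3
    before late features reach z=1, as in observed progression patterns.
    """
    T = len(grid.thresholds)
    rank = {name: i for i, name in enumerate(priority)}
    keys = []
    for e in range(grid.n_events):
        f = grid.features[grid.event_feature(e)]
        r = e % T
        keys.append(rank[f] + spread * r + 1e-6 * e)
    return np.array(sorted(range(grid.n_events), key=lambda e: keys[e]), dtype=int)


_CORT = ["parietal_gm", "occipital_gm", "frontal_gm", "temporal_gm", "limbic_gm"]
_NAWM = ["t1t2_cc", "t1t2_cingulate", "t1t2_cerebellum", "t1t2_temporal",
         "t1t2_parietal", "t1t2_frontal"]


def _default_sequences(grid: EventGrid) -> np.ndarray:
    """Three planted orderings: cortex-led (cortical atrophy first, NAWM
    last), NAWM-led (corpus callosum / cingulate T1/T2 first), lesion-led
    (lesion accrual then deep grey matter atrophy first, NAWM last)."""
    cortex_led = _CORT + ["lesion_volume", "deep_gm"] + _NAWM
    nawm_led = _NAWM[:2] + _NAWM[2:] + ["occipital_gm", "lesion_volume",
                                        "parietal_gm", "frontal_gm",
                                        "temporal_gm", "limbic_gm", "deep_gm"]
    lesion_led = (["lesion_volume", "deep_gm"]
                  + ["occipital_gm", "parietal_gm", "temporal_gm",
                     "frontal_gm", "limbic_gm"] + _NAWM)
    return np.vstack([
        _schedule_sequence(grid, order)
        for order in (cortex_led, nawm_led, lesion_led)
    ])


@dataclass
class ClinicalCoupling:
    """How clinical outcomes attach to subtype and stage.

    Baseline EDSS = intercept + stage_coef * baseline stage + subtype
    offset + N(0, baseline_sd), rounded to the 0.5 lattice and clipped to
    [0, 10].  At each follow-up year the EDSS jumps by the subject's
    confirmed-progression threshold with probability progression_prob[c] *
    arm multiplier (so the discrete-time progression hazard ratio and the
    expected EDSS-slope treatment response are planted directly).  Relapses
    between visits are Poisson(relapse_rate[c] * multiplier * dt); contrast-
    enhancing lesion counts are Poisson(gad_mean[c] * multiplier).
    """

    edss_intercept: float = 1.5
    edss_stage_coef: float = 0.13
    edss_subtype_offset: tuple[float, ...] = (0.0, -0.3, 0.5)
    edss_baseline_sd: float = 0.5
    progression_prob: tuple[float, ...] = (0.20, 0.20, 0.26)
    treatment_multiplier: tuple[float, ...] = (1.0, 1.0, 0.34)
    relapse_rate: tuple[float, ...] = (0.25, 0.25, 0.55)
    gad_mean: tuple[float, ...] = (0.93, 0.51, 2.28)


@dataclass
class GroundTruthConfig:
    """Full ground truth for one simulated study collection."""

    features: tuple[str, ...] = FEATURE_NAMES
    affected_features: tuple[str, ...] = AFFECTED_FEATURES
    n_subtypes: int = 3
    sequences: np.ndarray | None = None  # (C, E) over the affected-feature grid
    fractions: tuple[float, ...] = (0.43, 0.32, 0.25)
    # truncated-geometric baseline-stage laws chosen so the mean baseline
    # stage per subtype is ~14.5 / 13.8 / 16.2 of 39 (lesion-led highest)
    stage_geometric_p: tuple[float, ...] = (0.038, 0.0445, 0.0253)
    progression_rate: tuple[float, ...] = (0.2, 0.3, 0.65)
    control_means: dict[str, float] = field(
        default_factory=lambda: {f.name: f.control_mean for f in FEATURES})
    control_sds: dict[str, float] = field(
        default_factory=lambda: {f.name: f.control_sd for f in FEATURES})
    covariate_coefs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {f.name: f.coefs for f in FEATURES})
    dataset_offsets: tuple[float, ...] = (0.0, 0.1, -0.1)  # in control-SD units
    noise_scale: float = 0.5  # patient measurement noise, in control-SD units
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    clinical: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    visit_interval: float = 1.0  # years
    max_rows: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("subtype fractions must sum to 1")
        if len(self.fractions) != self.n_subtypes:
            raise ValueError("one fraction per subtype required")
        if not set(self.affected_features) <= set(self.features):
            raise ValueError("affected_features must be a subset of features")
        if any(r < 0 for r in self.progression_rate):
            raise ValueError("progression rates must be >= 0")
        if self.sequences is None:
            if (self.n_subtypes == 3
                    and tuple(self.affected_features) == AFFECTED_FEATURES):
                self.sequences = _default_sequences(self.grid)
            else:
                raise ValueError("sequences must be given for non-default grids")
        self.sequences = np.atleast_2d(np.asarray(self.sequences, dtype=int))
        if self.sequences.shape[0] != self.n_subtypes:
            raise ValueError("one sequence per subtype required")
        for s in self.sequences:
            if not is_valid_sequence(self.grid, s):
                raise ValueError("planted sequence is not a valid event order")

    @property
    def grid(self) -> EventGrid:
        return build_event_grid(self.affected_features, self.thresholds, self.z_max)

    @property
    def n_events(self) -> int:
        return self.grid.n_events

    def stage_law(self, subtype: int) -> np.ndarray:
        """Truncated-geometric baseline-stage distribution over 0..E."""
        k = np.arange(self.n_events + 1)
        p = self.stage_geometric_p[subtype]
        w = p * (1 - p) ** k
        return w / w.sum()

    def to_dict(self) -> dict:
        d = {
            "features": list(self.features),
            "affected_features": list(self.affected_features),
            "n_subtypes": self.n_subtypes,
            "sequences": self.sequences.tolist(),
            "fractions": list(self.fractions),
            "stage_geometric_p": list(self.stage_geometric_p),
            "progression_rate": list(self.progression_rate),
            "control_means": dict(self.control_means),
            "control_sds": dict(self.control_sds),
            "covariate_coefs": {k: list(v) for k, v in self.covariate_coefs.items()},
            "dataset_offsets": list(self.dataset_offsets),
            "noise_scale": self.noise_scale,
            "thresholds": list(self.thresholds),
            "z_max": self.z_max,
            "clinical": dataclasses.asdict(self.clinical),
            "visit_interval": self.visit_interval,
            "seed": self.seed,
        }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthConfig":
        d = dict(d)
        clin = d.pop("clinical", None)
        kwargs = {
            k: (tuple(v) if isinstance(v, list) and k != "sequences" else v)
            for k, v in d.items()
        }
        if "sequences" in kwargs and kwargs["sequences"] is not None:
            kwargs["sequences"] = np.asarray(kwargs["sequences"], dtype=int)
        if "covariate_coefs" in kwargs:
            kwargs["covariate_coefs"] = {
                k: tuple(v) for k, v in d["covariate_coefs"].items()}
        if clin is not None:
            kwargs["clinical"] = ClinicalCoupling(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in clin.items()})
        kwargs.pop("max_rows", None)
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "GroundTruthConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _rng(config: GroundTruthConfig, stream: int) -> np.random.Generator:
    # one RNG stream per table, derived from the master seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _covariates(rng, n, *, patient: bool):
    if patient:
        age = np.clip(rng.normal(43.0, 10.0, n), 18.0, 75.0)
        sex = (rng.uniform(size=n) < 0.64).astype(int)  # 1 = female
    else:
        age = rng.uniform(25.0, 65.0, n)
        sex = (rng.uniform(size=n) < 0.5).astype(int)
    tiv = rng.normal(1500.0, 120.0, n)
    return age, sex, tiv


def _design(age, sex, tiv) -> np.ndarray:
    return np.column_stack([tiv, sex, age, age**2])


def _predicted(config: GroundTruthConfig, age, sex, tiv) -> np.ndarray:
    X = _design(age, sex, tiv)
    B = np.array([config.covariate_coefs[f] for f in config.features])  # (F, 4)
    mu = np.array([config.control_means[f] for f in config.features])
    # centre covariates at reference values so control_mean is the value at
    # the reference subject (tiv 1500, male, age 45)
    ref = np.array([1500.0, 0.0, 45.0, 45.0**2])
    return mu[None, :] + (X - ref[None, :]) @ B.T


def generate_controls(config: GroundTruthConfig, n: int) -> pd.DataFrame:
    """Healthy-control table: one visit each, features = covariate-driven
    normative value + N(0, control_sd).  Deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(config, 1)
    age, sex, tiv = _covariates(rng, n, patient=False)
    pred = _predicted(config, age, sex, tiv)
    sds = np.array([config.control_sds[f] for f in config.features])
    values = pred + rng.standard_normal((n, len(config.features))) * sds[None, :]
    df = pd.DataFrame({
        "subject_id": [f"HC{i:05d}" for i in range(n)],
        "dataset_id": "controls",
        "arm": "control",
        "visit_time": 0.0,
        "age": age,
        "sex": sex,
        "tiv": tiv,
    })
    for j, f in enumerate(config.features):
        df[f] = values[:, j]
    for col in ("edss", "relapses_since_last_visit", "gad_count"):
        df[col] = np.nan
    df["true_subtype"] = np.nan
    df["true_stage"] = np.nan
    return df


def _cdp_threshold(baseline_edss: np.ndarray) -> np.ndarray:
    out = np.where(baseline_edss == 0.0, 1.5,
                   np.where(baseline_edss <= 5.5, 1.0, 0.5))
    return out


def generate_patients(
    config: GroundTruthConfig, n: int, n_datasets: int = 3, n_visits: int = 3
) -> pd.DataFrame:
    """Patient table: longitudinal visits with advancing stage and coupled
    clinical outcomes.

    Each subject draws a latent subtype from the mixture fractions and a
    baseline stage from the truncated-geometric stage law; stage at later
    visits advances by progression_rate * elapsed years with stochastic
    rounding (one uniform per subject, so stages are monotone within
    subject and unbiased in expectation).  Affected raw features sit at the
    normative prediction displaced by the expected trajectory z-value times
    the control SD (sign-flipped for volumes/T1-T2; positive for lesions)
    plus measurement noise ``noise_scale * control_sd``; unaffected
    features follow the control law.  Datasets are assigned round-robin
    with per-dataset additive offsets; arms alternate placebo/treated.
    """
    C = config.n_subtypes
    if n < C:
        raise ValueError("need at least one subject per subtype")
    if n_datasets < 1 or n_visits < 1:
        raise ValueError("n_datasets and n_visits must be >= 1")
    if n * n_visits > config.max_rows:
        raise ValueError("requested table exceeds configured row cap")
    rng = _rng(config, 2)
    E = config.n_events
    grid = config.grid
    clin = config.clinical

    subtype = rng.choice(C, size=n, p=np.asarray(config.fractions))
    stage0 = np.empty(n, dtype=int)
    for c in range(C):
        mask = subtype == c
        stage0[mask] = rng.choice(E + 1, size=mask.sum(), p=config.stage_law(c))
    round_u = rng.uniform(size=n)

    age0, sex, tiv = _covariates(rng, n, patient=True)
    dataset_idx = np.arange(n) % n_datasets
    arm = np.where(np.arange(n) % 2 == 0, "placebo", "treated")
    mult = np.where(
        arm == "treated",
        np.asarray(clin.treatment_multiplier)[subtype],
        1.0,
    )

    # baseline EDSS on the half-point lattice
    edss0 = (clin.edss_intercept
             + clin.edss_stage_coef * stage0
             + np.asarray(clin.edss_subtype_offset)[subtype]
             + rng.normal(0.0, clin.edss_baseline_sd, n))
    edss0 = np.clip(np.round(edss0 * 2.0) / 2.0, 0.0, 10.0)
    thr = _cdp_threshold(edss0)

    # per-subtype expected-trajectory matrices over the affected grid
    Gs = np.stack([expected_values(grid, s) for s in config.sequences])  # (C,F_a,E+1)
    aff_idx = [config.features.index(f) for f in config.affected_features]
    sds = np.array([config.control_sds[f] for f in config.features])
    sign = np.array([
        +1.0 if f == "lesion_volume" or f not in FLIPPED_FEATURES else -1.0
        for f in config.features
    ])
    offsets = np.asarray(config.dataset_offsets, dtype=float)
    if offsets.size < n_datasets:
        offsets = np.resize(offsets, n_datasets)

    rates = np.asarray(config.progression_rate)[subtype]
    prog_p = np.asarray(clin.progression_prob)[subtype] * mult
    lam = np.asarray(clin.relapse_rate)[subtype] * mult
    gad_lam = np.asarray(clin.gad_mean)[subtype] * mult

    rows = []
    n_feat = len(config.features)
    edss_cur = edss0.copy()
    # pre-draw per-visit randomness for determinism regardless of row order
    for v in range(n_visits):
        t = v * config.visit_interval
        stage_v = np.minimum(E, stage0 + np.floor(rates * t + round_u).astype(int))
        age = age0 + t
        pred = _predicted(config, age, sex, tiv)
        values = pred + rng.standard_normal((n, n_feat)) * sds[None, :]
        # overwrite affected features: displacement + reduced noise
        z_true = Gs[subtype, :, :][np.arange(n), :, stage_v]  # (n, F_a)
        for j_a, j in enumerate(aff_idx):
            noise = rng.standard_normal(n) * (config.noise_scale * sds[j])
            values[:, j] = pred[:, j] + sign[j] * z_true[:, j_a] * sds[j] + noise
        values += (offsets[dataset_idx][:, None] * sds[None, :])
        if v > 0:
            dt = config.visit_interval
            jump = rng.uniform(size=n) < prog_p * dt
            edss_cur = np.clip(edss_cur + jump * thr, 0.0, 10.0)
            relapses = rng.poisson(lam * dt)
        else:
            relapses = np.full(n, np.nan)
        gad = rng.poisson(gad_lam)
        df_v = pd.DataFrame({
            "subject_id": [f"MS{i:05d}" for i in range(n)],
            "dataset_id": [f"D{d + 1}" for d in dataset_idx],
            "arm": arm,
            "visit_time": t,
            "age": age,
            "sex": sex,
            "tiv": tiv,
        })
        for j, f in enumerate(config.features):
            df_v[f] = values[:, j]
        df_v["edss"] = edss_cur.copy()
        df_v["relapses_since_last_visit"] = relapses
        df_v["gad_count"] = gad.astype(float)
        df_v["true_subtype"] = subtype.astype(float)
        df_v["true_stage"] = stage_v.astype(float)
        rows.append(df_v)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["subject_id", "visit_time"], kind="stable")
    return out.reset_index(drop=True)


_FIXTURE_SEED = 20210406


def default_config(seed: int = _FIXTURE_SEED) -> GroundTruthConfig:
    """The packaged ground-truth configuration G1 (18 features, 13
    affected, three planted subtypes with fractions 0.43/0.32/0.25)."""
    return GroundTruthConfig(seed=seed)


def default_fixture(seed: int = _FIXTURE_SEED):
    """(config, controls, patients): the packaged synthetic stand-in for the
    inaccessible training studies — 500 controls; 2000 patients across 3
    pseudo-trials with 3 annual visits each."""
    config = default_config(seed)
    controls = generate_controls(config, 500)
    patients = generate_patients(config, 2000, n_datasets=3, n_visits=3)
    return config, controls, patients


def planted_model(config: GroundTruthConfig):
    """The ground-truth SubtypeModel implied by a configuration (unit
    emission noise, the planted sequences and fractions)."""
    from .sustain import SubtypeModel

    return SubtypeModel(
        grid=config.grid,
        sequences=config.sequences,
        fractions=np.asarray(config.fractions, dtype=float),
        sigma=1.0,
    )
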