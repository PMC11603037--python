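"""Synthetic perioperative cohort generator.

The real cohort behind this kind of study cannot be shared, so every
downstream stage is exercised on simulated data with controllable class
signal.  The generator emulates the structural properties that matter for
the methods, not physiology:

* ~8-9% POD prevalence, multiple surgeries per patient, patient-level random
  intercepts shared across a patient's surgeries;
* per-feature latent trajectories: stationary AR(1) on a 1-minute grid plus
  a class-dependent mean shift and within-window linear trend, observed at
  Poisson-process times with i.i.d. Gaussian measurement noise;
* informative missingness: a class-dependent log-shift of the observation
  Poisson rate, so POD-positive surgeries are observed more or less often;
* Nu-DESC assessments drawn after anesthesia end, with positives guaranteed
  a total score >= 1 and negatives all-zero.

One global seed drives a counter-based Philox stream per surgery, so adding
surgeries never perturbs earlier ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import EVENT_COLUMNS, FeatureSpec, NUDESC_CATEGORIES

__all__ = [
    "FeatureSim",
    "SimConfig",
    "SimTruth",
    "default_config",
    "generate_cohort",
    "make_mean_matched_slope_cohort",
    "simulated_feature_specs",
    "write_cohort",
]


@dataclass(frozen=True)
class FeatureSim:
    """Generator parameters for one time-dynamic feature.

    ``obs_rate_per_min`` is the Poisson observation rate; 1/3 per minute
    reproduces the ~3-minute spacing typical of intraoperative vital-sign
    charting.  Class effects are applied to POD-positive surgeries only:
    ``delta_mean`` shifts the latent level, ``delta_slope_per_min`` adds a
    linear trend (in latent-SD units per minute), ``delta_log_obs_rate``
    shifts the log observation rate (informative missingness).
    """

    name: str
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    ar1_coef: float = 0.9
    obs_rate_per_min: float = 1.0 / 3.0
    noise_sd: float = 0.1
    delta_mean: float = 0.0
    delta_slope_per_min: float = 0.0
    delta_log_obs_rate: float = 0.0

    def __post_init__(self):
        if not 0 <= self.ar1_coef < 1:
            raise ValueError(f"{self.name}: ar1_coef must be in [0, 1)")
        if self.obs_rate_per_min <= 0:
            raise ValueError(f"{self.name}: obs_rate_per_min must be > 0")


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 500
    surgeries_per_patient_rate: float = 0.15  # extra surgeries ~ Poisson(rate)
    prevalence_target: float = 0.085
    surgery_length_mean_min: float = 150.0
    surgery_length_sd_min: float = 50.0
    surgery_length_min_min: float = 100.0
    surgery_length_max_min: float = 480.0
    features: tuple[FeatureSim, ...] = ()
    static_effects: dict = field(default_factory=dict)  # static name -> mean shift
    patient_intercept_sd: float = 0.3
    slope_center_min: float | None = None  # center of applied trends (mean-matching)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth for recovery tests: latent class and intercept per
    surgery, plus the effect sizes that were applied."""

    surgery_ids: list
    patient_ids: list
    y: list
    patient_intercepts: dict
    effects: dict  # feature -> {delta_mean, delta_slope_per_min, delta_log_obs_rate}

    def to_json(self) -> str:
        d = asdict(self)
        d["surgery_ids"] = [str(s) for s in d["surgery_ids"]]
        d["patient_ids"] = [str(p) for p in d["patient_ids"]]
        d["patient_intercepts"] = {str(k): v for k, v in d["patient_intercepts"].items()}
        return json.dumps(d, indent=1)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """A small realistic feature menu: blood pressure, heart rate, oxygen
    saturation, an opioid infusion rate, and an EEG sedation index."""
    features = (
        FeatureSim("ibp_sys", 120.0, 15.0, 0.9, 1 / 3, 2.0, delta_mean=6.0),
        FeatureSim("hr", 75.0, 10.0, 0.9, 1 / 3, 1.0),
        FeatureSim("spo2", 97.0, 1.5, 0.8, 1 / 3, 0.5),
        FeatureSim("in_rt_remif", 0.1, 0.03, 0.85, 1 / 5, 0.005, delta_mean=0.012),
        FeatureSim("psi", 40.0, 8.0, 0.9, 1 / 3, 1.0, delta_log_obs_rate=0.4),
    )
    cfg = dict(
        n_patients=500,
        prevalence_target=0.085,
        features=features,
        static_effects={"age": 7.0, "asa": 1},
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def simulated_feature_specs(config: SimConfig) -> list[FeatureSpec]:
    """Feature-specification table matching the generated cohort."""
    specs = [
        FeatureSpec(f.name, domain="vital_signs", time_variance="dynamic",
                    missing_indicator=True)
        for f in config.features
    ]
    specs.append(FeatureSpec("age", domain="demographics", time_variance="static"))
    specs.append(FeatureSpec("asa", domain="scores", time_variance="static"))
    specs.append(FeatureSpec("op_length_min", domain="scores", time_variance="static"))
    return specs


def _stream(seed: int, kind: int, index: int) -> np.random.Generator:
    # counter-based stream: entity `index` is independent of cohort size
    return np.random.Generator(
        np.random.Philox(key=np.uint64(seed), counter=(kind << 56) | index)
    )


def _latent_path(rng, length: int, mean: float, sd: float, phi: float) -> np.ndarray:
    eps_sd = sd * np.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, eps_sd, size=length)
    path = np.empty(length)
    x = rng.normal(0.0, sd)
    for t in range(length):
        x = phi * x + shocks[t]
        path[t] = x
    return mean + path


def generate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (events, statics, nudesc, truth); reproducible by seed."""
    seed = config.seed if seed is None else seed

    # patients, surgeries, class assignment — every patient and surgery owns
    # a counter-based stream, so growing the cohort never perturbs earlier
    # entities
    patient_ids = [f"p{i:05d}" for i in range(config.n_patients)]
    intercepts = {}
    surgeries: list[tuple[str, str, int]] = []  # (surgery_id, patient_id, counter)
    for i, p in enumerate(patient_ids):
        prng = _stream(seed, 1, i)
        intercepts[p] = float(prng.normal(0.0, config.patient_intercept_sd))
        n_surg = 1 + int(prng.poisson(config.surgeries_per_patient_rate))
        for j in range(n_surg):
            surgeries.append((f"{p}_s{j}", p, (i << 8) | j))
    m = len(surgeries)

    y = np.empty(m, dtype=int)
    lengths = np.empty(m)
    for idx, (_sid, _pid, counter) in enumerate(surgeries):
        srng = _stream(seed, 2, counter)
        y[idx] = int(srng.random() < config.prevalence_target)
        lengths[idx] = np.clip(
            srng.normal(config.surgery_length_mean_min, config.surgery_length_sd_min),
            config.surgery_length_min_min,
            config.surgery_length_max_min,
        )
    if y.sum() == 0:
        warnings.warn("no POD-positive surgeries drawn; increase n or prevalence")

    event_rows = []
    nudesc_rows = []
    static_rows = []
    for idx, ((sid, pid, counter), label) in enumerate(zip(surgeries, y)):
        srng = _stream(seed, 3, counter)
        length = float(lengths[idx])
        n_min = int(np.ceil(length))
        b = intercepts[pid]
        center = (
            config.slope_center_min
            if config.slope_center_min is not None
            else length / 2.0
        )
        for f in config.features:
            mean = f.baseline_mean + b * f.baseline_sd
            if label:
                mean += f.delta_mean
            path = _latent_path(srng, n_min, mean, f.baseline_sd, f.ar1_coef)
            if label and f.delta_slope_per_min:
                trend = f.delta_slope_per_min * f.baseline_sd * (
                    np.arange(n_min) - center
                )
                path = path + trend
            rate = f.obs_rate_per_min * (
                np.exp(f.delta_log_obs_rate) if label else 1.0
            )
            n_obs = srng.poisson(rate * length)
            if n_obs == 0:
                continue
            times = np.sort(srng.uniform(0.0, length, size=n_obs))
            vals = path[np.minimum(times.astype(int), n_min - 1)]
            vals = vals + srng.normal(0.0, f.noise_sd, size=n_obs)
            for t, v in zip(times, vals):
                event_rows.append((sid, pid, f.name, float(t), float(v)))

        # statics: age, ASA class, anesthesia length
        age = 55.0 + 15.0 * srng.standard_normal()
        if label:
            age += config.static_effects.get("age", 0.0)
        asa_shift = config.static_effects.get("asa", 0.0) if label else 0.0
        asa = int(np.clip(srng.poisson(2.0) + round(asa_shift), 1, 5))
        static_rows.append(
            {
                "surgery_id": sid,
                "patient_id": pid,
                "age": float(np.clip(age, 18, 100)),
                "asa": asa,
                "op_length_min": length,
            }
        )

        # Nu-DESC in the recovery room: positives guaranteed a score >= 1
        n_assess = 1 + srng.poisson(0.2)
        for a in range(n_assess):
            t_assess = float(30.0 + 30.0 * srng.random())
            cats = np.zeros(5, dtype=int)
            if label:
                cats = srng.binomial(2, 0.25, size=5)
                if cats.sum() == 0:
                    cats[srng.integers(5)] = 1
            nudesc_rows.append(
                {
                    "surgery_id": sid,
                    "assess_time_min": t_assess,
                    **{c: int(v) for c, v in zip(NUDESC_CATEGORIES, cats)},
                }
            )

    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    statics = pd.DataFrame(static_rows)
    nudesc = pd.DataFrame(
        nudesc_rows, columns=["surgery_id", "assess_time_min", *NUDESC_CATEGORIES]
    )
    truth = SimTruth(
        surgery_ids=[s for s, _, _ in surgeries],
        patient_ids=[p for _, p, _ in surgeries],
        y=[int(v) for v in y],
        patient_intercepts=intercepts,
        effects={
            f.name: {
                "delta_mean": f.delta_mean,
                "delta_slope_per_min": f.delta_slope_per_min,
                "delta_log_obs_rate": f.delta_log_obs_rate,
            }
            for f in config.features
        },
    )
    return events, statics, nudesc, truth


def make_mean_matched_slope_cohort(
    config: SimConfig | None = None,
    seed: int = 0,
    signal_feature: str = "ibp_sys",
    window_min: tuple[float, float] = (0.0, 30.0),
    delta_slope_sd_per_window: float = 1.25,
    n_patients: int = 500,
    signal_ar1: float = 0.5,
    signal_obs_rate_per_min: float = 1.0,
    signal_noise_sd_factor: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Cohort in which classes differ *only* in the within-window slope of one
    feature; the window mean is matched between classes by centering the
    trend on the window midpoint.

    This is the test bed for the claim that temporal patterns carry signal
    that time-aggregated summaries lose: a per-surgery least-squares slope
    separates the classes while the window mean does not.  So that the slope
    is identifiable at all, the construction observes the signal feature
    densely (one observation per minute on average) and gives it weak
    autocorrelation: strong AR(1) memory produces spurious within-window
    drift that mimics the class signal, and sparse observation leaves a
    third of the grid bins to imputation.  All class effects on means,
    observation rates and statics are zeroed.
    """
    lo, hi = window_min
    if hi - lo < 2.0:
        raise ValueError("window shorter than 2 sampling intervals")
    slope_per_min = delta_slope_sd_per_window / (hi - lo)
    base = config or default_config(seed=seed, n_patients=n_patients)
    features = []
    found = False
    for f in base.features:
        if f.name == signal_feature:
            found = True
            noise_sd = (
                f.noise_sd
                if signal_noise_sd_factor is None
                else signal_noise_sd_factor * f.baseline_sd
            )
            f = FeatureSim(
                f.name, f.baseline_mean, f.baseline_sd, signal_ar1,
                signal_obs_rate_per_min, noise_sd,
                delta_mean=0.0,
                delta_slope_per_min=slope_per_min,
                delta_log_obs_rate=0.0,
            )
        else:
            f = FeatureSim(
                f.name, f.baseline_mean, f.baseline_sd, f.ar1_coef,
                f.obs_rate_per_min, f.noise_sd,
            )
        features.append(f)
    if not found:
        raise ValueError(f"signal feature {signal_feature!r} not in feature menu")
    cfg = SimConfig(
        n_patients=base.n_patients,
        surgeries_per_patient_rate=base.surgeries_per_patient_rate,
        prevalence_target=base.prevalence_target,
        surgery_length_mean_min=base.surgery_length_mean_min,
        surgery_length_sd_min=base.surgery_length_sd_min,
        surgery_length_min_min=base.surgery_length_min_min,
        surgery_length_max_min=base.surgery_length_max_min,
        features=tuple(features),
        static_effects={},
        patient_intercept_sd=base.patient_intercept_sd,
        slope_center_min=(lo + hi) / 2.0,
        seed=seed,
    )
    return generate_cohort(cfg, seed)


def write_cohort(out_dir, events, statics, nudesc, truth: SimTruth) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events.to_csv(out / "events.csv", index=False)
    statics.to_csv(out / "statics.csv", index=False)
    nudesc.to_csv(out / "nudesc.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
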