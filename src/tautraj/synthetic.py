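"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Each subject carries a latent progression score theta drawn from a
class-conditional normal (Clinically Stable centred at 0, Clinically
Declining at 1, Alzheimer's Clinical Syndrome at 1.8).  Baseline features
are noisy linear readouts of theta: cortical amyloid in centiloids
(bimodal across classes by construction), a declining medial-temporal
grey-matter density score, and an APOE4 carrier flag with
progression-linked prevalence.  Longitudinal tau follows ROI-specific
linear links: the subject's true annualized rate in ROI r is

    rate_r = b0_r + b1_r * theta + rate noise,

with positive b1 only in the temporal/parietal ROIs that accumulate tau
early in AD and a small negative drift (b0) elsewhere, emulating the
regional specificity of tau accumulation; observed SUVR at scan time t is
baseline_r(theta) + rate_r * t + measurement noise over a realistic scan
schedule (2-4 scans about 1.2 +/- 0.4 years apart).  PACC declines at
-gamma * theta points/year.

All defaults are declared test fixtures emulating the published group
separation and effect regimes, not estimates of any real cohort; identical
config + seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .roi import HIGH_SLOPE_ROIS, default_roi_list
from .tables import CLASS_ACS, CLASS_DECLINING, CLASS_STABLE

__all__ = ["RoiLaw", "SyntheticConfig", "SyntheticCohort", "generate_cohort",
           "truth_report", "default_roi_laws"]


@dataclass(frozen=True)
class RoiLaw:
    """Linear links from latent progression theta to one ROI's tau signal.

    ``baseline_intercept + baseline_slope * theta`` is the expected SUVR at
    the first scan; ``rate_intercept + rate_slope * theta`` is the expected
    annualized accumulation rate (SUVR/yr).
    """

    baseline_intercept: float
    baseline_slope: float
    rate_intercept: float
    rate_slope: float


def default_roi_laws() -> dict[str, RoiLaw]:
    """Positive progression->rate slope only in the early-accumulating
    temporal/parietal set; every ROI shares a small negative drift
    (reference-region and tracer washout effects pull measured cortical
    SUVR slightly down in the absence of disease accumulation)."""
    laws = {}
    for roi in default_roi_list():
        if roi in HIGH_SLOPE_ROIS:
            laws[roi] = RoiLaw(1.20, 0.15, -0.003, 0.03)
        else:
            laws[roi] = RoiLaw(1.10, 0.02, -0.003, 0.0)
    return laws


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_stable: int = 250
    n_declining: int = 250
    n_acs: int = 250
    seed: int = 0
    #: per-class (mean, sd) of latent progression theta
    theta_params: dict = field(default_factory=lambda: {
        CLASS_STABLE: (0.0, 0.2),
        CLASS_DECLINING: (1.0, 0.35),
        CLASS_ACS: (1.8, 0.4),
    })
    #: amyloid centiloids = a0 + a1 * theta + N(0, sd)
    amyloid_params: tuple = (10.0, 55.0, 15.0)
    amyloid_clip: tuple = (-30.0, 220.0)
    #: grey-matter density = g0 - g1 * theta + N(0, sd)
    gm_params: tuple = (0.60, 0.15, 0.05)
    #: P(APOE4 carrier) = logistic(b0 + b1 * theta)
    apoe_params: tuple = (-1.0, 1.5)
    roi_laws: dict = field(default_factory=default_roi_laws)
    rate_noise_sd: float = 0.02         # SUVR/yr around the linear rate law
    measurement_noise_sd: float = 0.01  # SUVR per scan
    #: (n_scans range inclusive, mean interval yr, interval sd yr)
    scan_schedule: tuple = ((2, 4), 1.2, 0.4)
    min_interval_yr: float = 0.3
    #: PACC rate = -gamma * theta + N(0, sd) points/yr
    pacc_params: tuple = (0.5, 0.3)
    pacc_measurement_sd: float = 0.5
    cohort_name: str = "synthetic"

    def class_counts(self) -> dict[str, int]:
        return {CLASS_STABLE: self.n_stable, CLASS_DECLINING: self.n_declining,
                CLASS_ACS: self.n_acs}

    def validate(self) -> None:
        counts = self.class_counts()
        if any(n < 0 for n in counts.values()):
            raise ValueError("class counts must be nonnegative")
        if sum(counts.values()) <= 0:
            raise ValueError("total cohort size must be positive")
        for name, (_, sd) in self.theta_params.items():
            if sd < 0:
                raise ValueError(f"negative theta sd for class {name}")
        for label, sd in [("amyloid", self.amyloid_params[2]),
                          ("gm", self.gm_params[2]),
                          ("rate", self.rate_noise_sd),
                          ("measurement", self.measurement_noise_sd),
                          ("pacc rate", self.pacc_params[1]),
                          ("pacc measurement", self.pacc_measurement_sd),
                          ("scan interval", self.scan_schedule[2])]:
            if sd < 0:
                raise ValueError(f"negative {label} noise sd")
        if not self.roi_laws:
            raise ValueError("roi_laws must not be empty")
        lo, hi = self.scan_schedule[0]
        if not (2 <= lo <= hi):
            raise ValueError("scan count range must start at >= 2 scans")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """Generated cohort: baseline table, longitudinal series, and the
    generating truth (latent theta and true rates) for validation."""

    cohort_table: pd.DataFrame
    series: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(config: SyntheticConfig, roi_list=None) -> SyntheticCohort:
    """Draw a seeded synthetic cohort under the configured linear-Gaussian
    progression model.

    Raises if the config is invalid or ``roi_laws`` does not cover the
    configured ROI list (the offending ROI is named).
    """
    config.validate()
    if roi_list is None:
        roi_list = list(config.roi_laws)
    for roi in roi_list:
        if roi not in config.roi_laws:
            raise ValueError(f"roi_laws missing ROI {roi!r}")

    rng = np.random.default_rng(config.seed)
    labels, thetas = [], []
    for cls, n in config.class_counts().items():
        mean, sd = config.theta_params[cls]
        thetas.append(mean + sd * rng.standard_normal(n))
        labels += [cls] * n
    theta = np.concatenate(thetas)
    labels = np.asarray(labels)
    n_total = len(theta)
    subject_ids = np.array([f"S{i:04d}" for i in range(n_total)])

    a0, a1, a_sd = config.amyloid_params
    amyloid = a0 + a1 * theta + a_sd * rng.standard_normal(n_total)
    n_clipped = int(np.sum((amyloid < config.amyloid_clip[0])
                           | (amyloid > config.amyloid_clip[1])))
    amyloid = np.clip(amyloid, *config.amyloid_clip)

    g0, g1, g_sd = config.gm_params
    gm = g0 - g1 * theta + g_sd * rng.standard_normal(n_total)

    b0, b1 = config.apoe_params
    apoe = (rng.random(n_total) < _logistic(b0 + b1 * theta)).astype(int)

    # baseline syndromic diagnosis, weakly linked to progression so that
    # agreement with the biomarker stratification stays near chance
    mci = rng.random(n_total) < _logistic(-0.85 + 0.3 * theta)
    baseline_dx = np.where(mci, "MCI", "CN")

    cohort_table = pd.DataFrame({
        "subject_id": subject_ids,
        "cohort": config.cohort_name,
        "amyloid_centiloid": amyloid,
        "mtl_gm_density": gm,
        "apoe4": apoe,
        "class_label": labels,
        "baseline_dx": baseline_dx,
    })
    cohort_table.attrs["n_amyloid_clipped"] = n_clipped

    # scan schedules: cumulative times from 0
    (lo, hi), mean_iv, sd_iv = config.scan_schedule
    n_scans = rng.integers(lo, hi + 1, size=n_total)
    times = []
    for i in range(n_total):
        ivs = np.maximum(mean_iv + sd_iv * rng.standard_normal(n_scans[i] - 1),
                         config.min_interval_yr)
        times.append(np.concatenate([[0.0], np.cumsum(ivs)]))

    truth_rates = {}
    series_rows = []
    for roi in roi_list:
        law = config.roi_laws[roi]
        true_rate = (law.rate_intercept + law.rate_slope * theta
                     + config.rate_noise_sd * rng.standard_normal(n_total))
        baseline = law.baseline_intercept + law.baseline_slope * theta
        truth_rates[roi] = true_rate
        for i in range(n_total):
            t = times[i]
            vals = (baseline[i] + true_rate[i] * t
                    + config.measurement_noise_sd * rng.standard_normal(len(t)))
            for tt, vv in zip(t, vals):
                series_rows.append((subject_ids[i], roi, tt, vv))

    gamma, pacc_sd = config.pacc_params
    pacc_rate = -gamma * theta + pacc_sd * rng.standard_normal(n_total)
    for i in range(n_total):
        t = times[i]
        vals = pacc_rate[i] * t + config.pacc_measurement_sd * rng.standard_normal(len(t))
        for tt, vv in zip(t, vals):
            series_rows.append((subject_ids[i], "PACC", tt, vv))

    series = pd.DataFrame(series_rows,
                          columns=["subject_id", "measure", "time_yr", "value"])

    truth = pd.DataFrame({"subject_id": subject_ids, "theta": theta,
                          **{f"rate_{roi}": truth_rates[roi] for roi in roi_list},
                          "rate_PACC": pacc_rate})
    return SyntheticCohort(cohort_table, series, truth, config)


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-subject latent theta and true rates, aligned to subject ids.

    Intended for validation against estimates; not part of the analysis
    path.
    """
    return cohort.truth.set_index("subject_id")
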