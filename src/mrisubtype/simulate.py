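"""Synthetic two-arm, two-visit MCI trial cohorts.

The generator emulates the tabular structure of a 12-month randomized
donepezil-vs-placebo trial in amnestic MCI: per-visit Desikan regional
morphometry, totals and ICV, visual-rating scores, cognitive scores and
demographics, all io_schema-conformant.

Generative model, per subject i:

* two latent dimensions (severity z, typicality z), bivariate Gaussian with
  configurable correlation (default 0);
* baseline volumes/thicknesses are drawn around realistic regional means,
  scaled partially by ICV and modulated by the latents so that low severity z
  gives a globally low BV/CSF index and low typicality z gives a relatively
  small hippocampus;
* the true annualized atrophy rate of each MRI efficacy measure m is the
  linear predictor

      rate_m(i) = base_m + g_sev,m (sev_i - ref_sev) + g_typ,m (typ_i - ref_typ)
                  + g_age,m (age_i - ref_age) + eps_i
                  + arm_i (main_m + b_sev,m sev_i + b_typ,m typ_i)

  where sev_i and typ_i are the subject's *realized* baseline BV/CSF index
  and hippocampus-to-cortex ratio (computed from the generated baseline
  table), so a regression of the measured APC on the measured dimensions
  recovers the injected coefficients without attenuation;
* follow-up value = baseline x (1 + rate/100 x interval/365) + measurement
  noise; the MRI interval is near 12 months for most subjects with a
  configurable fraction (default 10%) uniform in 6-11 months;
* visual ratings are monotone noisy transforms of the relevant regional
  atrophy (MTA from hippocampal volume, PA/GCA-F from the cortical latents),
  clipped to their scale bounds;
* every generated subject satisfies the trial's inclusion screen (amnestic
  FCSRT deficit, CDR 0.5, MMSE > 24, age in (50, 94]).

Defaults mirror the published trial's baseline table (age 73.8 (6.6) years,
26% 3T scanners, hippocampus 6270 (905) mm3, BV/CSF 28.9 (12.9), ...) and
its reported interaction coefficients as the injected treatment effects.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import AnalysisConfig, HEMISPHERES, default_config
from .derive import compute_bv_csf_index, compute_hc_ratio
from .io_schema import (
    Cohort,
    cohort_from_frames,
    cortical_thk_col,
    cortical_vol_col,
    subcortical_vol_col,
)

logger = logging.getLogger(__name__)

MEASURES = ("hippocampus", "ventricles", "gray_matter", "ad_signature")

# typical per-hemisphere Desikan volumes (mm3) and thicknesses (mm)
REGION_BASE_VOLUME = {
    "bankssts": 2500.0, "caudalanteriorcingulate": 2000.0, "caudalmiddlefrontal": 6500.0,
    "cuneus": 3000.0, "entorhinal": 1800.0, "frontalpole": 1000.0, "fusiform": 9500.0,
    "inferiorparietal": 13000.0, "inferiortemporal": 10500.0, "insula": 6500.0,
    "isthmuscingulate": 2500.0, "lateraloccipital": 11000.0, "lateralorbitofrontal": 7500.0,
    "lingual": 6500.0, "medialorbitofrontal": 5000.0, "middletemporal": 10000.0,
    "paracentral": 3500.0, "parahippocampal": 2000.0, "parsopercularis": 4500.0,
    "parsorbitalis": 2000.0, "parstriangularis": 3500.0, "pericalcarine": 2000.0,
    "postcentral": 9500.0, "posteriorcingulate": 3000.0, "precentral": 12500.0,
    "precuneus": 9500.0, "rostralanteriorcingulate": 2500.0, "rostralmiddlefrontal": 16000.0,
    "superiorfrontal": 21000.0, "superiorparietal": 12500.0, "superiortemporal": 11500.0,
    "supramarginal": 10000.0, "temporalpole": 2200.0, "transversetemporal": 1000.0,
}
REGION_BASE_THICKNESS = {
    "bankssts": 2.4, "caudalanteriorcingulate": 2.6, "caudalmiddlefrontal": 2.5,
    "cuneus": 1.8, "entorhinal": 3.3, "frontalpole": 2.7, "fusiform": 2.7,
    "inferiorparietal": 2.4, "inferiortemporal": 2.7, "insula": 3.0,
    "isthmuscingulate": 2.4, "lateraloccipital": 2.1, "lateralorbitofrontal": 2.6,
    "lingual": 1.9, "medialorbitofrontal": 2.4, "middletemporal": 2.8,
    "paracentral": 2.3, "parahippocampal": 2.7, "parsopercularis": 2.5,
    "parsorbitalis": 2.6, "parstriangularis": 2.4, "pericalcarine": 1.6,
    "postcentral": 2.0, "posteriorcingulate": 2.4, "precentral": 2.5,
    "precuneus": 2.3, "rostralanteriorcingulate": 2.8, "rostralmiddlefrontal": 2.3,
    "superiorfrontal": 2.7, "superiorparietal": 2.1, "superiortemporal": 2.7,
    "supramarginal": 2.5, "temporalpole": 3.6, "transversetemporal": 2.3,
}

# regions receiving structured latent signal; everything else gets calibrated noise
TYPICALITY_PARTS = ("caudalmiddlefrontal", "rostralmiddlefrontal", "inferiorparietal", "superiortemporal")
SIGNATURE_PARTS = ("entorhinal", "inferiortemporal", "middletemporal", "fusiform")


def _m(**kw) -> dict:
    out = {m: 0.0 for m in MEASURES}
    out.update(kw)
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the generator; defaults are the emulated trial's conditions."""

    n_subjects: int = 173
    arm_ratio: float = 83.0 / 173.0  # fraction randomized to donepezil
    seed: int = 0

    # demographics
    age_mean: float = 73.8
    age_sd: float = 6.6
    age_range: tuple[float, float] = (51.0, 94.0)  # rating cut-point support, age > 50 at entry
    female_fraction: float = 0.52
    education_probs: tuple[float, ...] = (0.006, 0.075, 0.42, 0.21, 0.289)
    field_strength_3t: float = 0.26

    # latent dimensions
    latent_correlation: float = 0.0
    severity_mean: float = 28.9
    severity_sd: float = 12.9
    severity_min: float = 6.0

    # head size and baseline morphometry
    icv_mean: float = 1.45e6
    icv_sd: float = 1.3e5
    icv_coupling: float = 0.5  # fraction of relative ICV deviation passed to volumes
    gm_mean: float = 552000.0
    gm_sd: float = 24000.0
    gm_severity_sd: float = 20000.0
    wm_mean: float = 455000.0
    wm_sd: float = 20000.0
    wm_severity_sd: float = 10000.0
    hippocampus_mean: float = 6270.0
    hippocampus_rel_sd: float = 0.06
    hippocampus_typ_loading: float = 0.0975  # 0.13 * 0.75
    hippocampus_sev_loading: float = 0.0455  # 0.13 * 0.35
    ventricle_mean: float = 36600.0
    ventricle_log_sd: float = 0.37
    ventricle_sev_loading: float = -0.45
    cortical_rel_sd: float = 0.05
    cortical_sev_loading: float = 0.05
    cortical_typ_loading: float = -0.03
    thickness_sd: float = 0.08
    signature_sev_loading: float = 0.04
    signature_typ_loading: float = -0.02

    # annual atrophy rates (%/year) of the efficacy measures
    reference_severity: float = 28.9
    reference_typicality: float = 0.2
    reference_age: float = 73.8
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=-1.8, ventricles=5.0, gray_matter=-0.7, ad_signature=-1.0))
    severity_slope: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=0.1, ventricles=-0.1, gray_matter=0.04, ad_signature=0.01))
    typicality_slope: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=-17.7, ventricles=61.8, gray_matter=4.6, ad_signature=-71.7))
    age_slope: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=-0.03, ventricles=-0.04, gray_matter=-0.1, ad_signature=-0.1))
    rate_sd: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=1.0, ventricles=3.0, gray_matter=0.5, ad_signature=0.6))

    # injected treatment effects (%/year, and %/year per unit dimension)
    treatment_main: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=-2.0, ventricles=8.9, gray_matter=2.5, ad_signature=-2.2))
    treatment_severity: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=0.01, ventricles=-0.1, gray_matter=0.1, ad_signature=0.11))
    treatment_typicality: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=25.2, ventricles=-101.8, gray_matter=-27.7, ad_signature=16.4))

    # follow-up measurement noise (per measured column, absolute units)
    measurement_noise: Mapping[str, float] = field(
        default_factory=lambda: _m(hippocampus=21.0, ventricles=106.0, gray_matter=1500.0, ad_signature=0.034))
    noise_scale: float = 1.0  # global multiplier on measurement/rate/rating noise

    # background change of columns without structured signal
    other_region_rate: float = -0.5
    other_region_rate_sd: float = 0.5
    other_noise_frac: float = 0.004
    wm_rate: float = -0.3
    csf_rate: float = 2.0

    # MRI interval: most scans near 12 months, a fraction earlier (6-11 months)
    early_fraction: float = 0.10
    early_range_days: tuple[float, float] = (183.0, 334.0)
    interval_mean_days: float = 357.0
    interval_sd_days: float = 14.0
    interval_range_days: tuple[float, float] = (336.0, 395.0)

    # visual-rating links (monotone in the relevant atrophy, before noise)
    mta_intercept: float = 1.45
    mta_deficit_slope: float = 0.55  # per SD of hippocampal deficit
    mta_age_slope: float = 0.015
    mta_noise: float = 0.45
    mta_side_noise: float = 0.25
    pa_intercept: float = 0.45
    pa_severity_slope: float = -0.25
    pa_typicality_slope: float = 0.15
    pa_noise: float = 0.35
    gcaf_intercept: float = 0.40
    gcaf_severity_slope: float = -0.22
    gcaf_typicality_slope: float = 0.10
    gcaf_noise: float = 0.33

    # cognitive scores: test -> (baseline mean, baseline sd, annual change %,
    # change sd %, treatment effect on change %, lower clip, upper clip)
    cognitive: Mapping[str, tuple] = field(default_factory=lambda: {
        "mmse": (26.0, 1.5, -3.0, 8.0, 0.0, 18.0, 30.0),
        "adas_cog_mci": (12.0, 4.2, 8.0, 15.0, 0.0, 1.0, 70.0),
        "tmt_a": (62.0, 29.0, 6.0, 15.0, 0.0, 10.0, 400.0),
        "tmt_b": (150.0, 62.0, 6.0, 15.0, 0.0, 20.0, 600.0),
        "benton": (7.0, 2.0, -3.0, 12.0, 0.0, 1.0, 12.0),
        "isaacs_15": (24.8, 5.2, -3.0, 10.0, 0.0, 5.0, 60.0),
        "isaacs_60": (50.0, 11.0, -3.0, 10.0, 0.0, 10.0, 120.0),
    })

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if not 0.0 <= self.arm_ratio <= 1.0:
            raise ValueError("arm_ratio must be in [0, 1]")
        if not -1.0 < self.latent_correlation < 1.0:
            raise ValueError("latent_correlation must be in (-1, 1)")
        for name in ("age_sd", "severity_sd", "icv_sd", "noise_scale", "early_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.early_fraction > 1.0:
            raise ValueError("early_fraction must be in [0, 1]")
        for mapping in (self.base_rates, self.severity_slope, self.typicality_slope, self.age_slope,
                        self.rate_sd, self.treatment_main, self.treatment_severity,
                        self.treatment_typicality, self.measurement_noise):
            missing = set(MEASURES) - set(mapping)
            if missing:
                raise ValueError(f"per-measure mapping missing entries: {sorted(missing)}")
        for m in MEASURES:
            if self.rate_sd[m] < 0 or self.measurement_noise[m] < 0:
                raise ValueError("noise SDs must be non-negative")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mta_link(hipp_total, age, config: SimulationConfig):
    """Expected (pre-noise) MTA score; monotone in hippocampal deficit."""
    deficit = (config.hippocampus_mean - np.asarray(hipp_total, dtype=float)) / 905.0
    return (config.mta_intercept + config.mta_deficit_slope * deficit
            + config.mta_age_slope * (np.asarray(age, dtype=float) - config.reference_age))


def generate_cohort(
    config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    validate: bool = False,
) -> Cohort:
    """Draw one full cohort. Deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    aconf = analysis_config or default_config()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ns = config.noise_scale

    ids = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    n_don = int(round(n * config.arm_ratio))
    arm = rng.permutation(np.array(["donepezil"] * n_don + ["placebo"] * (n - n_don)))
    arm01 = (arm == "donepezil").astype(float)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    edu_levels = np.array(["none", "primary", "certification_of_primary", "secondary", "higher"])
    probs = np.asarray(config.education_probs, dtype=float)
    education = edu_levels[rng.choice(5, size=n, p=probs / probs.sum())]
    field_strength = np.where(rng.random(n) < config.field_strength_3t, "3T", "1.5T")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)

    # latent dimensions
    sev_z = rng.standard_normal(n)
    rho = config.latent_correlation
    typ_z = rho * sev_z + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)

    icv = np.clip(rng.normal(config.icv_mean, config.icv_sd, n), 1.1e6, None)
    icv_f = 1.0 + config.icv_coupling * (icv / config.icv_mean - 1.0)

    severity_index = np.clip(config.severity_mean + config.severity_sd * sev_z,
                             config.severity_min, None)
    gm = (config.gm_mean + config.gm_severity_sd * sev_z + rng.normal(0.0, config.gm_sd, n)) * icv_f
    wm = (config.wm_mean + config.wm_severity_sd * sev_z + rng.normal(0.0, config.wm_sd, n)) * icv_f
    gm = np.clip(gm, 3.0e5, None)
    wm = np.clip(wm, 2.5e5, None)
    csf = (gm + wm) / severity_index  # BV/CSF index equals severity_index by construction

    hipp_total = config.hippocampus_mean * (
        1.0 + config.hippocampus_typ_loading * typ_z + config.hippocampus_sev_loading * sev_z
        + config.hippocampus_rel_sd * rng.standard_normal(n)
    ) * icv_f
    hipp_total = np.clip(hipp_total, 1500.0, None)
    asym = rng.normal(0.0, 0.01, n)
    hipp_l = hipp_total * (0.5 - asym)
    hipp_r = hipp_total * (0.5 + asym)

    vent_total = config.ventricle_mean * np.exp(
        config.ventricle_log_sd * (config.ventricle_sev_loading * sev_z
                                   + np.sqrt(1 - config.ventricle_sev_loading ** 2) * rng.standard_normal(n))
    )
    vasym = rng.normal(0.0, 0.02, n)
    vent_l = vent_total * (0.5 - vasym)
    vent_r = vent_total * (0.5 + vasym)

    # baseline cortical columns (volumes, then thicknesses)
    regions = aconf.cortical_regions
    vol_noise = rng.standard_normal((n, len(regions) * 2))
    thk_noise = rng.standard_normal((n, len(regions) * 2))
    cort_vol = {}
    cort_thk = {}
    for j, region in enumerate(regions):
        structured = region in TYPICALITY_PARTS
        sig = region in SIGNATURE_PARTS
        base_v = REGION_BASE_VOLUME[region]
        base_t = REGION_BASE_THICKNESS[region]
        for h, hemi in enumerate(HEMISPHERES):
            z = vol_noise[:, 2 * j + h]
            mod = 1.0 + config.cortical_rel_sd * z
            if structured:
                mod = mod + config.cortical_sev_loading * sev_z + config.cortical_typ_loading * typ_z
            else:
                mod = mod + 0.03 * sev_z
            cort_vol[(region, hemi)] = np.clip(base_v * mod * icv_f, base_v * 0.3, None)
            tz = thk_noise[:, 2 * j + h]
            tmod = base_t + config.thickness_sd * tz
            if sig:
                tmod = tmod + base_t * (config.signature_sev_loading * sev_z
                                        + config.signature_typ_loading * typ_z)
            cort_thk[(region, hemi)] = np.clip(tmod, 0.8, None)

    # realized baseline dimensions drive the true rates
    sev_dim = np.asarray(compute_bv_csf_index(gm, wm, csf))
    typ_regions = {
        name: (sum(cort_vol[(p, "left")] for p in parts), sum(cort_vol[(p, "right")] for p in parts))
        for name, parts in aconf.typicality_regions.items()
    }
    typ_dim = np.asarray(compute_hc_ratio(hipp_l, hipp_r, typ_regions))

    # MRI interval
    early = rng.random(n) < config.early_fraction
    d_early = rng.uniform(*config.early_range_days, n)
    d_main = np.clip(rng.normal(config.interval_mean_days, config.interval_sd_days, n),
                     *config.interval_range_days)
    interval = np.where(early, d_early, d_main).round().astype(int)
    interval = np.maximum(interval, 1)

    rate = {}
    for m in MEASURES:
        rate[m] = (
            config.base_rates[m]
            + config.severity_slope[m] * (sev_dim - config.reference_severity)
            + config.typicality_slope[m] * (typ_dim - config.reference_typicality)
            + config.age_slope[m] * (age - config.reference_age)
            + ns * config.rate_sd[m] * rng.standard_normal(n)
            + arm01 * (config.treatment_main[m]
                       + config.treatment_severity[m] * sev_dim
                       + config.treatment_typicality[m] * typ_dim)
        )
    growth = {m: 1.0 + rate[m] / 100.0 * interval / 365.0 for m in MEASURES}

    def noisy(x, sd):
        return x + ns * sd * rng.standard_normal(n)

    hipp_l2 = np.clip(noisy(hipp_l * growth["hippocampus"], config.measurement_noise["hippocampus"]), 1.0, None)
    hipp_r2 = np.clip(noisy(hipp_r * growth["hippocampus"], config.measurement_noise["hippocampus"]), 1.0, None)
    vent_l2 = np.clip(noisy(vent_l * growth["ventricles"], config.measurement_noise["ventricles"]), 1.0, None)
    vent_r2 = np.clip(noisy(vent_r * growth["ventricles"], config.measurement_noise["ventricles"]), 1.0, None)
    gm2 = np.clip(noisy(gm * growth["gray_matter"], config.measurement_noise["gray_matter"]), 1.0, None)
    wm2 = wm * (1.0 + config.wm_rate / 100.0 * interval / 365.0)
    csf2 = csf * (1.0 + config.csf_rate / 100.0 * interval / 365.0)

    other_rate = (config.other_region_rate
                  + ns * config.other_region_rate_sd * rng.standard_normal(n))
    other_growth = 1.0 + other_rate / 100.0 * interval / 365.0
    fup_vol_noise = rng.standard_normal((n, len(regions) * 2))
    fup_thk_noise = rng.standard_normal((n, len(regions) * 2))
    cort_vol2, cort_thk2 = {}, {}
    for j, region in enumerate(regions):
        sig = region in SIGNATURE_PARTS
        for h, hemi in enumerate(HEMISPHERES):
            v = cort_vol[(region, hemi)] * other_growth
            v = v + ns * config.other_noise_frac * REGION_BASE_VOLUME[region] * fup_vol_noise[:, 2 * j + h]
            cort_vol2[(region, hemi)] = np.clip(v, 1.0, None)
            t = cort_thk[(region, hemi)]
            g = growth["ad_signature"] if sig else other_growth
            t = t * g + ns * (config.measurement_noise["ad_signature"] if sig else 0.01) \
                * fup_thk_noise[:, 2 * j + h]
            cort_thk2[(region, hemi)] = np.clip(t, 0.5, None)

    # visual ratings (baseline), monotone links plus clipped Gaussian noise
    mta_center = _mta_link(hipp_total, age, config) + ns * config.mta_noise * rng.standard_normal(n)
    mta_left = np.clip(mta_center + ns * config.mta_side_noise * rng.standard_normal(n), 0.0, 4.0)
    mta_right = np.clip(mta_center + ns * config.mta_side_noise * rng.standard_normal(n), 0.0, 4.0)
    pa = np.clip(config.pa_intercept + config.pa_severity_slope * sev_z
                 + config.pa_typicality_slope * typ_z
                 + ns * config.pa_noise * rng.standard_normal(n), 0.0, 3.0)
    gcaf = np.clip(config.gcaf_intercept + config.gcaf_severity_slope * sev_z
                   + config.gcaf_typicality_slope * typ_z
                   + ns * config.gcaf_noise * rng.standard_normal(n), 0.0, 3.0)

    # eligibility fields: all generated subjects pass the screen
    fcsrt_free = np.clip(np.round(rng.normal(11.0, 4.0, n)), 0, 17)
    fcsrt_total = np.clip(np.round(rng.normal(30.0, 8.0, n)), 5, 48)
    cdr = np.full(n, 0.5)
    mmse_screen = np.clip(np.round(rng.normal(26.2, 1.8, n)), 25, 30)

    clinical = {
        "subject_id": ids, "age_baseline": age, "sex": sex, "education": education,
        "arm": arm, "fcsrt_free_recall": fcsrt_free, "fcsrt_total_recall": fcsrt_total,
        "cdr": cdr, "mmse": mmse_screen, "mta_left": mta_left, "mta_right": mta_right,
        "pa": pa, "gcaf": gcaf,
        "hamilton": np.clip(np.round(rng.normal(3.0, 2.7, n)), 0, 20),
    }
    for test, (mu, sd, annual, change_sd, tx, lo, hi) in config.cognitive.items():
        b = np.clip(rng.normal(mu, sd, n), lo, hi)
        pct = annual + arm01 * tx + ns * change_sd * rng.standard_normal(n)
        f = np.clip(b * (1.0 + pct / 100.0), lo, hi)
        clinical[f"{test}_baseline"] = b
        clinical[f"{test}_followup"] = f
    clinical_df = pd.DataFrame(clinical)

    def morph_frame(visit):
        is_base = visit == "baseline"
        cols = {
            "subject_id": ids,
            "visit": np.full(n, visit),
            "scan_date_offset_days": np.zeros(n, dtype=int) if is_base else interval,
            "field_strength": field_strength,
        }
        vol = cort_vol if is_base else cort_vol2
        thk = cort_thk if is_base else cort_thk2
        for region in regions:
            for hemi in HEMISPHERES:
                cols[cortical_vol_col(region, hemi)] = vol[(region, hemi)]
        for region in regions:
            for hemi in HEMISPHERES:
                cols[cortical_thk_col(region, hemi)] = thk[(region, hemi)]
        cols[subcortical_vol_col("hippocampus", "left")] = hipp_l if is_base else hipp_l2
        cols[subcortical_vol_col("hippocampus", "right")] = hipp_r if is_base else hipp_r2
        cols[subcortical_vol_col("lateral_ventricle", "left")] = vent_l if is_base else vent_l2
        cols[subcortical_vol_col("lateral_ventricle", "right")] = vent_r if is_base else vent_r2
        cols["gm_total"] = gm if is_base else gm2
        cols["wm_total"] = wm if is_base else wm2
        cols["csf_total"] = csf if is_base else csf2
        cols["icv"] = icv
        return pd.DataFrame(cols)

    morphometry = pd.concat([morph_frame("baseline"), morph_frame("followup")], ignore_index=True)
    cohort = cohort_from_frames(morphometry, clinical_df, aconf, validate=validate)
    logger.info("simulate: generated cohort of %d subjects (seed %d)", n, config.seed)
    return cohort


def generate_null_cohort(
    config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    validate: bool = False,
) -> Cohort:
    """As :func:`generate_cohort` with every treatment-related coefficient zeroed
    (arm labels then carry no information; the type-I-error harness)."""
    config = config or SimulationConfig()
    cognitive = {t: v[:4] + (0.0,) + v[5:] for t, v in config.cognitive.items()}
    null_cfg = config.replace(
        treatment_main=_m(), treatment_severity=_m(), treatment_typicality=_m(),
        cognitive=cognitive,
    )
    return generate_cohort(null_cfg, analysis_config, validate=validate)


def scenario_amnestic_mci(config: SimulationConfig | None = None) -> SimulationConfig:
    """Preset emulating an amnestic-MCI trial population.

    The rating links and latent-dimension parameters are pinned so that,
    after categorical classification, minimal-atrophy and limbic-predominant
    are the two most frequent subtypes (the typical composition of an
    amnestic-MCI cohort selected for cued-recall memory impairment, where
    hippocampal damage dominates and global atrophy is still mild).
    """
    base = config or SimulationConfig()
    return base.replace(
        age_mean=73.8, age_sd=6.6,
        severity_mean=28.9, severity_sd=12.9,
        mta_intercept=1.45, mta_deficit_slope=0.55, mta_age_slope=0.015,
        mta_noise=0.45, mta_side_noise=0.25,
        pa_intercept=0.45, pa_severity_slope=-0.25, pa_typicality_slope=0.15, pa_noise=0.35,
        gcaf_intercept=0.40, gcaf_severity_slope=-0.22, gcaf_typicality_slope=0.10, gcaf_noise=0.33,
    )


def export_truth(config: SimulationConfig, path) -> None:
    """Write every injected parameter to JSON (for recovery checks)."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=list)
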