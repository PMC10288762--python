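"""Derived morphometric measures and treatment-efficacy outcomes.

Computes, per subject:

* the **severity** dimension: BV/CSF index = (grey + white matter volume) /
  CSF volume — lower means more global atrophy;
* the **typicality** dimension: hippocampus-to-cortex ratio = mean(L, R
  hippocampal volume) / mean over three cortical aggregates (middle frontal,
  inferior parietal, superior temporal) of their L/R mean volumes — lower
  means relatively more hippocampal (limbic-predominant-like) atrophy;
* the AD-signature cortical thickness (mean over entorhinal, inferior
  temporal, middle temporal and fusiform of the per-region L/R mean);
* head-size correction of volumes by the residual approach (value minus the
  cohort OLS slope on intracranial volume times the centred ICV);
* the annualized percentage change (APC, %/year, annualized with a 365-day
  year over the actual MRI interval) of the four MRI efficacy measures, and
  the plain percentage change (PC, %) of the cognitive scores.

Negative APC means loss of volume/thickness; ventricular expansion gives a
positive APC.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import HEMISPHERES, AnalysisConfig
from .io_schema import Cohort, cortical_thk_col, cortical_vol_col, subcortical_vol_col

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0  # annualization constant, exactly as defined

#: MRI efficacy measures (APC outcomes) in canonical order.
MRI_MEASURES = ("hippocampus", "ventricles", "gray_matter", "ad_signature")


def _asarray(x):
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# elementary formulas


def adjust_icv_residual(values, icv, fit_sample_mask=None):
    """Head-size-adjust volumes by the residual approach.

    The slope ``b`` of an OLS regression of value on ICV is estimated over the
    fit sample (all observations by default) and ``value - b * (icv -
    mean(icv over fit sample))`` is returned for every observation. Adjusted
    values are uncorrelated with ICV over the fit sample by construction.
    """
    values, icv = _asarray(values), _asarray(icv)
    if values.shape != icv.shape:
        raise ValueError("values and icv must have the same shape")
    mask = np.ones_like(values, dtype=bool) if fit_sample_mask is None else np.asarray(fit_sample_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("ICV adjustment needs a fit sample of at least 3 subjects")
    icv_fit, val_fit = icv[mask], values[mask]
    icv_mean = icv_fit.mean()
    dx = icv_fit - icv_mean
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("ICV is constant in the fit sample; adjustment slope undefined")
    b = float(dx @ (val_fit - val_fit.mean())) / sxx
    return values - b * (icv - icv_mean)


def icv_slope(values, icv, fit_sample_mask=None) -> float:
    """The OLS slope used by :func:`adjust_icv_residual` (exposed for audit)."""
    values, icv = _asarray(values), _asarray(icv)
    mask = np.ones_like(values, dtype=bool) if fit_sample_mask is None else np.asarray(fit_sample_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("ICV adjustment needs a fit sample of at least 3 subjects")
    dx = icv[mask] - icv[mask].mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("ICV is constant in the fit sample; adjustment slope undefined")
    return float(dx @ (values[mask] - values[mask].mean())) / sxx


def compute_bv_csf_index(gm_total, wm_total, csf_total):
    """(GM + WM) / CSF. Lower values indicate more atrophy."""
    gm, wm, csf = _asarray(gm_total), _asarray(wm_total), _asarray(csf_total)
    if np.any(gm <= 0) or np.any(wm <= 0):
        raise ValueError("gm_total and wm_total must be positive")
    if np.any(csf <= 0):
        raise ValueError("csf_total must be positive")
    out = (gm + wm) / csf
    return float(out) if out.ndim == 0 else out


def compute_hc_ratio(hipp_left, hipp_right, region_volumes: Mapping[str, tuple]):
    """Hippocampus-to-cortex ratio (typicality dimension).

    ``region_volumes`` maps each cortical region to its (left, right) volumes.
    The numerator is the L/R mean hippocampal volume; the denominator is the
    unweighted mean over regions of the per-region L/R means (two-level
    averaging, not a volume sum).
    """
    hl, hr = _asarray(hipp_left), _asarray(hipp_right)
    if np.any(hl <= 0) or np.any(hr <= 0):
        raise ValueError("hippocampal volumes must be positive")
    if not region_volumes:
        raise ValueError("no cortical regions supplied")
    region_means = []
    for name, (left, right) in region_volumes.items():
        l, r = _asarray(left), _asarray(right)
        if np.any(l <= 0) or np.any(r <= 0):
            raise ValueError(f"non-positive volume for region {name!r}")
        region_means.append((l + r) / 2.0)
    denom = np.mean(region_means, axis=0)
    out = ((hl + hr) / 2.0) / denom
    return float(out) if np.ndim(out) == 0 else out


def compute_ad_signature(thickness: Mapping[str, tuple]):
    """AD-signature composite: mean over regions of per-region L/R mean thickness."""
    if not thickness:
        raise ValueError("no signature regions supplied")
    region_means = []
    for name, (left, right) in thickness.items():
        l, r = _asarray(left), _asarray(right)
        if np.any(l <= 0) or np.any(r <= 0):
            raise ValueError(f"non-positive thickness for region {name!r}")
        region_means.append((l + r) / 2.0)
    out = np.mean(region_means, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def compute_apc(value_baseline, value_followup, mri_interval_days):
    """Annualized percentage change in %/year.

    ``((followup - baseline) / baseline) * (365 / interval) * 100``. Negative
    values indicate loss of volume or thickness. Values outside +/-100 %/year
    are possible (a measure more than doubling within a year) and trigger a
    warning, not an error.
    """
    b, f = _asarray(value_baseline), _asarray(value_followup)
    d = _asarray(mri_interval_days)
    if np.any(b == 0):
        raise ValueError("APC undefined for zero baseline value")
    if np.any(d <= 0):
        raise ValueError("MRI interval must be positive")
    apc = (f - b) / b * (DAYS_PER_YEAR / d) * 100.0
    if np.any(np.abs(apc) > 100.0):
        warnings.warn("APC outside [-100, 100] %/year", RuntimeWarning, stacklevel=2)
    return float(apc) if apc.ndim == 0 else apc


def compute_pc(value_baseline, value_followup):
    """Percentage change ``((followup - baseline) / baseline) * 100`` (no annualization)."""
    b, f = _asarray(value_baseline), _asarray(value_followup)
    if np.any(b == 0):
        raise ValueError("PC undefined for zero baseline value")
    out = (f - b) / b * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# cohort-level derivation


def _typicality_inputs(morph: pd.DataFrame, config: AnalysisConfig):
    hl = morph[subcortical_vol_col("hippocampus", "left")]
    hr = morph[subcortical_vol_col("hippocampus", "right")]
    regions = {}
    for name, parts in config.typicality_regions.items():
        left = sum(morph[cortical_vol_col(p, "left")] for p in parts)
        right = sum(morph[cortical_vol_col(p, "right")] for p in parts)
        regions[name] = (left, right)
    return hl, hr, regions


def _signature_inputs(morph: pd.DataFrame, config: AnalysisConfig):
    return {
        region: (morph[cortical_thk_col(region, "left")], morph[cortical_thk_col(region, "right")])
        for region in config.signature_regions
    }


def derive_measures(
    cohort: Cohort,
    adjust_icv: bool = True,
    icv_fit_mask: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Compute all derived measures and efficacy outcomes, one row per subject.

    The ICV-adjustment slope is fitted once on the baseline visit (over
    ``icv_fit_mask`` subjects if given, e.g. a control-only sample) and the
    same slope is applied at both visits, so the adjustment does not leak fit
    noise into the change scores. Subjects without a follow-up scan get NaN
    change scores and ``complete=False``.
    """
    config = cohort.config
    base = cohort.baseline
    fup = cohort.followup
    ids = cohort.subject_ids

    out = pd.DataFrame(index=ids.copy())
    out.index.name = "subject_id"

    # subtyping dimensions at baseline (ratios are self-normalizing for head size)
    out["severity"] = np.asarray(compute_bv_csf_index(base["gm_total"], base["wm_total"], base["csf_total"]))
    hl, hr, regions = _typicality_inputs(base, config)
    out["typicality"] = np.asarray(compute_hc_ratio(hl, hr, regions))

    complete = ids.isin(fup.index)
    out["complete"] = complete
    fup_aligned = fup.reindex(ids)

    # raw totals per visit
    def totals(morph):
        hipp = morph[subcortical_vol_col("hippocampus", "left")] + morph[subcortical_vol_col("hippocampus", "right")]
        vent = morph[subcortical_vol_col("lateral_ventricle", "left")] + morph[
            subcortical_vol_col("lateral_ventricle", "right")]
        return hipp.to_numpy(), vent.to_numpy(), morph["gm_total"].to_numpy(), morph["icv"].to_numpy()

    hipp_b, vent_b, gm_b, icv_b = totals(base)
    hipp_f, vent_f, gm_f, icv_f = totals(fup_aligned)

    sig_b = np.asarray(compute_ad_signature(_signature_inputs(base, config)))
    with np.errstate(invalid="ignore"):
        sig_f = np.asarray(
            np.mean([(l.to_numpy() + r.to_numpy()) / 2.0 for l, r in _signature_inputs(fup_aligned, config).values()],
                    axis=0)
        )

    if adjust_icv:
        mask = np.ones(len(ids), dtype=bool) if icv_fit_mask is None else np.asarray(icv_fit_mask, dtype=bool)
        adjusted = {}
        for name, vb, vf in (("hippocampus", hipp_b, hipp_f), ("ventricles", vent_b, vent_f),
                             ("gray_matter", gm_b, gm_f)):
            b = icv_slope(vb, icv_b, mask)
            icv_ref = icv_b[mask].mean()
            adjusted[name] = (vb - b * (icv_b - icv_ref), vf - b * (icv_f - icv_ref))
        hipp_b, hipp_f = adjusted["hippocampus"]
        vent_b, vent_f = adjusted["ventricles"]
        gm_b, gm_f = adjusted["gray_matter"]

    out["hippocampal_volume_adj_baseline"] = hipp_b
    out["hippocampal_volume_adj_followup"] = hipp_f
    out["ventricular_volume_adj_baseline"] = vent_b
    out["ventricular_volume_adj_followup"] = vent_f
    out["gm_total_adj_baseline"] = gm_b
    out["gm_total_adj_followup"] = gm_f
    out["ad_signature_thickness_baseline"] = sig_b
    out["ad_signature_thickness_followup"] = sig_f

    interval = fup_aligned["scan_date_offset_days"].to_numpy(dtype=float)
    out["mri_interval_days"] = interval

    pairs = {
        "apc_hippocampus": (hipp_b, hipp_f),
        "apc_ventricles": (vent_b, vent_f),
        "apc_gray_matter": (gm_b, gm_f),
        "apc_ad_signature": (sig_b, sig_f),
    }
    c = complete.to_numpy() if hasattr(complete, "to_numpy") else np.asarray(complete)
    for col, (vb, vf) in pairs.items():
        vals = np.full(len(ids), np.nan)
        if c.any():
            vals[c] = compute_apc(vb[c], vf[c], interval[c])
        out[col] = vals

    # cognitive percentage change (no annualization)
    for test in config.cognitive_tests:
        b = cohort.clinical[f"{test}_baseline"].to_numpy(dtype=float)
        f = cohort.clinical[f"{test}_followup"].to_numpy(dtype=float)
        vals = np.full(len(ids), np.nan)
        ok = ~np.isnan(b) & ~np.isnan(f) & (b != 0)
        if np.any(~np.isnan(b) & (b == 0)):
            warnings.warn(f"PC undefined at zero baseline for {test}; left missing", RuntimeWarning)
        if ok.any():
            vals[ok] = compute_pc(b[ok], f[ok])
        out[f"pc_{test}"] = vals

    logger.info("derive: %d subjects (%d complete)", len(out), int(c.sum()))
    return out
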