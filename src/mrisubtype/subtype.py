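"""Placement on the severity/typicality plane and categorical subtyping.

The continuous characterization keeps each subject's BV/CSF index (severity:
low = typical-AD-like, high = minimal-atrophy-like) and hippocampus-to-cortex
ratio (typicality: low = limbic-predominant-like, high =
hippocampal-sparing-like) as-is; age-banded severity bands are attached for
descriptive reporting only.

The conventional categorical classifier thresholds the visual-rating scores:
left/right MTA are combined by arithmetic mean and compared against an
age-banded cut (>= 1.5 at 45-74 years, >= 2.0 at 75-84, >= 2.5 at 85-94);
PA and GCA-F are abnormal at >= 1 regardless of age. The three booleans map
to four subtypes:

====================  ====  ================
MTA abnormal          PA or GCA-F abnormal  label
====================  ====  ================
yes                   yes   typical_AD
yes                   no    limbic_predominant
no                    yes   hippocampal_sparing
no                    no    minimal_atrophy
====================  ====  ================

Continuous (e.g. model-estimated) rating scores are thresholded directly,
without rounding to half steps. Ages outside the cut table's support raise an
error; the rule table is never extrapolated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SEVERITY_BANDS, SUBTYPE_LABELS, AnalysisConfig, CutpointTable, default_config
from .derive import derive_measures
from .io_schema import Cohort

logger = logging.getLogger(__name__)


def _band_index(age, bands) -> np.ndarray:
    """Index of each age's band; bands are [lo, hi) with the last closed at hi."""
    age = np.asarray(age, dtype=float)
    idx = np.full(age.shape, -1, dtype=int)
    for i, (band, _) in enumerate(bands):
        last = i == len(bands) - 1
        in_band = (age >= band.lower) & ((age <= band.upper) if last else (age < band.upper))
        idx[in_band] = i
    if np.any(idx < 0):
        bad = np.atleast_1d(age)[np.atleast_1d(idx) < 0]
        lo, hi = bands[0][0].lower, bands[-1][0].upper
        raise ValueError(
            f"age(s) {np.unique(bad)[:5]} outside the configured cut-point support [{lo}, {hi}]"
        )
    return idx


def mta_cut_for_age(age, cuts: CutpointTable):
    """Age-banded MTA abnormality threshold; error outside the table's support."""
    idx = _band_index(age, cuts.mta_cuts)
    values = np.array([v for _, v in cuts.mta_cuts])
    out = values[idx]
    return float(out) if np.ndim(age) == 0 else out


def _check_range(score, lo, hi, name):
    s = np.asarray(score, dtype=float)
    if np.any(np.isnan(s)):
        raise ValueError(f"missing {name} score")
    if np.any((s < lo) | (s > hi)):
        raise ValueError(f"{name} score outside [{lo}, {hi}]")
    return s


def mta_abnormal(mta_left, mta_right, age, cuts: CutpointTable | None = None):
    """Mean of left/right MTA >= the age-banded cut."""
    cuts = cuts or default_config().cutpoints
    l = _check_range(mta_left, 0, 4, "MTA")
    r = _check_range(mta_right, 0, 4, "MTA")
    cut = mta_cut_for_age(age, cuts)
    out = (l + r) / 2.0 >= cut
    return bool(out) if np.ndim(out) == 0 else out


def pa_abnormal(pa, cuts: CutpointTable | None = None):
    """PA >= cut (default 1), at any age."""
    cuts = cuts or default_config().cutpoints
    s = _check_range(pa, 0, 3, "PA")
    out = s >= cuts.pa_cut
    return bool(out) if np.ndim(out) == 0 else out


def gcaf_abnormal(gcaf, cuts: CutpointTable | None = None):
    """GCA-F >= cut (default 1), at any age."""
    cuts = cuts or default_config().cutpoints
    s = _check_range(gcaf, 0, 3, "GCA-F")
    out = s >= cuts.gcaf_cut
    return bool(out) if np.ndim(out) == 0 else out


def assign_categorical_subtype(mta_ab, pa_ab, gcaf_ab):
    """Total mapping from the three abnormality booleans to the four subtypes."""
    m = np.asarray(mta_ab, dtype=bool)
    posterior_or_frontal = np.asarray(pa_ab, dtype=bool) | np.asarray(gcaf_ab, dtype=bool)
    out = np.select(
        [m & posterior_or_frontal, m & ~posterior_or_frontal, ~m & posterior_or_frontal],
        ["typical_AD", "limbic_predominant", "hippocampal_sparing"],
        default="minimal_atrophy",
    )
    return str(out) if np.ndim(out) == 0 else out.astype(object)


def classify_severity_band(bv_csf_index, age, cuts: CutpointTable | None = None):
    """Descriptive severity band from age-banded BV/CSF thresholds.

    Thresholds are compared descending with >=, so a value exactly on a
    boundary falls in the less-atrophic band.
    """
    cuts = cuts or default_config().cutpoints
    if not cuts.severity_band_cuts:
        raise ValueError("no severity-band thresholds configured")
    idx = _band_index(age, cuts.severity_band_cuts)
    thresholds = np.array([v for _, v in cuts.severity_band_cuts])  # (bands, 3) descending
    x = np.asarray(bv_csf_index, dtype=float)
    t = thresholds[idx]
    t_no, t_mild, t_mod = np.moveaxis(np.atleast_2d(t), -1, 0)
    xx = np.atleast_1d(x)
    out = np.select([xx >= t_no, xx >= t_mild, xx >= t_mod],
                    ["no_atrophy", "mild", "moderate"], default="severe")
    return str(out[0]) if np.ndim(x) == 0 else out.astype(object)


def build_subtype_profiles(
    cohort: Cohort,
    derived: pd.DataFrame | None = None,
    cuts: CutpointTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One subtype profile per subject plus a frequency table.

    Returns ``(profiles, frequencies)``: profiles carry the continuous
    dimensions, the severity band and the categorical label; frequencies
    count the four categorical labels and four severity bands (they each sum
    to the cohort size).
    """
    config: AnalysisConfig = cohort.config
    cuts = cuts or config.cutpoints
    if derived is None:
        derived = derive_measures(cohort)
    clin = cohort.clinical.loc[derived.index]
    age = clin["age_baseline"].to_numpy(dtype=float)

    profiles = pd.DataFrame(index=derived.index.copy())
    profiles["severity"] = derived["severity"]
    profiles["typicality"] = derived["typicality"]
    profiles["severity_band"] = classify_severity_band(derived["severity"].to_numpy(), age, cuts)
    m = mta_abnormal(clin["mta_left"].to_numpy(dtype=float), clin["mta_right"].to_numpy(dtype=float), age, cuts)
    p = pa_abnormal(clin["pa"].to_numpy(dtype=float), cuts)
    g = gcaf_abnormal(clin["gcaf"].to_numpy(dtype=float), cuts)
    profiles["mta_abnormal"] = m
    profiles["pa_abnormal"] = p
    profiles["gcaf_abnormal"] = g
    profiles["categorical_subtype"] = assign_categorical_subtype(m, p, g)

    rows = []
    n = len(profiles)
    for label in SUBTYPE_LABELS:
        k = int((profiles["categorical_subtype"] == label).sum())
        rows.append({"kind": "categorical_subtype", "level": label, "n": k, "pct": 100.0 * k / n})
    for band in SEVERITY_BANDS:
        k = int((profiles["severity_band"] == band).sum())
        rows.append({"kind": "severity_band", "level": band, "n": k, "pct": 100.0 * k / n})
    freq = pd.DataFrame(rows)
    logger.info("subtype: %d subjects classified", n)
    return profiles, freq
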