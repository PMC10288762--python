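"""Tabular data contract shared by all pipeline stages.

Two CSV files describe a cohort:

``morphometry.csv``
    One row per subject-visit. Columns: ``subject_id``, ``visit``
    (baseline/followup), ``scan_date_offset_days``, ``field_strength``
    (1.5T/3T), one ``<region>_<hemi>_vol`` and ``<region>_<hemi>_thk`` column
    per Desikan cortical region and hemisphere, one ``<structure>_<hemi>_vol``
    column per subcortical structure (hippocampus and lateral ventricle are
    required), and the totals ``gm_total``, ``wm_total``, ``csf_total``,
    ``icv`` (all mm3, thickness in mm). This mirrors a wide FreeSurfer
    stats-table export.

``clinical.csv``
    One row per subject: demographics, randomization arm, eligibility fields
    (FCSRT recall, CDR, MMSE), visual-rating scores (MTA left/right, PA,
    GCA-F), and per-visit cognitive scores as ``<test>_baseline`` /
    ``<test>_followup`` columns.

Missing values are empty cells. Validation is strict: unknown region columns,
out-of-range ratings, duplicate subject-visits and subjects without a baseline
scan are load errors naming the offending row/column. Subjects missing only
the follow-up scan are retained and flagged incomplete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ARM_LEVELS,
    EDUCATION_LEVELS,
    FIELD_STRENGTH_LEVELS,
    HEMISPHERES,
    SEX_LEVELS,
    VISITS,
    AnalysisConfig,
    default_config,
)

logger = logging.getLogger(__name__)

MISSING_TOKEN = ""  # empty cell encodes a missing value


class SchemaError(ValueError):
    """A cohort table violates the documented schema."""

    def __init__(self, message: str, *, row=None, column: str | None = None):
        detail = message
        if row is not None:
            detail += f" [row {row}]"
        if column is not None:
            detail += f" [column {column!r}]"
        super().__init__(detail)
        self.row = row
        self.column = column


# ---------------------------------------------------------------------------
# column layout


def cortical_vol_col(region: str, hemi: str) -> str:
    return f"{region}_{hemi}_vol"


def cortical_thk_col(region: str, hemi: str) -> str:
    return f"{region}_{hemi}_thk"


def subcortical_vol_col(structure: str, hemi: str) -> str:
    return f"{structure}_{hemi}_vol"


def morphometry_columns(config: AnalysisConfig, structures: Sequence[str] | None = None) -> list[str]:
    """Canonical column order for a morphometry table."""
    structures = list(structures if structures is not None else config.required_subcortical)
    cols = ["subject_id", "visit", "scan_date_offset_days", "field_strength"]
    for region in config.cortical_regions:
        for hemi in HEMISPHERES:
            cols.append(cortical_vol_col(region, hemi))
    for region in config.cortical_regions:
        for hemi in HEMISPHERES:
            cols.append(cortical_thk_col(region, hemi))
    for structure in structures:
        for hemi in HEMISPHERES:
            cols.append(subcortical_vol_col(structure, hemi))
    cols += ["gm_total", "wm_total", "csf_total", "icv"]
    return cols


def clinical_columns(config: AnalysisConfig) -> list[str]:
    cols = [
        "subject_id",
        "age_baseline",
        "sex",
        "education",
        "arm",
        "fcsrt_free_recall",
        "fcsrt_total_recall",
        "cdr",
        "mmse",
        "mta_left",
        "mta_right",
        "pa",
        "gcaf",
        "hamilton",
    ]
    for test in config.cognitive_tests:
        cols += [f"{test}_baseline", f"{test}_followup"]
    return cols


RATING_BOUNDS = {"mta_left": (0.0, 4.0), "mta_right": (0.0, 4.0), "pa": (0.0, 3.0), "gcaf": (0.0, 3.0)}


# ---------------------------------------------------------------------------
# record views


@dataclass(frozen=True)
class MorphometryRecord:
    """One subject-visit row of the morphometry table (a validated view)."""

    subject_id: str
    visit: str
    scan_date_offset_days: int
    field_strength: str
    data: pd.Series  # full numeric row

    def cortical_volume(self, region: str, hemi: str) -> float:
        return float(self.data[cortical_vol_col(region, hemi)])

    def cortical_thickness(self, region: str, hemi: str) -> float:
        return float(self.data[cortical_thk_col(region, hemi)])

    def subcortical_volume(self, structure: str, hemi: str) -> float:
        return float(self.data[subcortical_vol_col(structure, hemi)])


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical row plus the subject's one or two morphometry records."""

    subject_id: str
    clinical: pd.Series
    baseline: MorphometryRecord
    followup: MorphometryRecord | None

    @property
    def complete(self) -> bool:
        return self.followup is not None


@dataclass
class Cohort:
    """A validated cohort: clinical table (one row per subject, indexed by
    subject_id) plus morphometry table (one row per subject-visit)."""

    morphometry: pd.DataFrame
    clinical: pd.DataFrame
    config: AnalysisConfig = field(default_factory=default_config)

    @property
    def subject_ids(self) -> pd.Index:
        return self.clinical.index

    @property
    def n_subjects(self) -> int:
        return len(self.clinical)

    @property
    def baseline(self) -> pd.DataFrame:
        df = self.morphometry[self.morphometry["visit"] == "baseline"]
        return df.set_index("subject_id").loc[self.subject_ids]

    @property
    def followup(self) -> pd.DataFrame:
        """Follow-up morphometry rows, indexed by subject_id (subset of subjects)."""
        df = self.morphometry[self.morphometry["visit"] == "followup"]
        return df.set_index("subject_id")

    @property
    def incomplete_subjects(self) -> list[str]:
        return sorted(set(self.subject_ids) - set(self.followup.index))

    def subject(self, subject_id: str) -> SubjectRecord:
        clin = self.clinical.loc[subject_id]
        base_row = self.baseline.loc[subject_id]
        base = MorphometryRecord(
            subject_id,
            "baseline",
            int(base_row["scan_date_offset_days"]),
            str(base_row["field_strength"]),
            base_row,
        )
        fup = None
        if subject_id in self.followup.index:
            fup_row = self.followup.loc[subject_id]
            fup = MorphometryRecord(
                subject_id,
                "followup",
                int(fup_row["scan_date_offset_days"]),
                str(fup_row["field_strength"]),
                fup_row,
            )
        return SubjectRecord(subject_id, clin, base, fup)

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        ids = list(subject_ids)
        morph = self.morphometry[self.morphometry["subject_id"].isin(ids)].reset_index(drop=True)
        clin = self.clinical.loc[ids]
        return Cohort(morph, clin, self.config)


# ---------------------------------------------------------------------------
# validation


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s)", column=", ".join(missing))


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            raise SchemaError(f"{table}: non-numeric value", row=int(bad.idxmax()), column=col)
        df[col] = coerced


def _check_levels(df: pd.DataFrame, col: str, levels: Sequence[str], table: str) -> None:
    bad = ~df[col].isin(levels) & df[col].notna()
    if bad.any():
        raise SchemaError(
            f"{table}: value {df.loc[bad.idxmax(), col]!r} not in {list(levels)}",
            row=int(bad.idxmax()),
            column=col,
        )


def validate_morphometry(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Validate a morphometry table; returns a normalized copy."""
    df = df.copy()
    _require_columns(df, ["subject_id", "visit", "scan_date_offset_days", "field_strength"], "morphometry")
    df["subject_id"] = df["subject_id"].astype(str)
    _check_levels(df, "visit", VISITS, "morphometry")
    _check_levels(df, "field_strength", FIELD_STRENGTH_LEVELS, "morphometry")

    # determine which subcortical structures are present, reject unknown columns
    meta = {"subject_id", "visit", "scan_date_offset_days", "field_strength",
            "gm_total", "wm_total", "csf_total", "icv"}
    cortical_cols = {cortical_vol_col(r, h) for r in config.cortical_regions for h in HEMISPHERES}
    cortical_cols |= {cortical_thk_col(r, h) for r in config.cortical_regions for h in HEMISPHERES}
    subcort_cols = {subcortical_vol_col(s, h): s for s in config.subcortical_structures for h in HEMISPHERES}
    structures = []
    for col in df.columns:
        if col in meta or col in cortical_cols:
            continue
        if col in subcort_cols:
            if subcort_cols[col] not in structures:
                structures.append(subcort_cols[col])
            continue
        raise SchemaError("morphometry: unknown column (region name not in vocabulary?)", column=col)
    missing_struct = [s for s in config.required_subcortical if s not in structures]
    if missing_struct:
        raise SchemaError("morphometry: missing required subcortical structure columns",
                          column=", ".join(missing_struct))

    expected = morphometry_columns(config, structures)
    _require_columns(df, expected, "morphometry")
    df = df[expected]

    numeric_cols = [c for c in expected if c not in ("subject_id", "visit", "field_strength")]
    _check_numeric(df, numeric_cols, "morphometry")

    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        raise SchemaError("morphometry: duplicate subject-visit", row=int(dup.idxmax()),
                          column="subject_id")

    # visit offsets
    base = df["visit"] == "baseline"
    bad = base & (df["scan_date_offset_days"] != 0)
    if bad.any():
        raise SchemaError("morphometry: baseline scan_date_offset_days must be 0",
                          row=int(bad.idxmax()), column="scan_date_offset_days")
    bad = ~base & ~(df["scan_date_offset_days"] > 0)
    if bad.any():
        raise SchemaError("morphometry: follow-up scan_date_offset_days must be > 0",
                          row=int(bad.idxmax()), column="scan_date_offset_days")

    # strict positivity of all measures
    measure_cols = [c for c in numeric_cols if c != "scan_date_offset_days"]
    vals = df[measure_cols]
    nonpos = (vals <= 0) | vals.isna()
    if nonpos.any().any():
        col = nonpos.any(axis=0).idxmax()
        raise SchemaError("morphometry: measure must be strictly positive and present",
                          row=int(nonpos[col].idxmax()), column=col)

    bad = ~(df["icv"] > df["gm_total"])
    if bad.any():
        raise SchemaError("morphometry: icv must exceed gm_total", row=int(bad.idxmax()), column="icv")
    return df.reset_index(drop=True)


def validate_clinical(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Validate a clinical table; returns a normalized copy."""
    df = df.copy()
    expected = clinical_columns(config)
    _require_columns(df, [c for c in expected if c != "hamilton"], "clinical")
    if "hamilton" not in df.columns:  # optional depression score
        df["hamilton"] = np.nan
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError("clinical: unknown column(s)", column=", ".join(unknown))
    df = df[expected]
    df["subject_id"] = df["subject_id"].astype(str)

    dup = df.duplicated(subset=["subject_id"])
    if dup.any():
        raise SchemaError("clinical: duplicate subject", row=int(dup.idxmax()), column="subject_id")

    _check_levels(df, "sex", SEX_LEVELS, "clinical")
    _check_levels(df, "education", EDUCATION_LEVELS, "clinical")
    _check_levels(df, "arm", ARM_LEVELS, "clinical")

    numeric_cols = [c for c in expected if c not in ("subject_id", "sex", "education", "arm")]
    _check_numeric(df, numeric_cols, "clinical")

    bad = ~(df["age_baseline"] > 0)
    if bad.any():
        raise SchemaError("clinical: age_baseline must be positive", row=int(bad.idxmax()),
                          column="age_baseline")

    for col, (lo, hi) in RATING_BOUNDS.items():
        vals = df[col]
        bad = vals.notna() & ~vals.between(lo, hi)
        if bad.any():
            raise SchemaError(f"clinical: rating outside [{lo}, {hi}]", row=int(bad.idxmax()), column=col)

    bad = df["mmse"].notna() & ~df["mmse"].between(0, 30)
    if bad.any():
        raise SchemaError("clinical: mmse outside [0, 30]", row=int(bad.idxmax()), column="mmse")
    bad = df["cdr"].notna() & ~df["cdr"].between(0, 3)
    if bad.any():
        raise SchemaError("clinical: cdr outside [0, 3]", row=int(bad.idxmax()), column="cdr")
    return df.reset_index(drop=True)


def _check_join(morph: pd.DataFrame, clinical: pd.DataFrame) -> None:
    clin_ids = set(clinical["subject_id"])
    base_counts = morph[morph["visit"] == "baseline"]["subject_id"].value_counts()
    fup_counts = morph[morph["visit"] == "followup"]["subject_id"].value_counts()
    stray = set(morph["subject_id"]) - clin_ids
    if stray:
        raise SchemaError(f"morphometry rows for subject(s) absent from clinical table: {sorted(stray)[:5]}")
    missing_base = sorted(clin_ids - set(base_counts.index))
    if missing_base:
        raise SchemaError(f"subject(s) without a baseline morphometry row: {missing_base[:5]}")
    orphan_fup = sorted(set(fup_counts.index) - set(base_counts.index))
    if orphan_fup:  # unreachable once missing_base checked, kept for clarity
        raise SchemaError(f"follow-up row without baseline for subject(s): {orphan_fup[:5]}")


def cohort_from_frames(
    morphometry: pd.DataFrame,
    clinical: pd.DataFrame,
    config: AnalysisConfig | None = None,
    validate: bool = True,
) -> Cohort:
    """Assemble a Cohort from in-memory tables (the simulator's entry point)."""
    config = config or default_config()
    if validate:
        morphometry = validate_morphometry(morphometry, config)
        clinical = validate_clinical(clinical, config)
        _check_join(morphometry, clinical)
    clinical = clinical.set_index(clinical["subject_id"].astype(str))
    clinical.index.name = "subject_id"
    cohort = Cohort(morphometry.reset_index(drop=True), clinical, config)
    n_inc = len(cohort.incomplete_subjects)
    if n_inc:
        logger.info("cohort: %d of %d subjects missing the follow-up scan (flagged incomplete)",
                    n_inc, cohort.n_subjects)
    return cohort


def read_cohort(morphometry_path, clinical_path, config: AnalysisConfig | None = None) -> Cohort:
    """Read and validate the two cohort CSVs and join them into a Cohort."""
    config = config or default_config()
    morph = pd.read_csv(morphometry_path, dtype={"subject_id": str})
    clinical = pd.read_csv(clinical_path, dtype={"subject_id": str})
    return cohort_from_frames(morph, clinical, config, validate=True)


def write_cohort(cohort: Cohort, morphometry_path, clinical_path) -> None:
    """Write the two cohort CSVs; ``read_cohort`` on the output round-trips."""
    cohort.morphometry.to_csv(morphometry_path, index=False, na_rep=MISSING_TOKEN)
    cohort.clinical.reset_index(drop=True).to_csv(clinical_path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# eligibility screen

ELIGIBILITY_FIELDS = ("age_baseline", "fcsrt_free_recall", "fcsrt_total_recall", "cdr", "mmse")


def apply_inclusion_criteria(record: Mapping) -> tuple[bool, list[str]]:
    """Trial eligibility screen for one subject.

    Included iff age > 50, an amnestic deficit on the FCSRT (free recall <= 17
    or total recall < 40), CDR <= 0.5 and MMSE > 24. Returns the decision and
    the list of failed criteria; a missing eligibility field is an error, not
    a silent exclusion.
    """
    for fieldname in ELIGIBILITY_FIELDS:
        if fieldname not in record or pd.isna(record[fieldname]):
            raise ValueError(f"missing eligibility field {fieldname!r}")
    reasons = []
    if not record["age_baseline"] > 50:
        reasons.append("age")
    if not (record["fcsrt_free_recall"] <= 17 or record["fcsrt_total_recall"] < 40):
        reasons.append("fcsrt")
    if not record["cdr"] <= 0.5:
        reasons.append("cdr")
    if not record["mmse"] > 24:
        reasons.append("mmse")
    return (not reasons, reasons)


def inclusion_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject eligibility decision with reasons (deterministic, rowwise)."""
    rows = {}
    for sid, row in cohort.clinical.iterrows():
        ok, reasons = apply_inclusion_criteria(row)
        rows[sid] = {"eligible": ok, "reasons": ";".join(reasons)}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")


def filter_eligible(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Apply the inclusion screen; returns the eligible sub-cohort and the
    per-subject decision table."""
    table = inclusion_table(cohort)
    keep = table.index[table["eligible"]]
    logger.info("inclusion screen: %d of %d subjects eligible", len(keep), cohort.n_subjects)
    return cohort.subset(keep), table
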