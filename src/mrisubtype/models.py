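"""Inferential models: treatment-by-dimension interaction regressions with
backward selection, subtype-by-treatment ANCOVA with BH-adjusted post hocs,
and baseline group-comparison descriptives.

The interaction model for an efficacy outcome y (an APC or PC) is

    y ~ treatment + severity + typicality + age [+ field_strength]
        + severity:treatment + typicality:treatment

with treatment a 0/1 dummy (0 = placebo, 1 = donepezil) and field strength
included only when the outcome is an MRI change score. The two interaction
coefficients are the effects of interest. Age (and field strength, when
present) are forced covariates that selection never drops; interactions are
never retained without their main effects (marginality).

Backward selection scores candidate sub-models by BIC. The default strategy
enumerates every marginality-respecting sub-model exhaustively (feasible for
the small term sets used here); a greedy strategy eliminates one term at a
time down to the empty candidate set and returns the BIC-best model visited
along that path. Both are deterministic.

All fits are complete-case for the variables of the specific model, and the
n actually used is reported with every result.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .config import ARM_LEVELS, SUBTYPE_LABELS
from .io_schema import Cohort, subcortical_vol_col

logger = logging.getLogger(__name__)

#: candidate terms, in canonical order
CANDIDATE_TERMS = (
    "treatment",
    "severity",
    "typicality",
    "severity_x_treatment",
    "typicality_x_treatment",
)
#: marginality: interaction -> required main effects
TERM_DEPENDENCIES = {
    "severity_x_treatment": ("severity", "treatment"),
    "typicality_x_treatment": ("typicality", "treatment"),
}


def is_mri_outcome(outcome: str) -> bool:
    return outcome.startswith("apc_")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one interaction regression."""

    outcome: str
    selection: str = "none"  # none | backward
    include_field_strength: bool | None = None  # None -> automatic (MRI outcomes only)
    candidate_terms: tuple[str, ...] = CANDIDATE_TERMS

    @property
    def field_strength_included(self) -> bool:
        if self.include_field_strength is None:
            return is_mri_outcome(self.outcome)
        return self.include_field_strength

    @property
    def forced_terms(self) -> tuple[str, ...]:
        return ("age", "field_strength") if self.field_strength_included else ("age",)


@dataclass
class ModelResult:
    """Fitted terms and model-level statistics of one regression."""

    outcome: str
    terms: pd.DataFrame  # index term; columns B, se, t, p
    f_stat: float
    f_pvalue: float
    r_squared: float
    n: int
    selected_terms: tuple[str, ...]
    selection_trace: list = field(default_factory=list)


def _complete_cases(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return data.dropna(subset=[c for c in cols if c in data.columns])


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for t in terms:
        if t == "severity_x_treatment":
            X[t] = data["severity"] * data["treatment"]
        elif t == "typicality_x_treatment":
            X[t] = data["typicality"] * data["treatment"]
        elif t == "field_strength":
            X[t] = data["field_strength_3t"].astype(float)
        else:
            X[t] = data[t].astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        aliased = []
        for j, col in enumerate(X.columns):
            others = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                aliased.append(col)
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased}")


def _ols(data: pd.DataFrame, outcome: str, terms: Sequence[str]):
    X = _design_matrix(data, terms)
    _check_rank(X)
    return sm.OLS(data[outcome].to_numpy(dtype=float), X).fit()


def _valid_subsets(candidates: Sequence[str]):
    """All subsets of candidate terms respecting marginality, in deterministic order."""
    cands = list(candidates)
    for size in range(len(cands), -1, -1):
        for combo in itertools.combinations(cands, size):
            s = set(combo)
            if all(set(TERM_DEPENDENCIES.get(t, ())) <= s for t in combo):
                yield combo


def backward_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    criterion: str = "bic",
    strategy: str = "exhaustive",
) -> tuple[tuple[str, ...], list]:
    """Select the candidate-term subset minimizing the information criterion.

    Forced covariates (age, field strength when applicable) and the intercept
    are always included. ``strategy='exhaustive'`` scores every
    marginality-respecting sub-model; ``strategy='greedy'`` eliminates, at
    each step, the removable term whose removal yields the lowest criterion,
    continuing to the empty candidate set, and returns the best model visited.
    Ties break toward fewer terms, then lexicographically. Deterministic
    given the data.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if strategy not in ("exhaustive", "greedy"):
        raise ValueError("strategy must be 'exhaustive' or 'greedy'")

    cols = [spec.outcome, "treatment", "severity", "typicality", "age"]
    if spec.field_strength_included:
        cols.append("field_strength_3t")
    cc = _complete_cases(data, cols)

    def score(terms: tuple[str, ...]) -> float:
        res = _ols(cc, spec.outcome, tuple(spec.forced_terms) + terms)
        return float(getattr(res, criterion))

    trace = []
    if strategy == "exhaustive":
        best, best_ic = None, np.inf
        for combo in _valid_subsets(spec.candidate_terms):
            ic = score(combo)
            trace.append({"terms": combo, criterion: ic})
            # strict improvement keeps the first (largest, canonical-order) model on ties;
            # round to avoid float noise, then prefer fewer terms
            if ic < best_ic - 1e-10 or (abs(ic - best_ic) <= 1e-10 and best is not None and len(combo) < len(best)):
                best, best_ic = combo, ic
    else:
        current = tuple(spec.candidate_terms)
        path = [(current, score(current))]
        trace.append({"step": 0, "terms": current, criterion: path[0][1], "removed": None})
        step = 0
        while current:
            removable = [
                t for t in current
                if not any(t in TERM_DEPENDENCIES.get(u, ()) for u in current if u != t)
            ]
            scored = sorted(
                ((score(tuple(t2 for t2 in current if t2 != t)), t) for t in removable),
                key=lambda x: (x[0], x[1]),
            )
            ic, removed = scored[0]
            current = tuple(t for t in current if t != removed)
            step += 1
            path.append((current, ic))
            trace.append({"step": step, "terms": current, criterion: ic, "removed": removed})
        best, best_ic = min(path, key=lambda x: (round(x[1], 10), len(x[0])))
    return tuple(best), trace


def fit_interaction_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the treatment-by-dimension interaction regression for one outcome.

    ``data`` needs columns ``treatment`` (0/1), ``severity``, ``typicality``,
    ``age``, ``field_strength_3t`` (for MRI outcomes) and the outcome itself.
    Complete-case; requires at least two subjects per arm.
    """
    cols = [spec.outcome, "treatment", "severity", "typicality", "age"]
    if spec.field_strength_included:
        cols.append("field_strength_3t")
    cc = _complete_cases(data, cols)
    arm_counts = cc["treatment"].value_counts()
    if len(arm_counts) < 2:
        raise ValueError("both treatment arms must be present among complete cases")
    if arm_counts.min() < 2:
        raise ValueError("need at least 2 complete cases per arm")

    trace: list = []
    if spec.selection == "backward":
        selected, trace = backward_select(data, spec)
    elif spec.selection == "none":
        selected = tuple(spec.candidate_terms)
    else:
        raise ValueError(f"unknown selection {spec.selection!r}")

    res = _ols(cc, spec.outcome, tuple(spec.forced_terms) + selected)
    terms = pd.DataFrame(
        {"B": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    return ModelResult(
        outcome=spec.outcome,
        terms=terms,
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        selected_terms=selected,
        selection_trace=trace,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AnovaResult:
    """Between-subjects subtype-by-treatment ANCOVA for one outcome."""

    outcome: str
    table: pd.DataFrame  # Type-II ANOVA table
    interaction_f: float
    interaction_p: float
    posthoc: pd.DataFrame  # per-subtype arm contrast with BH-adjusted p
    n: int
    notes: list = field(default_factory=list)


def fit_subtype_anova(
    data: pd.DataFrame,
    outcome: str,
    include_field_strength: bool | None = None,
) -> AnovaResult:
    """Two-factor between-subjects ANCOVA: subtype (up to 4 levels) x arm.

    Age is always a covariate; MRI field strength is added for MRI outcomes.
    Sums of squares are Type II (robust to the heavily unbalanced subtype
    cells). Post hoc donepezil-vs-placebo contrasts within each subtype
    (evaluated at the mean covariate values) are BH-adjusted as one family
    per outcome; a subtype with an empty or singleton cell gets an undefined
    contrast and a warning.
    """
    if include_field_strength is None:
        include_field_strength = is_mri_outcome(outcome)
    cols = [outcome, "categorical_subtype", "arm", "age"]
    if include_field_strength:
        cols.append("field_strength_3t")
    cc = _complete_cases(data, cols).copy()

    if cc["arm"].nunique() < 2:
        raise ValueError("both treatment arms must be present")
    levels = [s for s in SUBTYPE_LABELS if s in set(cc["categorical_subtype"])]
    if len(levels) < 2:
        raise ValueError("need at least 2 subtype levels with data")

    notes = []
    cell = cc.groupby(["categorical_subtype", "arm"], observed=True).size()
    degenerate = set()
    for s in levels:
        for arm in ARM_LEVELS:
            if cell.get((s, arm), 0) < 2:
                degenerate.add(s)
    if degenerate:
        msg = f"subtype cell(s) with <2 observations: {sorted(degenerate)}; contrasts undefined"
        notes.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    formula = f"{outcome} ~ C(categorical_subtype) + C(arm) + C(categorical_subtype):C(arm) + age"
    if include_field_strength:
        formula += " + field_strength_3t"
    model = smf.ols(formula, data=cc).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm emits noisy df warnings on unbalanced data
        table = anova_lm(model, typ=2)
    inter_row = "C(categorical_subtype):C(arm)"
    interaction_f = float(table.loc[inter_row, "F"])
    interaction_p = float(table.loc[inter_row, "PR(>F)"])

    # post hoc: adjusted arm difference within each subtype
    import patsy

    di = model.model.data.design_info
    ref = {"age": float(cc["age"].mean())}
    if include_field_strength:
        ref["field_strength_3t"] = float(cc["field_strength_3t"].mean())
    rows = []
    for s in levels:
        if s in degenerate:
            rows.append({"subtype": s, "estimate": np.nan, "se": np.nan, "t": np.nan, "p": np.nan})
            continue
        frames = []
        for arm in ("donepezil", "placebo"):
            frames.append(pd.DataFrame([{**ref, "categorical_subtype": s, "arm": arm}]))
        (md,) = patsy.build_design_matrices([di], pd.concat(frames, ignore_index=True))
        L = np.asarray(md)[0] - np.asarray(md)[1]
        tt = model.t_test(L)
        rows.append({
            "subtype": s,
            "estimate": float(np.squeeze(tt.effect)),
            "se": float(np.squeeze(tt.sd)),
            "t": float(np.squeeze(tt.tvalue)),
            "p": float(np.squeeze(tt.pvalue)),
        })
    posthoc = pd.DataFrame(rows)
    defined = posthoc["p"].notna()
    posthoc["p_bh"] = np.nan
    if defined.any():
        posthoc.loc[defined, "p_bh"] = bh_adjust(posthoc.loc[defined, "p"].to_numpy())
    return AnovaResult(outcome, table, interaction_f, interaction_p, posthoc, int(model.nobs), notes)


# ---------------------------------------------------------------------------
# baseline descriptives


def baseline_comparison_table(cohort: Cohort, variables: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Arm-wise descriptives with group-difference tests at baseline.

    Continuous variables get mean (SD) per arm and a one-way ANOVA p-value
    (or Kruskal-Wallis for variables listed in the config's
    ``kruskal_variables``); categorical variables get counts (%) per arm and
    a chi-square p-value. ``variables`` maps variable name to
    ``'continuous'``/``'categorical'``; a sensible default covering
    demographics, cognition, ratings and raw MRI totals is used when omitted.
    """
    clin = cohort.clinical
    base = cohort.baseline
    df = clin.copy()
    df["field_strength"] = base["field_strength"]
    df["mta_mean"] = (clin["mta_left"] + clin["mta_right"]) / 2.0
    df["hippocampus_total"] = (
        base[subcortical_vol_col("hippocampus", "left")] + base[subcortical_vol_col("hippocampus", "right")]
    )
    df["lateral_ventricle_total"] = (
        base[subcortical_vol_col("lateral_ventricle", "left")]
        + base[subcortical_vol_col("lateral_ventricle", "right")]
    )
    df["gm_total"] = base["gm_total"]

    if variables is None:
        variables = {"age_baseline": "continuous", "sex": "categorical", "education": "categorical"}
        for test in cohort.config.cognitive_tests:
            variables[f"{test}_baseline"] = "continuous"
        variables.update({
            "fcsrt_free_recall": "continuous",
            "fcsrt_total_recall": "continuous",
            "hamilton": "continuous",
            "mta_mean": "continuous",
            "pa": "continuous",
            "gcaf": "continuous",
            "field_strength": "categorical",
            "hippocampus_total": "continuous",
            "lateral_ventricle_total": "continuous",
            "gm_total": "continuous",
        })

    groups = {arm: df[df["arm"] == arm] for arm in ARM_LEVELS}
    for arm, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"arm {arm!r} has no subjects")

    kruskal = set(cohort.config.kruskal_variables)
    rows = []
    for var, kind in variables.items():
        if var not in df.columns:
            warnings.warn(f"baseline table: variable {var!r} absent; omitted", RuntimeWarning)
            continue
        if kind == "continuous":
            samples = [g[var].dropna().to_numpy(dtype=float) for g in groups.values()]
            if any(len(s) == 0 for s in samples):
                warnings.warn(f"baseline table: variable {var!r} empty in an arm; omitted", RuntimeWarning)
                continue
            if var in kruskal:
                test = "kruskal"
                try:
                    stat, p = scipy.stats.kruskal(*samples)
                except ValueError:  # all identical values
                    stat, p = 0.0, 1.0
            else:
                test = "anova"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = scipy.stats.f_oneway(*samples)
                if np.isnan(p):  # zero between- and within-group variance
                    stat, p = 0.0, 1.0
            rows.append({
                "variable": var, "type": "continuous", "test": test,
                "placebo_summary": f"{samples[0].mean():.2f} ({samples[0].std(ddof=1):.2f})",
                "donepezil_summary": f"{samples[1].mean():.2f} ({samples[1].std(ddof=1):.2f})",
                "statistic": float(stat), "p": float(p),
            })
        elif kind == "categorical":
            counts = pd.crosstab(df[var], df["arm"])
            counts = counts.loc[:, [a for a in ARM_LEVELS if a in counts.columns]]
            # drop all-zero rows; chi-square needs a full-rank table
            counts = counts.loc[counts.sum(axis=1) > 0]
            if counts.shape[0] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = scipy.stats.chi2_contingency(counts.to_numpy(), correction=False)
            def fmt(arm):
                tot = counts[arm].sum()
                return "; ".join(f"{lvl}: {int(k)} ({100.0 * k / tot:.0f}%)" for lvl, k in counts[arm].items())
            rows.append({
                "variable": var, "type": "categorical", "test": "chi2",
                "placebo_summary": fmt("placebo"), "donepezil_summary": fmt("donepezil"),
                "statistic": float(stat), "p": float(p),
            })
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis-table assembly and batch fitting


def build_analysis_table(
    cohort: Cohort,
    derived: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge derived measures, demographics and (optionally) subtype labels
    into the one-row-per-subject table the models consume."""
    data = derived.copy()
    clin = cohort.clinical.loc[data.index]
    base = cohort.baseline.loc[data.index]
    data["arm"] = clin["arm"]
    data["treatment"] = (clin["arm"] == "donepezil").astype(int)
    data["age"] = clin["age_baseline"].astype(float)
    data["field_strength_3t"] = (base["field_strength"] == "3T").astype(int)
    if profiles is not None:
        data["categorical_subtype"] = profiles.loc[data.index, "categorical_subtype"]
    return data


def fit_all_interactions(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    selection: str = "none",
) -> tuple[pd.DataFrame, list[ModelResult]]:
    """Fit the interaction regression for every outcome; returns a tidy
    one-row-per-(outcome, term) table plus the full results."""
    results = []
    rows = []
    for outcome in outcomes:
        spec = ModelSpec(outcome=outcome, selection=selection)
        res = fit_interaction_model(data, spec)
        results.append(res)
        for term, trow in res.terms.iterrows():
            rows.append({
                "outcome": outcome, "term": term, "B": trow["B"], "se": trow["se"],
                "t": trow["t"], "p": trow["p"], "F": res.f_stat, "model_p": res.f_pvalue,
                "R2": res.r_squared, "n": res.n,
            })
    return pd.DataFrame(rows), results


def fit_all_anovas(data: pd.DataFrame, outcomes: Sequence[str]) -> tuple[pd.DataFrame, list[AnovaResult]]:
    """Subtype-by-treatment ANCOVA for every outcome (tidy summary + results)."""
    results, rows = [], []
    for outcome in outcomes:
        res = fit_subtype_anova(data, outcome)
        results.append(res)
        rows.append({
            "outcome": outcome,
            "interaction_F": res.interaction_f,
            "interaction_p": res.interaction_p,
            "n": res.n,
            "notes": "; ".join(res.notes),
        })
    return pd.DataFrame(rows), results
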