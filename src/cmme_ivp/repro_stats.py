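"""Repeatability analytics: CV%, balanced ANOVA, ICC, acceptability rules.

Operates on long-format :class:`~cmme_ivp.cmm_io.StudyTable` data from a
balanced goat x scan (observer/time) x cycle design.  The suite follows
common echocardiographic repeatability practice:

* between-cycle CV% (intraobserver): CV across the replicate cycles in
  each goat x scan cell, averaged over cells;
* between-scan CV% (interobserver): CV of the two per-scan means within
  each goat, averaged over goats;
* a two-way crossed ANOVA (goat, time, goat x time) whose factors should
  all be non-significant for a repeatable technique, plus a one-way
  within-goat ANOVA on the pooled cycles;
* ICC, by default the two-way random-effects absolute-agreement
  single-measurement form ICC(2,1), with every scan x cycle measurement
  as a "rater"; acceptable when >= 0.75;
* variability classes: low (CV < 15), moderate (15 <= CV <= 25), high
  (CV > 25), and the combined acceptability rule (non-significant ANOVA
  and CV < 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cmm_io import StudyTable, ValidationError

__all__ = [
    "AnovaResult", "ICCResult", "VariabilityClass",
    "cv_percent", "between_cycle_cv", "between_scan_cv",
    "two_way_anova", "one_way_within_goat_anova", "icc",
    "classify_variability", "acceptability", "repeatability_report",
    "ICC_THRESHOLD", "CV_LOW", "CV_HIGH",
]

ICC_THRESHOLD = 0.75
CV_LOW = 15.0
CV_HIGH = 25.0


@dataclass(frozen=True)
class FactorRow:
    sum_of_squares: float
    df: int
    mean_square: float
    F: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Classical fixed-layout ANOVA table for a balanced design."""

    factors: dict[str, FactorRow]
    ss_total: float
    df_total: int
    degenerate: bool = False

    def p(self, factor: str) -> float:
        return self.factors[factor].p

    def all_nonsignificant(self, alpha: float = 0.05) -> bool:
        return all(row.p >= alpha for name, row in self.factors.items()
                   if name != "error")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"factor": k, "ss": v.sum_of_squares, "df": v.df,
              "ms": v.mean_square, "F": v.F, "p": v.p}
             for k, v in self.factors.items()])


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model_label: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int

    @property
    def acceptable(self) -> bool:
        return self.icc >= ICC_THRESHOLD


@dataclass(frozen=True)
class VariabilityClass:
    cv_percent: float
    label: str        # "low" | "moderate" | "high"


# ---------------------------------------------------------------------------
# coefficients of variation
# ---------------------------------------------------------------------------

def cv_percent(values) -> float:
    """100 x sample SD (n-1 denominator) / mean.

    Undefined (error) for fewer than two values or zero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def _pivot(table: StudyTable, variable: str) -> np.ndarray:
    """Balanced (goat, scan, cycle) value array, goats/scans/cycles sorted."""
    table.check_balanced(variable)
    sub = table.values_for(variable)
    piv = sub.pivot_table(index="goat_id", columns=["scan_id", "cycle_index"],
                          values="value", aggfunc="first").sort_index()
    if piv.isna().any().any():
        raise ValidationError(f"incomplete design for {variable!r}")
    n_scans = piv.columns.get_level_values(0).nunique()
    n_cycles = piv.columns.get_level_values(1).nunique()
    return piv.to_numpy().reshape(len(piv), n_scans, n_cycles)


def between_cycle_cv(table: StudyTable, variable: str) -> float:
    """Intraobserver variability: mean CV across cycles over goat x scan cells."""
    y = _pivot(table, variable)
    cvs = [cv_percent(y[i, j, :]) for i in range(y.shape[0]) for j in range(y.shape[1])]
    return float(np.mean(cvs))


def between_scan_cv(table: StudyTable, variable: str) -> float:
    """Interobserver variability: mean over goats of the CV of per-scan means."""
    y = _pivot(table, variable)
    if y.shape[1] < 2:
        raise ValidationError("between-scan CV needs >= 2 scans")
    scan_means = y.mean(axis=2)                      # goats x scans
    return float(np.mean([cv_percent(scan_means[i]) for i in range(y.shape[0])]))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _f_p(ss: float, df: int, ms_error: float, df_error: int) -> tuple[float, float]:
    ms = ss / df
    if ms_error == 0:
        # degenerate: no residual variation
        return (np.inf, 0.0) if ss > 0 else (np.nan, 1.0)
    F = ms / ms_error
    return F, float(stats.f.sf(F, df, df_error))


def two_way_anova(table: StudyTable, variable: str) -> AnovaResult:
    """Balanced two-way crossed ANOVA with interaction (goat, time).

    Classical sum-of-squares decomposition; each effect tested against
    the within-cell mean square.  The decomposition is exact:
    SS_goat + SS_time + SS_interaction + SS_error == SS_total.
    """
    y = _pivot(table, variable)
    a, b, r = y.shape
    if r < 2:
        raise ValidationError("two-way ANOVA with interaction needs replicate cycles")
    grand = y.mean()
    m_goat = y.mean(axis=(1, 2))
    m_time = y.mean(axis=(0, 2))
    m_cell = y.mean(axis=2)
    ss_goat = b * r * float(np.sum((m_goat - grand) ** 2))
    ss_time = a * r * float(np.sum((m_time - grand) ** 2))
    ss_int = r * float(np.sum((m_cell - m_goat[:, None] - m_time[None, :] + grand) ** 2))
    ss_err = float(np.sum((y - m_cell[:, :, None]) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))
    df_goat, df_time = a - 1, b - 1
    df_int, df_err = df_goat * df_time, a * b * (r - 1)
    ms_err = ss_err / df_err
    degenerate = ms_err == 0.0
    factors = {}
    for name, ss, df in (("goat", ss_goat, df_goat), ("time", ss_time, df_time),
                         ("goat x time", ss_int, df_int)):
        F, p = _f_p(ss, df, ms_err, df_err)
        factors[name] = FactorRow(ss, df, ss / df, F, p)
    factors["error"] = FactorRow(ss_err, df_err, ms_err, np.nan, np.nan)
    return AnovaResult(factors=factors, ss_total=ss_tot, df_total=a * b * r - 1,
                       degenerate=degenerate)


def one_way_within_goat_anova(table: StudyTable, variable: str) -> AnovaResult:
    """One-way ANOVA on cycles pooled per goat across scans (goat as only factor)."""
    y = _pivot(table, variable)
    a = y.shape[0]
    flat = y.reshape(a, -1)
    k = flat.shape[1]
    if k < 2:
        raise ValidationError("one-way ANOVA needs replicate measurements per goat")
    grand = flat.mean()
    m_goat = flat.mean(axis=1)
    ss_goat = k * float(np.sum((m_goat - grand) ** 2))
    ss_err = float(np.sum((flat - m_goat[:, None]) ** 2))
    ss_tot = float(np.sum((flat - grand) ** 2))
    df_goat, df_err = a - 1, a * (k - 1)
    ms_err = ss_err / df_err
    F, p = _f_p(ss_goat, df_goat, ms_err, df_err)
    factors = {
        "goat": FactorRow(ss_goat, df_goat, ss_goat / df_goat, F, p),
        "error": FactorRow(ss_err, df_err, ms_err, np.nan, np.nan),
    }
    return AnovaResult(factors=factors, ss_total=ss_tot, df_total=a * k - 1,
                       degenerate=ms_err == 0.0)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc(table: StudyTable, variable: str, form: str = "icc2_1") -> ICCResult:
    """Single-measurement ICC over goats x (every scan x cycle as a rater).

    ``icc2_1`` (default): two-way random effects, absolute agreement,

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E));

    ``icc3_1``: two-way mixed, consistency,

        (MS_R - MS_E) / (MS_R + (k-1) MS_E).
    """
    if form not in ("icc2_1", "icc3_1"):
        raise ValidationError(f"unknown ICC form {form!r}")
    y = _pivot(table, variable)
    n = y.shape[0]
    flat = y.reshape(n, -1)          # subjects x raters
    k = flat.shape[1]
    if k < 2:
        raise ValidationError("ICC needs k >= 2 repeated measurements per goat")
    if n < 2:
        raise ValidationError("ICC needs >= 2 goats")
    grand = flat.mean()
    m_row = flat.mean(axis=1)
    m_col = flat.mean(axis=0)
    ss_row = k * float(np.sum((m_row - grand) ** 2))
    ss_col = n * float(np.sum((m_col - grand) ** 2))
    ss_tot = float(np.sum((flat - grand) ** 2))
    ss_err = ss_tot - ss_row - ss_col
    ms_r = ss_row / (n - 1)
    ms_c = ss_col / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "icc2_1":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
        label = "ICC(2,1) two-way random, absolute agreement"
    else:
        denom = ms_r + (k - 1) * ms_e
        label = "ICC(3,1) two-way mixed, consistency"
    value = np.nan if denom == 0 else float((ms_r - ms_e) / denom)
    return ICCResult(icc=value, model_label=label, ms_rows=ms_r, ms_cols=ms_c,
                     ms_error=ms_e, n_subjects=n, k_raters=k)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_variability(cv: float) -> VariabilityClass:
    """low (< 15), moderate (15-25, boundaries inclusive), high (> 25)."""
    if cv < 0:
        raise ValidationError("CV must be >= 0")
    if cv < CV_LOW:
        label = "low"
    elif cv <= CV_HIGH:
        label = "moderate"
    else:
        label = "high"
    return VariabilityClass(cv_percent=cv, label=label)


def acceptability(anova: AnovaResult, cv: float, alpha: float = 0.05) -> bool:
    """Acceptable iff all ANOVA factors are non-significant and CV < 25."""
    return anova.all_nonsignificant(alpha) and cv < CV_HIGH


# ---------------------------------------------------------------------------
# report emitter
# ---------------------------------------------------------------------------

def repeatability_report(table: StudyTable, variables: list[str] | None = None,
                         icc_form: str = "icc2_1", alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable repeatability summary (the study's Table-2 analogue).

    Columns: pooled mean, SD, textbook 95 % t-interval of the mean over
    per-goat means, between-cycle and between-scan CV%, variability
    class, ICC (with form label), and the combined acceptability flag.
    """
    if variables is None:
        variables = table.variables()
    rows = []
    for var in variables:
        y = _pivot(table, var)
        goat_means = y.reshape(y.shape[0], -1).mean(axis=1)
        n = len(goat_means)
        mean = float(goat_means.mean())
        sd = float(goat_means.std(ddof=1)) if n > 1 else np.nan
        if n > 1:
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            ci = (mean - half, mean + half)
        else:
            ci = (np.nan, np.nan)
        cv_cycle = between_cycle_cv(table, var)
        cv_scan = between_scan_cv(table, var)
        an = two_way_anova(table, var)
        ic = icc(table, var, form=icc_form)
        rows.append({
            "variable": var,
            "mean": mean, "sd": sd,
            "ci95_low": ci[0], "ci95_high": ci[1],
            "cv_between_cycles": cv_cycle,
            "cv_between_scans": cv_scan,
            "variability": classify_variability(cv_cycle).label,
            "p_goat": an.p("goat"), "p_time": an.p("time"),
            "p_interaction": an.p("goat x time"),
            "icc": ic.icc, "icc_form": ic.model_label,
            "icc_acceptable": ic.acceptable,
            "acceptable": acceptability(an, cv_cycle, alpha),
        })
    return pd.DataFrame(rows)
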