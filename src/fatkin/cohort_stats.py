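"""Cohort-level statistics on the individual fatigue-model parameters.

Paired HF-vs-LF comparisons of the fitted asymptotes and curvature
constants (and of the VA/Q_tw estimates at fixed IMVC decrements) use
classical paired t-tests; because several tests form a family, a
Bonferroni-adjusted p-value is reported alongside the raw one.
Relationships between individual parameters (e.g. whether subjects with
a lower VA asymptote show a lower Q_tw asymptote) use simple ordinary
least squares with the signed Pearson r and the coefficient of
determination R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import CONDITIONS, VARIABLES

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "PairedTestResult",
    "RegressionResult",
    "paired_t_test",
    "linear_regression",
    "run_condition_comparisons",
    "run_parameter_correlations",
    "summarize_cohort",
    "normality_report",
]


@dataclass(frozen=True)
class CohortTable:
    """Per-subject (A, tau, R^2) for IMVC/VA/QTW in both conditions.

    Wraps the long fitted-parameter table (columns ``subject_id,
    condition, variable, A_pct, tau_s`` and optionally ``r_squared``);
    subjects are kept in sorted order so paired extractions align.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "condition", "variable", "A_pct", "tau_s"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.data.duplicated(["subject_id", "condition", "variable"]).any():
            raise ValueError("duplicate subject x condition x variable rows")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].astype(str).unique())

    def column(self, condition: str, variable: str, param: str) -> np.ndarray:
        """Values of one parameter column, ordered by subject id.

        ``param`` is one of ``A_pct``, ``tau_s``, ``r_squared``.
        """
        sel = self.data[
            (self.data.condition == condition) & (self.data.variable == variable)
        ].sort_values("subject_id")
        if sel.empty:
            raise KeyError(f"no rows for {condition}/{variable}")
        if list(sel.subject_id.astype(str)) != self.subjects():
            raise ValueError(f"incomplete cases for {condition}/{variable}")
        return sel[param].to_numpy(dtype=float)


@dataclass(frozen=True)
class PairedTestResult:
    name: str
    mean_diff: float
    t_stat: float
    df: int
    p_raw: float
    p_bonferroni: float
    family_size: int
    n: int


@dataclass(frozen=True)
class RegressionResult:
    name: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def paired_t_test(x, y, family_size: int = 1, name: str = "") -> PairedTestResult:
    """Classical two-sided paired t-test with Bonferroni-adjusted p.

    ``p_bonferroni = min(1, p_raw * family_size)``.  Zero-variance
    differences give t = 0, p = 1 when the mean difference is zero, and
    are reported with p = 0 (the t -> infinity convention) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("complete cases only: NaNs present")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            t, p = 0.0, 1.0
        else:
            logger.warning("zero-variance nonzero differences in %s: p set to 0", name or "test")
            t, p = float("inf"), 0.0
    else:
        t, p = stats.ttest_rel(x, y)
    return PairedTestResult(
        name=name,
        mean_diff=float(d.mean()),
        t_stat=float(t),
        df=n - 1,
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p * family_size)),
        family_size=family_size,
        n=n,
    )


def linear_regression(x, y, name: str = "") -> RegressionResult:
    """Simple OLS of y on x with signed Pearson r and R^2.

    The p-value is the two-sided test of the slope on n - 2 degrees of
    freedom (equivalently of the correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-D arrays of equal length >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("x has zero variance: regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        name=name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=x.size,
    )


def run_condition_comparisons(
    cohort: CohortTable,
    decrements: pd.DataFrame | None = None,
    family_size: int | None = None,
) -> list[PairedTestResult]:
    """HF-vs-LF paired tests on A and tau for each variable, and on decrements.

    Produces 6 parameter tests (A, tau for IMVC, VA, QTW) plus, when a
    decrement-estimate table is supplied, one test per variable x IMVC
    level over subjects reachable in both conditions.  The Bonferroni
    family defaults to the number of tests actually executed.
    """
    specs: list[tuple[str, np.ndarray, np.ndarray]] = []
    for var in VARIABLES:
        for param, label in (("A_pct", "A"), ("tau_s", "tau")):
            try:
                x = cohort.column("HF", var, param)
                y = cohort.column("LF", var, param)
            except (KeyError, ValueError) as exc:
                logger.warning("skipping %s_%s HF vs LF: %s", label, var, exc)
                continue
            specs.append((f"{label}_{var}_HF_vs_LF", x, y))
    if decrements is not None:
        for (var, level), grp in decrements.groupby(["variable", "imvc_decrease"], sort=True):
            wide = grp.pivot(index="subject_id", columns="condition", values="dv_value").dropna()
            if len(wide) < 3 or not {"HF", "LF"} <= set(wide.columns):
                logger.warning("skipping decrement test %s at %g%%: too few pairs", var, level)
                continue
            specs.append(
                (
                    f"{var}_at_{level:g}pct_decrease_HF_vs_LF",
                    wide["HF"].to_numpy(),
                    wide["LF"].to_numpy(),
                )
            )
    family = family_size if family_size is not None else len(specs)
    return [paired_t_test(x, y, family_size=family, name=name) for name, x, y in specs]


#: The individual-parameter regressions reported for this design: VA-vs-Q_tw
#: asymptotes and curvature constants within each condition, the cross-condition
#: Q_tw asymptote relation, and the (non-significant) cross-condition VA and
#: IMVC asymptote checks.
CORRELATION_PLAN = (
    ("A_VA~A_QTW_HF", ("HF", "QTW", "A_pct"), ("HF", "VA", "A_pct")),
    ("A_VA~A_QTW_LF", ("LF", "QTW", "A_pct"), ("LF", "VA", "A_pct")),
    ("tau_VA~tau_QTW_HF", ("HF", "QTW", "tau_s"), ("HF", "VA", "tau_s")),
    ("tau_VA~tau_QTW_LF", ("LF", "QTW", "tau_s"), ("LF", "VA", "tau_s")),
    ("A_QTW_HF~A_QTW_LF", ("HF", "QTW", "A_pct"), ("LF", "QTW", "A_pct")),
    ("A_VA_HF~A_VA_LF", ("HF", "VA", "A_pct"), ("LF", "VA", "A_pct")),
    ("A_IMVC_HF~A_IMVC_LF", ("HF", "IMVC", "A_pct"), ("LF", "IMVC", "A_pct")),
)


def run_parameter_correlations(cohort: CohortTable) -> list[RegressionResult]:
    """The battery of individual-parameter regressions (see CORRELATION_PLAN)."""
    out = []
    for name, (cx, vx, px), (cy, vy, py) in CORRELATION_PLAN:
        out.append(linear_regression(cohort.column(cx, vx, px), cohort.column(cy, vy, py), name=name))
    return out


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Column-wise mean and sample SD of every parameter.

    Means are computed from the table as given; a table holding printed
    (rounded) parameters therefore summarizes the rounded values, which
    can differ from a summary rounded after averaging the raw ones.
    """
    params = [c for c in ("A_pct", "tau_s", "r_squared") if c in cohort.data.columns]
    g = cohort.data.groupby(["condition", "variable"], sort=True)[params]
    out = g.agg(["mean", lambda s: s.std(ddof=1) if len(s) > 1 else float("nan"), "count"])
    out.columns = [f"{p}_{stat}" for p, stat in
                   ((p, s) for p in params for s in ("mean", "sd", "n"))]
    return out.reset_index()


def normality_report(cohort: CohortTable) -> pd.DataFrame:
    """Shapiro-Wilk diagnostics of the paired HF-LF differences.

    Purely informational: it never gates the paired tests.
    """
    rows = []
    for var in VARIABLES:
        for param in ("A_pct", "tau_s"):
            d = cohort.column("HF", var, param) - cohort.column("LF", var, param)
            w, p = stats.shapiro(d)
            rows.append({"variable": var, "param": param, "shapiro_w": w, "p_value": p})
    return pd.DataFrame(rows)
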