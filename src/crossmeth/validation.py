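"""Validation-layer statistics: qPCR quantification and factorial ANOVA.

Covers relative quantification of qPCR data by the 2^-ddCt method (for both
mRNA expression and MeDIP bound-fraction enrichment), two-tailed two-sample
t-tests at alpha 0.05, and the two-way stress x age ANOVA with Fisher's LSD
post hoc comparisons used for developmental trajectories.

The two-sample test is Welch's (unequal variances) by default with a classical
pooled-variance switch.  The two-way ANOVA uses Type II sums of squares by
default — on the unbalanced cell counts typical of animal cohorts Type II main
effects are not contaminated by the interaction — with sequential (Type I) SS
available; on balanced designs the two coincide with the classical closed
forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .errors import InputError

ALPHA = 0.05


# ----------------------------------------------------------------- qPCR ----

def delta_delta_ct(measurements: pd.DataFrame, calibrator_group: str = "control",
                   group_col: str = "group", target_col: str = "ct_target",
                   reference_col: str = "ct_reference",
                   by: list[str] | None = None) -> pd.DataFrame:
    """Per-sample fold change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt subtracts the mean dCt
    of the calibrator group; fold = 2^-ddCt.  With ``by`` (e.g. ``["age"]``)
    the calibrator mean is computed within each stratum, so the calibrator is
    the control group at the same age.  ``percent_of_calibrator`` is the fold
    change scaled to calibrator = 100.
    """
    for col in (group_col, target_col, reference_col, *(by or [])):
        if col not in measurements.columns:
            raise InputError(f"Ct table lacks column {col!r}")
    out = measurements.copy()
    for col in (target_col, reference_col):
        vals = out[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise InputError(f"missing or non-finite Ct in column {col!r}")
    out["delta_ct"] = out[target_col] - out[reference_col]
    is_cal = out[group_col] == calibrator_group
    if not is_cal.any():
        raise InputError(f"calibrator group {calibrator_group!r} is empty")
    if by:
        cal_mean = (out.loc[is_cal].groupby(by)["delta_ct"].mean()
                    .rename("calibrator_mean"))
        out = out.merge(cal_mean, left_on=by, right_index=True, how="left")
        if out["calibrator_mean"].isna().any():
            stratum = out.loc[out["calibrator_mean"].isna(), by].iloc[0].tolist()
            raise InputError(f"no calibrator samples in stratum {stratum}")
    else:
        out["calibrator_mean"] = out.loc[is_cal, "delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - out["calibrator_mean"]
    out["fold_change"] = np.exp2(-out["delta_delta_ct"])
    out["percent_of_calibrator"] = 100.0 * out["fold_change"]
    return out.drop(columns=["calibrator_mean"])


def medip_enrichment(measurements: pd.DataFrame, calibrator_group: str = "control",
                     group_col: str = "group", bound_col: str = "ct_bound",
                     input_col: str = "ct_input",
                     by: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative bound-fraction enrichment from bound/input qPCR Ct values.

    Identical arithmetic to :func:`delta_delta_ct` with the input fraction as
    the reference channel.  Returns the per-sample table (``enrichment``
    column) and a per-group summary with mean and s.e.m.
    """
    per_sample = delta_delta_ct(
        measurements, calibrator_group=calibrator_group, group_col=group_col,
        target_col=bound_col, reference_col=input_col, by=by,
    ).rename(columns={"fold_change": "enrichment"})
    keys = (by or []) + [group_col]
    summary = (per_sample.groupby(keys)["enrichment"]
               .agg(mean="mean", sem=lambda x: x.sem(ddof=1), n="size")
               .reset_index())
    return per_sample, summary


# -------------------------------------------------------------- t-tests ----

@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float
    significant: bool


def welch_t_two_tailed(group_a, group_b, alpha: float = ALPHA,
                       equal_var: bool = False) -> TTestResult:
    """Two-tailed two-sample t-test (Welch by default, pooled on request)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("need >=2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: identical-variance-free convention
        equal_means = a.mean() == b.mean()
        df = a.size + b.size - 2
        return TTestResult(0.0 if equal_means else np.inf * np.sign(a.mean() - b.mean()),
                           float(df), 1.0 if equal_means else 0.0, not equal_means)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    return TTestResult(float(res.statistic), df, float(res.pvalue),
                       bool(res.pvalue < alpha))


# ---------------------------------------------------------------- ANOVA ----

@dataclass
class AnovaTerm:
    ss: float
    df: int
    f: float
    p_value: float


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA table plus what Fisher's LSD needs."""

    factor_a: str
    factor_b: str
    terms: dict[str, AnovaTerm]   # factor_a, factor_b, interaction
    residual_ss: float
    residual_df: int
    nobs: int
    cell_means: pd.DataFrame      # factor_a levels x factor_b levels
    cell_counts: pd.DataFrame
    ss_type: int

    @property
    def mse(self) -> float:
        return self.residual_ss / self.residual_df


def _check_design(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> None:
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise InputError(f"data lacks column {col!r}")
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise InputError("both factors need >= 2 levels")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise InputError(f"empty design cell ({factor_a}={la!r}, "
                                 f"{factor_b}={lb!r})")


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  factor_a: str = "group", factor_b: str = "age",
                  ss_type: int = 2) -> AnovaResult:
    """Two-way factorial ANOVA with interaction.

    ``ss_type`` 2 (default) or 1 (sequential).  On balanced designs both equal
    the classical closed-form sums of squares.  A degenerate dataset with zero
    total variance reports SS 0, F 0, p 1 for every term.
    """
    _check_design(data, value, factor_a, factor_b)
    if ss_type not in (1, 2):
        raise InputError("ss_type must be 1 or 2")
    y = data[value].to_numpy(dtype=float)
    n = len(data)
    cell_means = data.pivot_table(index=factor_a, columns=factor_b, values=value,
                                  aggfunc="mean", observed=True)
    cell_counts = data.pivot_table(index=factor_a, columns=factor_b, values=value,
                                   aggfunc="size", observed=True)
    df_a = data[factor_a].nunique() - 1
    df_b = data[factor_b].nunique() - 1
    df_ab = df_a * df_b
    df_res = n - (df_a + 1) * (df_b + 1)
    if df_res < 1:
        raise InputError("no residual degrees of freedom (one observation per cell)")

    total_ss = float(((y - y.mean()) ** 2).sum())
    if total_ss <= 1e-12 * max(1.0, float((y ** 2).sum())):
        zero = AnovaTerm(0.0, 0, 0.0, 1.0)
        terms = {factor_a: AnovaTerm(0.0, df_a, 0.0, 1.0),
                 factor_b: AnovaTerm(0.0, df_b, 0.0, 1.0),
                 "interaction": AnovaTerm(0.0, df_ab, 0.0, 1.0)}
        return AnovaResult(factor_a, factor_b, terms, 0.0, df_res, n,
                           cell_means, cell_counts, ss_type)

    frame = data[[value, factor_a, factor_b]].copy()
    frame.columns = ["y", "fa", "fb"]
    fit = ols("y ~ C(fa) * C(fb)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=ss_type)
    key = {"C(fa)": factor_a, "C(fb)": factor_b, "C(fa):C(fb)": "interaction"}
    residual_ss = float(table.loc["Residual", "sum_sq"])
    if residual_ss <= 1e-12 * total_ss:  # perfect cell fit up to rounding
        residual_ss = 0.0
    residual_df = int(table.loc["Residual", "df"])
    mse = residual_ss / residual_df
    terms = {}
    for row, name in key.items():
        ss = float(table.loc[row, "sum_sq"])
        ss = max(ss, 0.0)
        df = int(table.loc[row, "df"])
        if mse > 0:
            f = ss / df / mse
            p = float(stats.f.sf(f, df, residual_df))
        else:  # perfect fit: only effects with SS>0 are "infinitely" significant
            f, p = (np.inf, 0.0) if ss > 0 else (0.0, 1.0)
        terms[name] = AnovaTerm(ss, df, f, p)
    return AnovaResult(factor_a, factor_b, terms, residual_ss, residual_df, n,
                       cell_means, cell_counts, ss_type)


def fisher_lsd(anova: AnovaResult, alpha: float = ALPHA) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons of factor-A levels at each factor-B level.

    Each comparison is t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)) on
    the ANOVA residual degrees of freedom, two-sided, with no multiplicity
    adjustment.
    """
    if anova.residual_df < 1:
        raise InputError("LSD needs residual df >= 1")
    if anova.mse <= 0:
        raise InputError("LSD undefined with zero residual mean square")
    rows = []
    levels_a = list(anova.cell_means.index)
    for lb in anova.cell_means.columns:
        for i, j in [(i, j) for i in range(len(levels_a))
                     for j in range(i + 1, len(levels_a))]:
            la, la2 = levels_a[i], levels_a[j]
            m1, m2 = anova.cell_means.loc[la, lb], anova.cell_means.loc[la2, lb]
            n1, n2 = anova.cell_counts.loc[la, lb], anova.cell_counts.loc[la2, lb]
            diff = m1 - m2
            se = np.sqrt(anova.mse * (1.0 / n1 + 1.0 / n2))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), anova.residual_df))
            rows.append((lb, la, la2, m1, m2, diff, float(t), anova.residual_df,
                         p, p < alpha))
    return pd.DataFrame(rows, columns=[
        anova.factor_b, f"{anova.factor_a}_1", f"{anova.factor_a}_2",
        "mean_1", "mean_2", "diff", "t", "df", "p_value", "significant"])
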