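"""Inferential layer: repeated-measures ANOVA, FDR-corrected pairwise
t-tests, relatedness regressions with confidence bands, thirds-split
facilitation/interference tests, pooled-set regressions, and the
NoChange-baselined between-experiment order contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .design import Condition, CONDITION_ORDER

__all__ = [
    "AnovaResult",
    "RegressionFit",
    "rm_anova",
    "pairwise_t_fdr",
    "relatedness_regression",
    "thirds_split_test",
    "combine_stimulus_sets",
    "order_contrast",
]


@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    note: str = ""


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    p_intercept: float
    slope_se: float
    intercept_se: float
    n: int
    band_x: np.ndarray = field(repr=False, default=None)
    band_lower: np.ndarray = field(repr=False, default=None)
    band_upper: np.ndarray = field(repr=False, default=None)
    band_fit: np.ndarray = field(repr=False, default=None)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se


def _as_wide(data) -> pd.DataFrame:
    """Accept a wide subjects x conditions frame of recall proportions."""
    wide = pd.DataFrame(data)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"missing condition cell for subject {bad}")
    return wide


def rm_anova(wide: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA over condition means.

    ``wide`` holds one recall proportion per subject (rows) and condition
    (columns).  ``F = MS_condition / MS_(condition x subject)`` with
    ``df = (k-1, (k-1)(n-1))``.
    """
    wide = _as_wide(wide)
    x = wide.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = x - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    scale = np.mean(x**2) + 1.0
    if ms_cond < 1e-14 * scale:
        ms_cond = 0.0
    if ms_err < 1e-14 * scale:
        ms_err = 0.0
    if ms_err == 0.0:
        if ms_cond == 0.0:
            return AnovaResult(0.0, df_num, df_den, 1.0, note="degenerate: no variance")
        return AnovaResult(np.inf, df_num, df_den, 0.0, note="zero error variance")
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_num, df_den))
    return AnovaResult(float(F), df_num, df_den, p)


def pairwise_t_fdr(wide: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise within-subject t-tests with Benjamini-Hochberg FDR.

    One FDR family per call (all condition pairs of one experiment).
    """
    wide = _as_wide(wide)
    cols = [c.value if isinstance(c, Condition) else c for c in wide.columns]
    rows = []
    for a, b in itertools.combinations(range(len(cols)), 2):
        res = sps.ttest_rel(wide.iloc[:, a], wide.iloc[:, b])
        rows.append(
            {
                "condition_a": cols[a],
                "condition_b": cols[b],
                "mean_diff": float(wide.iloc[:, a].mean() - wide.iloc[:, b].mean()),
                "t": float(res.statistic),
                "df": int(len(wide) - 1),
                "p_raw": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")[1]
    return out


def relatedness_regression(
    table: pd.DataFrame,
    value_col: str = "memorability",
    x_col: str = "relatedness",
    n_grid: int = 50,
    band_level: float = 0.95,
) -> RegressionFit:
    """OLS of a per-pair value on relatedness, with a mean-prediction band.

    The confidence band is the pointwise CI for the conditional mean on an
    evenly spaced relatedness grid.
    """
    df = pd.DataFrame(table)[[x_col, value_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 pairs for a regression")
    x = df[x_col].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in relatedness")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(
        alpha=1.0 - band_level
    )
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        p_intercept=float(fit.pvalues[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        n=len(df),
        band_x=grid,
        band_lower=pred["mean_ci_lower"].to_numpy(),
        band_upper=pred["mean_ci_upper"].to_numpy(),
        band_fit=pred["mean"].to_numpy(),
    )


def thirds_split_test(
    table: pd.DataFrame,
    value_col: str = "memorability",
    x_col: str = "relatedness",
) -> pd.DataFrame:
    """Rank pairs by relatedness, split into thirds, t-test each against 0.

    With 45 pairs each third holds 15 values (t with df=14); a remainder is
    assigned to the middle third and noted.
    """
    df = pd.DataFrame(table)[[x_col, value_col]].dropna().sort_values(x_col)
    n = len(df)
    base, rem = divmod(n, 3)
    sizes = [base, base + rem, base]
    note = "" if rem == 0 else f"remainder of {rem} assigned to middle third"
    labels = ["low", "mid", "high"]
    rows = []
    start = 0
    for label, size in zip(labels, sizes):
        vals = df[value_col].to_numpy()[start : start + size]
        start += size
        if np.allclose(vals, vals * 0.0) and np.ptp(vals) == 0:
            t, p = 0.0, 1.0
        else:
            res = sps.ttest_1samp(vals, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "third": label,
                "n": size,
                "df": size - 1,
                "mean": float(vals.mean()),
                "t": t,
                "p": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def combine_stimulus_sets(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    value_col: str = "memorability",
    **kwargs,
) -> RegressionFit:
    """Pool two stimulus sets' per-pair tables on the shared GloVe metric
    and refit the relatedness regression on the concatenation."""
    for t in (table_a, table_b):
        if t.attrs.get("metric") != "glove":
            raise ValueError(
                "combined-set analysis requires GloVe relatedness in both tables "
                f"(got {t.attrs.get('metric')!r})"
            )
    pooled = pd.concat([table_a, table_b], ignore_index=True)
    pooled.attrs["metric"] = "glove"
    return relatedness_regression(pooled, value_col=value_col, **kwargs)


def order_contrast(
    wide_a: pd.DataFrame,
    wide_b: pd.DataFrame,
    label_a: str = "retroactive",
    label_b: str = "proactive",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """NoChange-baselined between-experiment contrasts.

    For each subject, every condition mean is re-expressed relative to that
    subject's own NoChange mean; each non-NoChange condition is then
    compared between the two experiments with a Welch t-test, and the four
    contrasts form one Benjamini-Hochberg FDR family.  Positive
    ``mean_diff`` means the ``wide_a`` experiment retained more.
    """
    results = []
    no_change = Condition.NO_CHANGE.value
    for wide in (wide_a, wide_b):
        if no_change not in wide.columns:
            raise ValueError(f"missing {no_change} data in one experiment")
    rel_a = wide_a.sub(wide_a[no_change], axis=0)
    rel_b = wide_b.sub(wide_b[no_change], axis=0)
    for cond in CONDITION_ORDER:
        c = cond.value
        if c == no_change:
            continue
        a, b = rel_a[c].dropna(), rel_b[c].dropna()
        res = sps.ttest_ind(a, b, equal_var=False)
        if np.isnan(res.statistic):  # identical inputs, zero variance
            t, p, dof = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
        results.append(
            {
                "condition": c,
                f"mean_{label_a}": float(a.mean()),
                f"mean_{label_b}": float(b.mean()),
                "mean_diff": float(a.mean() - b.mean()),
                "t": t,
                "df": dof,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(results)
    out["p_fdr"] = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")[1]
    return out
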