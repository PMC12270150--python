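"""Outlier handling, replicate aggregation, and inferential statistics.

The inferential conventions mirror the study design: technical replicates
(wells) are averaged within an experiment, experiments are the units of
analysis (n = 3-4), summaries are means ± SEM across experiments, outliers
are removed with Tukey's fences at both the technical and the experimental
level, homoscedasticity is checked with the Brown-Forsythe variant of
Levene's test, dose-response slopes are tested with an F test on the OLS
slope, and group comparisons use one-way ANOVA with Dunnett's post hoc
(each dose vs control) or two-way ANOVA with Tukey's HSD over the
arm x condition cell means.  Effect sizes are Cohen's d with a 95%
normal-theory confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult", "EffectSize", "tukey_fences", "remove_technical_outliers",
    "aggregate", "cohens_d", "slope_test", "one_way_dunnett", "two_way_tukey",
    "tukey_pairwise", "levene_test", "t_test", "anova_suite",
]


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TestResult:
    test: str
    label: str
    statistic: float
    df: tuple
    p: float
    effect: EffectSize | None = None
    slope: dict | None = None

    def to_dict(self) -> dict:
        out = {"test": self.test, "label": self.label,
               "statistic": self.statistic, "df": list(self.df), "p": self.p}
        if self.effect is not None:
            out["effect"] = {"d": self.effect.d, "ci_low": self.effect.ci_low,
                             "ci_high": self.effect.ci_high}
        if self.slope is not None:
            out["slope"] = self.slope
        return out


def tukey_fences(values, k: float = 1.5) -> np.ndarray:
    """Inlier mask: value within [Q1 - k*IQR, Q3 + k*IQR], quartiles by
    linear interpolation.  Lists shorter than 4 are all inliers (quartiles
    of so few points are meaningless)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return np.ones(v.shape, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


def remove_technical_outliers(df: pd.DataFrame, value: str, keys: list[str],
                              k: float = 1.5) -> pd.DataFrame:
    """Drop rows outside Tukey's fences within each ``keys`` group."""
    mask = df.groupby(keys, dropna=False)[value].transform(
        lambda s: pd.Series(tukey_fences(s.to_numpy(), k), index=s.index)
    )
    return df[mask.astype(bool)]


def aggregate(df: pd.DataFrame, value: str, condition_keys: list[str],
              experiment_key: str = "experiment_id",
              k_technical: float | None = 1.5,
              k_experimental: float | None = 1.5) -> pd.DataFrame:
    """Two-level aggregation: wells -> per-experiment means -> mean ± SEM.

    Tukey's fences are applied to the well values within each
    (experiment, condition) group (technical level) and then to the
    per-experiment means within each condition (experimental level);
    pass ``None`` to skip a level.  SEM is computed across experiment
    means (ddof=1), never across wells.
    """
    work = df.dropna(subset=[value])
    if k_technical is not None:
        work = remove_technical_outliers(work, value, condition_keys + [experiment_key], k_technical)
    per_exp = work.groupby(condition_keys + [experiment_key], dropna=False)[value].mean().reset_index()
    if k_experimental is not None:
        per_exp = remove_technical_outliers(per_exp, value, condition_keys, k_experimental)
    out = per_exp.groupby(condition_keys, dropna=False)[value].agg(["mean", "sem", "count"])
    out.columns = ["mean", "sem", "n"]
    return out.reset_index()


def cohens_d(group_a, group_b) -> EffectSize:
    """Cohen's d (pooled SD) with a 95% CI from the normal-theory SE
    sqrt((na+nb)/(na*nb) + d^2/(2*(na+nb-2)))."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("cohens_d needs >= 2 observations per group")
    dof = na + nb - 2
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof)
    if pooled == 0:
        return EffectSize(float("nan"), float("nan"), float("nan"))
    d = (a.mean() - b.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * dof))
    tcrit = sps.t.ppf(0.975, dof)
    return EffectSize(d, d - tcrit * se, d + tcrit * se)


def slope_test(x, y, label: str = "slope") -> TestResult:
    """OLS slope with an F test (F(1, n-2)) against slope = 0."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.unique(x).size < 3:
        raise ValueError("slope_test needs >= 3 distinct x values")
    res = sps.linregress(x, y)
    n = x.size
    F = (res.slope / res.stderr) ** 2 if res.stderr > 0 else float("inf")
    return TestResult(
        test="SLOPE_F", label=label, statistic=float(F), df=(1, n - 2),
        p=float(res.pvalue),
        slope={"estimate": float(res.slope), "se": float(res.stderr),
               "intercept": float(res.intercept), "r2": float(res.rvalue**2)},
    )


def levene_test(groups: list[np.ndarray], label: str = "levene") -> TestResult:
    """Brown-Forsythe: Levene's test on absolute deviations from medians."""
    stat, p = sps.levene(*groups, center="median")
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult("LEVENE", label, float(stat), (k - 1, n - k), float(p))


def t_test(a, b, label: str = "t") -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.ttest_ind(a, b)
    eff = cohens_d(a, b) if min(a.size, b.size) >= 2 else None
    return TestResult("T_TEST", label, float(res.statistic),
                      (a.size + b.size - 2,), float(res.pvalue), effect=eff)


def one_way_dunnett(df: pd.DataFrame, value: str, group: str, control,
                    rng=None, label: str = "") -> list[TestResult]:
    """One-way ANOVA omnibus plus Dunnett's many-to-one comparisons.

    Observations should be per-experiment means.  Adjusted p-values come
    from the equicorrelated multivariate-t distribution (seeded randomized
    integration inside scipy, tolerance ~1e-3).
    """
    labels = [g for g in df[group].unique() if g != control]
    ctrl = df.loc[df[group] == control, value].to_numpy()
    samples = [df.loc[df[group] == g, value].to_numpy() for g in labels]
    if not samples or ctrl.size == 0:
        raise ValueError("one_way_dunnett needs a control group and >= 1 comparison group")
    groups = [ctrl] + samples
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    out = [TestResult("ONE_WAY_ANOVA", f"{label} omnibus", float(F), (k - 1, n - k), float(p))]
    res = sps.dunnett(*samples, control=ctrl, rng=rng)
    for g, stat, pv, samp in zip(labels, res.statistic, res.pvalue, samples):
        eff = cohens_d(samp, ctrl) if min(samp.size, ctrl.size) >= 2 else None
        out.append(TestResult("DUNNETT", f"{label} {g} vs {control}",
                              float(stat), (n - k,), float(pv), effect=eff))
    return out


def tukey_pairwise(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int]:
    """Tukey-Kramer HSD over cell means: (q statistics, adjusted p, error df).

    p-values come from the studentized-range distribution via the
    table-interpolated ``psturng`` (the standard implementation in
    statsmodels); values are effectively clipped to [0.001, 0.9].
    """
    from statsmodels.stats.libqsturng import psturng

    k = len(groups)
    sizes = np.array([g.size for g in groups])
    if (sizes < 2).any():
        raise ValueError("tukey_pairwise needs >= 2 observations per cell")
    dof = int(sizes.sum() - k)
    means = np.array([g.mean() for g in groups])
    mse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups) / dof
    q = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / sizes[i] + 1 / sizes[j]))
            qij = np.abs(means[i] - means[j]) / se if se > 0 else np.inf
            pij = 0.001 if np.isinf(qij) else float(np.clip(np.asarray(psturng(qij, k, dof)).ravel()[0], 0, 1))
            q[i, j] = q[j, i] = qij
            p[i, j] = p[j, i] = pij
    return q, p, dof


def two_way_tukey(df: pd.DataFrame, value: str, factor_a: str, factor_b: str,
                  label: str = "") -> list[TestResult]:
    """Two-way ANOVA (type II) plus Tukey's HSD over all cell means."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = term.replace("C(_a)", factor_a).replace("C(_b)", factor_b)
        out.append(TestResult(
            "TWO_WAY_ANOVA", f"{label} {name}", float(row["F"]),
            (int(row["df"]), int(table.loc["Residual", "df"])), float(row["PR(>F)"]),
        ))
    cells = [(a, b) for (a, b), _ in work.groupby(["_a", "_b"], sort=True)]
    groups = [work[(work["_a"] == a) & (work["_b"] == b)]["_y"].dropna().to_numpy()
              for a, b in cells]
    q, p, dof = tukey_pairwise(groups)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            out.append(TestResult(
                "TUKEY_HSD",
                f"{label} {cells[i][0]}|{cells[i][1]} vs {cells[j][0]}|{cells[j][1]}",
                float(q[i, j]), (dof,), float(p[i, j]),
            ))
    return out


def anova_suite(df: pd.DataFrame, design: str, value: str = "value", *,
                group: str = "group", factor_a: str = "arm", factor_b: str = "group",
                control=None, rng=None, label: str = "") -> list[TestResult]:
    """Dispatch the study's ANOVA designs and append the Levene check."""
    if design == "ONE_WAY_DUNNETT":
        results = one_way_dunnett(df, value, group, control, rng=rng, label=label)
        groups = [g[value].to_numpy() for _, g in df.groupby(group)]
    elif design == "TWO_WAY_TUKEY":
        results = two_way_tukey(df, value, factor_a, factor_b, label=label)
        groups = [g[value].to_numpy() for _, g in df.groupby([factor_a, factor_b])]
    else:
        raise ValueError(f"unknown design {design!r}")
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) >= 2:
        results.append(levene_test(usable, label=f"{label} homoscedasticity"))
    return results
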