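"""Cohort-level statistics over per-NMJ records.

The replication unit is the mouse: per-NMJ labels are first aggregated
to per-mouse proportions, and groups are summarized as mean ± s.e.m.
over mice. Two-group comparisons use unpaired two-sided t-tests;
factorial designs use a two-way ANOVA (type-II sums of squares, robust
to mildly unbalanced mouse counts) with Sidak-adjusted pairwise cell
comparisons on the pooled residual variance. The Sidak adjustment is
p_adj = 1 − (1 − p)^m over the explicitly named comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .classify import NMJRecord, bin_myonuclear_counts

__all__ = [
    "CohortSummary",
    "RegressionResult",
    "ComparisonResult",
    "summarize_groups",
    "regress_size_vs_nuclei",
    "permutation_regression_pvalues",
    "sidak_adjust",
    "run_tests",
]


@dataclass
class RegressionResult:
    """Ordinary least squares of a size measure on myonuclear count."""

    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


@dataclass
class ComparisonResult:
    name: str
    statistic: float
    p_raw: float
    p_sidak: float
    significant: bool  # at 0.05 after adjustment


@dataclass
class CohortSummary:
    """Group-level aggregation (mouse = replication unit)."""

    per_mouse: pd.DataFrame
    per_group: pd.DataFrame
    single_mouse_groups: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "per_mouse": self.per_mouse.to_dict(orient="records"),
            "per_group": self.per_group.to_dict(orient="records"),
            "single_mouse_groups": [list(g) if isinstance(g, tuple) else g
                                    for g in self.single_mouse_groups],
        }


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([asdict(r) for r in records])


def summarize_groups(
    records: Sequence[NMJRecord] | pd.DataFrame,
    group_cols: Sequence[str] = ("genotype", "age"),
    mouse_col: str = "mouse",
) -> CohortSummary:
    """Aggregate NMJ records: NMJ → mouse → group (in that fixed order).

    Per mouse: proportions of partially innervated, completely
    denervated and post-synaptically degenerated NMJs, mean myonuclear
    count, and the myonuclear cluster-size bin distribution. Per group:
    mean and s.e.m. over mice; groups with a single mouse are flagged
    (s.e.m. undefined → NaN).
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    if mouse_col not in df.columns:
        raise ValueError(f"records lack the mouse id column {mouse_col!r}")
    group_cols = list(group_cols)

    def per_mouse(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        bins = bin_myonuclear_counts(list(g["myonuclear_count"]))
        return pd.Series({
            "n_nmjs": n,
            "prop_partially_innervated": (g["pre_class"] == "partially_innervated").mean(),
            "prop_completely_denervated": (g["pre_class"] == "completely_denervated").mean(),
            "prop_post_degenerated": (g["post_class"] == "degenerated").mean(),
            "mean_myonuclear_count": g["myonuclear_count"].mean(),
            "prop_nuclei_0_2": bins["0-2"],
            "prop_nuclei_3_4": bins["3-4"],
            "prop_nuclei_gt4": bins[">4"],
        })

    # sort so output is independent of input row order
    df = df.sort_values(group_cols + [mouse_col, "id"], kind="mergesort")
    mouse = (
        df.groupby(group_cols + [mouse_col], sort=True)
        .apply(per_mouse, include_groups=False)
        .reset_index()
    )

    value_cols = [c for c in mouse.columns if c not in group_cols + [mouse_col]]
    grp = mouse.groupby(group_cols, sort=True)
    means = grp[value_cols].mean()
    sems = grp[value_cols].sem(ddof=1)
    n_mice = grp.size().rename("n_mice")
    per_group = means.join(sems, rsuffix="_sem").join(n_mice).reset_index()
    single = [tuple(idx) if isinstance(idx, tuple) else idx
              for idx, n in n_mice.items() if n < 2]
    return CohortSummary(per_mouse=mouse, per_group=per_group, single_mouse_groups=single)


def _ols_line(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.ptp(x) == 0:
        raise ValueError("myonuclear counts have zero variance; regression undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), r2=float(res.rvalue ** 2),
        p=float(res.pvalue), n=len(x),
    )


def regress_size_vs_nuclei(
    records: Sequence[NMJRecord] | pd.DataFrame,
    size_cols: Sequence[str] = ("volume_um3", "cumulative_intensity"),
    count_col: str = "myonuclear_count",
) -> dict[str, RegressionResult]:
    """OLS of NMJ size measures on post-synaptic myonuclear count.

    Returns one :class:`RegressionResult` per size column (NMJ volume
    and cumulative AChR intensity by default), each with slope,
    intercept, Pearson r, r² and two-sided p.
    """
    df = _records_frame(records)
    out = {}
    for col in size_cols:
        sub = df[[count_col, col]].dropna()
        sub = sub[np.isfinite(sub[col]) & np.isfinite(sub[count_col])]
        if len(sub) < 3:
            raise ValueError(f"need >= 3 finite records for {col}, got {len(sub)}")
        out[col] = _ols_line(sub[count_col].to_numpy(float), sub[col].to_numpy(float))
    return out


def permutation_regression_pvalues(
    x: np.ndarray, y: np.ndarray, n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """OLS two-sided p-values after permuting x against y (null ensemble).

    Vectorized via the correlation-to-t transform; used to check that
    the regression p is calibrated (uniform under the null).
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    perms = np.stack([rng.permutation(x) for _ in range(n_permutations)])
    xc = perms - perms.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    r = (xc @ yc) / (np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum()) + 1e-300)
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2 * sps.t.sf(np.abs(t), df=n - 2)


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiple-comparison adjustment p_adj = 1 − (1 − p)^m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m if np.ndim(p) else float(
        1.0 - (1.0 - float(p)) ** m
    )


def run_tests(
    data: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    comparisons: Sequence[tuple[dict, dict]] | None = None,
    alpha: float = 0.05,
) -> dict:
    """The study's test battery on (typically per-mouse) summary values.

    One factor with two levels → unpaired two-sided Student t-test.
    Two factors → two-way ANOVA (type-II SS) plus pairwise cell
    comparisons (pooled residual variance) with Sidak adjustment over
    the named family. Empty design cells raise a design error.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("run_tests supports one or two factors")
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"factor {f!r} missing from data")
    levels = [sorted(data[f].unique()) for f in factors]
    # every design cell must be populated
    cells = data.groupby(factors, sort=True)[dv].agg(["mean", "count"])
    n_expected = int(np.prod([len(lv) for lv in levels]))
    if len(cells) != n_expected or (cells["count"] == 0).any():
        raise ValueError("design has empty cells; cannot run the factorial battery")

    out: dict = {"alpha": alpha}
    if len(factors) == 1 and len(levels[0]) == 2:
        a = data.loc[data[factors[0]] == levels[0][0], dv].to_numpy(float)
        b = data.loc[data[factors[0]] == levels[0][1], dv].to_numpy(float)
        t, p = sps.ttest_ind(a, b)
        if not np.isfinite(t):  # identical constant groups
            t, p = 0.0, 1.0
        out["test"] = "student_t"
        out["comparisons"] = [ComparisonResult(
            name=f"{levels[0][0]} vs {levels[0][1]}",
            statistic=float(t), p_raw=float(p), p_sidak=float(p),
            significant=bool(p < alpha),
        )]
        return out

    # factorial: two-way ANOVA, type II
    d = data.rename(columns={dv: "_dv"}).copy()
    formula = "_dv ~ " + " * ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out["test"] = "two_way_anova_sidak"
    out["anova"] = {
        str(row): {"F": float(anova.loc[row, "F"]), "p": float(anova.loc[row, "PR(>F)"])}
        for row in anova.index if row != "Residual"
    }
    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_resid = float(anova.loc["Residual", "df"])

    if comparisons is None:
        # default family: within each level of the first factor, compare
        # the levels of the second pairwise
        comparisons = []
        lv1, lv2 = levels
        for a in lv1:
            for i in range(len(lv2)):
                for j in range(i + 1, len(lv2)):
                    comparisons.append((
                        {factors[0]: a, factors[1]: lv2[i]},
                        {factors[0]: a, factors[1]: lv2[j]},
                    ))
    m = len(comparisons)
    results = []
    for sel_a, sel_b in comparisons:
        ga = data.loc[np.logical_and.reduce([data[k] == v for k, v in sel_a.items()]), dv]
        gb = data.loc[np.logical_and.reduce([data[k] == v for k, v in sel_b.items()]), dv]
        if len(ga) == 0 or len(gb) == 0:
            raise ValueError(f"comparison {sel_a} vs {sel_b} selects an empty cell")
        se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
        t = (ga.mean() - gb.mean()) / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(t), df=df_resid) if se > 0 else 1.0
        p_adj = sidak_adjust(float(p), m)
        results.append(ComparisonResult(
            name=f"{sel_a} vs {sel_b}",
            statistic=float(t), p_raw=float(p), p_sidak=float(p_adj),
            significant=bool(p_adj < alpha),
        ))
    out["comparisons"] = results
    return out
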