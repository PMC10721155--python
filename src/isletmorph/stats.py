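"""Statistical battery for cohort comparisons.

Conventions: all tests are two-tailed; groups with unequal variance are
natural-log transformed before testing; p < 0.05 counts as significant and
0.05 <= p < 0.1 as a statistical trend; outliers, if any, are removed with
an iterative two-sided Grubbs test.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "CorrelationResult",
    "significance_category",
    "variance_check_log_transform",
    "two_group_test",
    "two_way_anova",
    "rm_two_way_anova",
    "pearson_correlation",
    "grubbs_critical_value",
    "grubbs_remove_outliers",
]

logger = logging.getLogger("isletmorph")


def significance_category(p: float) -> str:
    """Significance convention: ``significant`` (p<0.05), ``trend`` (0.05<=p<0.1), ``ns``."""
    if not (0 <= p <= 1 or math.isnan(p)):
        raise ValueError(f"p out of range: {p}")
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "ns"


@dataclass
class StatResult:
    """One statistical comparison."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    direction: str = ""  # sign of the (first) effect, "+", "-" or ""
    posthoc: pd.DataFrame | None = None
    category: str = ""
    transform: str = "none"  # "none" | "log"
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.category:
            self.category = significance_category(self.p)


@dataclass
class CorrelationResult:
    """Pearson correlation with the accompanying simple linear regression."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")

    @property
    def category(self) -> str:
        return significance_category(self.p)


def _equal_variance_p(groups: list[np.ndarray]) -> float:
    """Two-sided F test for 2 groups, Levene (median-centred) otherwise."""
    if len(groups) == 2:
        v1, v2 = np.var(groups[0], ddof=1), np.var(groups[1], ddof=1)
        if v1 == 0 and v2 == 0:
            return 1.0
        if min(v1, v2) == 0:
            return 0.0
        f = v1 / v2
        d1, d2 = len(groups[0]) - 1, len(groups[1]) - 1
        p = 2.0 * min(sps.f.cdf(f, d1, d2), sps.f.sf(f, d1, d2))
        return float(min(p, 1.0))
    return float(sps.levene(*groups, center="median").pvalue)


def variance_check_log_transform(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[list[np.ndarray], str]:
    """Log-transform all groups when their variances are detectably unequal.

    An F test (2 groups) or Levene test (>2) at ``alpha`` decides; the
    natural log is applied to every group or to none.  Unequal variance with
    non-positive values present yields a warning and no transform.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if _equal_variance_p(groups) >= alpha:
        return groups, "none"
    if any((g <= 0).any() for g in groups):
        warnings.warn(
            "unequal variance detected but non-positive values prevent the "
            "log transform; proceeding untransformed",
            stacklevel=2,
        )
        return groups, "none"
    return [np.log(g) for g in groups], "log"


def two_group_test(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    welch: bool = False,
    check_variance: bool = True,
) -> StatResult:
    """Two-tailed Student's t test between two groups.

    Groups with unequal variance are log transformed first (recorded in
    ``transform``).  ``welch=True`` switches to the unequal-variance Welch
    form.  Zero variance in both groups raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    transform = "none"
    if check_variance and not paired:
        (x, y), transform = variance_check_log_transform([x, y])
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            raise ValueError("zero variance in both groups")
        raise ValueError("zero variance in both groups; t undefined")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        res = sps.ttest_rel(x, y)
        df = (float(len(x) - 1),)
        name = "paired t"
    elif welch:
        res = sps.ttest_ind(x, y, equal_var=False)
        df = (float(res.df),)
        name = "Welch t"
    else:
        res = sps.ttest_ind(x, y, equal_var=True)
        df = (float(len(x) + len(y) - 2),)
        name = "Student t"
    t = float(res.statistic)
    return StatResult(
        test=name,
        statistic=t,
        df=df,
        p=float(res.pvalue),
        direction="+" if t > 0 else ("-" if t < 0 else ""),
        transform=transform,
    )


def _cell_label(a, b) -> str:
    return f"{a}:{b}"


def _posthoc_cells(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str, method: str
) -> pd.DataFrame:
    """Pairwise comparison of the A x B cells, Bonferroni or Tukey adjusted."""
    cells = {
        _cell_label(a, b): sub[value].to_numpy(dtype=float)
        for (a, b), sub in df.groupby([factor_a, factor_b], sort=True)
    }
    if method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = df.apply(lambda r: _cell_label(r[factor_a], r[factor_b]), axis=1)
        res = pairwise_tukeyhsd(df[value].to_numpy(dtype=float), labels.to_numpy())
        table = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        return pd.DataFrame(
            {
                "contrast": table["group1"] + " vs " + table["group2"],
                "p_adj": table["p-adj"].astype(float),
            }
        )
    if method != "bonferroni":
        raise ValueError(f"unknown post hoc method {method!r}")
    pairs = list(itertools.combinations(sorted(cells), 2))
    rows = []
    for c1, c2 in pairs:
        t = sps.ttest_ind(cells[c1], cells[c2], equal_var=True)
        rows.append(
            {"contrast": f"{c1} vs {c2}", "p_adj": min(1.0, float(t.pvalue) * len(pairs))}
        )
    return pd.DataFrame(rows)


def two_way_anova(
    df: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    posthoc: str,
) -> StatResult:
    """Two-way factorial ANOVA (type-II sums of squares) with post hoc tests.

    Reports the F and p of both main effects and the interaction in
    ``effects``; ``statistic``/``p`` carry the interaction term.  The post
    hoc method (``"bonferroni"`` or ``"tukey"``) must be named explicitly.
    Empty design cells raise, naming the cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for fac in (factor_a, factor_b):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    sizes = df.groupby([factor_a, factor_b]).size()
    full = pd.MultiIndex.from_product(
        [df[factor_a].unique(), df[factor_b].unique()]
    )
    missing = [c for c in full if c not in sizes.index or sizes[c] < 2]
    if missing:
        raise ValueError(f"empty or singleton design cells: {missing}")

    work = df[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "A", factor_b: "B"}
    )
    if np.ptp(work["y"].to_numpy(dtype=float)) == 0.0:
        # constant response: no signal by definition (0/0 in the F ratios)
        effects = {
            key: {"F": 0.0, "df": float("nan"), "p": 1.0}
            for key in (factor_a, factor_b, f"{factor_a}:{factor_b}")
        }
        return StatResult(
            test="two-way ANOVA", statistic=0.0, df=(float("nan"), float("nan")),
            p=1.0, posthoc=_posthoc_cells(df, value, factor_a, factor_b, posthoc),
            effects=effects,
        )
    model = smf.ols("y ~ C(A) * C(B)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {}
    for term, key in (("C(A)", factor_a), ("C(B)", factor_b),
                      ("C(A):C(B)", f"{factor_a}:{factor_b}")):
        effects[key] = {
            "F": float(table.loc[term, "F"]),
            "df": float(table.loc[term, "df"]),
            "p": float(table.loc[term, "PR(>F)"]),
        }
    inter = effects[f"{factor_a}:{factor_b}"]
    return StatResult(
        test="two-way ANOVA",
        statistic=inter["F"],
        df=(inter["df"], float(table.loc["Residual", "df"])),
        p=inter["p"],
        posthoc=_posthoc_cells(df, value, factor_a, factor_b, posthoc),
        effects=effects,
    )


def rm_two_way_anova(
    df: pd.DataFrame,
    value: str,
    between: str,
    within: str,
    subject: str,
    posthoc: str = "bonferroni",
) -> StatResult:
    """Repeated-measures (mixed) two-way ANOVA.

    ``within`` is the repeated factor (e.g. size class), ``between`` the
    group factor, ``subject`` the mouse.  Every subject must be observed at
    every within level (missing cells raise).  Post hoc: per within-level
    group contrasts, Bonferroni-adjusted over the number of levels.
    """
    import pingouin as pg

    counts = df.groupby([subject, within]).size().unstack(fill_value=0)
    if (counts.to_numpy() != 1).any():
        bad = [
            (s, w)
            for s in counts.index
            for w in counts.columns
            if counts.loc[s, w] != 1
        ]
        raise ValueError(f"missing or duplicated subject x within cells: {bad[:10]}")
    aov = pg.mixed_anova(
        data=df, dv=value, within=within, between=between, subject=subject
    )
    aov = aov.set_index("Source")
    effects = {
        str(src): {
            "F": float(aov.loc[src, "F"]),
            "df": float(aov.loc[src, "DF1"]),
            "p": float(aov.loc[src, "p_unc"]),
        }
        for src in aov.index
    }
    inter_key = "Interaction"
    inter = effects[inter_key]
    levels = sorted(df[within].unique())
    groups = sorted(df[between].unique())
    rows = []
    for lev in levels:
        sub = df[df[within] == lev]
        for g1, g2 in itertools.combinations(groups, 2):
            a = sub.loc[sub[between] == g1, value].to_numpy(dtype=float)
            b = sub.loc[sub[between] == g2, value].to_numpy(dtype=float)
            t = sps.ttest_ind(a, b, equal_var=True)
            n_comp = len(levels) * math.comb(len(groups), 2)
            rows.append(
                {
                    "contrast": f"{within}={lev}: {g1} vs {g2}",
                    "p_adj": min(1.0, float(t.pvalue) * n_comp),
                }
            )
    if posthoc != "bonferroni":
        raise ValueError("repeated-measures post hoc supports bonferroni only")
    return StatResult(
        test="RM two-way ANOVA",
        statistic=inter["F"],
        df=(inter["df"], float(aov.loc[inter_key, "DF2"])),
        p=inter["p"],
        posthoc=pd.DataFrame(rows),
        effects=effects,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with two-tailed p and the least-squares regression line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), slope=float(reg.slope),
        intercept=float(reg.intercept), n=len(x),
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    ``G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha/(2n)`` quantile of Student's t on ``n-2`` df.
    """
    if n < 3:
        raise ValueError("Grubbs needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_remove_outliers(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal.

    The most extreme point is removed while its studentized deviation
    exceeds the critical value, recomputing after each removal, capped at
    ``floor(n/5)`` removals of the original sample size.  Samples with
    ``n < 3`` (or zero spread) are returned unchanged, with a warning for
    the former.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        warnings.warn("Grubbs test needs n >= 3; returning data unchanged", stacklevel=2)
        return values, np.empty(0)
    kept = values.copy()
    removed: list[float] = []
    cap = len(values) // 5
    while len(removed) < cap and len(kept) >= 3:
        mean = kept.mean()
        sd = kept.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(kept - mean)
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= grubbs_critical_value(len(kept), alpha):
            break
        removed.append(kept[i])
        kept = np.delete(kept, i)
    return kept, np.asarray(removed)
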