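"""Inferential procedures over per-dwelling metrics.

* Repeated-measures ANOVA across the three rooms for the (approximately
  normal) mean winter temperatures, with Bonferroni-adjusted pairwise
  comparisons.
* Fixed-effects two-way ANOVA (Gaussian identity link) with the factors LTD
  and over-64 and their interaction, Type II sums of squares for the
  unbalanced design.
* Rank-transform factorial ANOVA for the non-normal exposure metrics:
  midranks are assigned over the entire sample (rank 1 = lowest value, ties
  averaged), then the parametric two-way ANOVA is applied to the ranks. The
  interaction test under the rank transform has inflated type-I error and
  its result carries a caution note; main-effect tests are well calibrated.
* Relative risk for a binary outcome between exposure groups, with the
  log-normal-approximation confidence interval.
* Gaussian kernel-density summaries (normal-reference bandwidth) for the
  probability-density-function figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM, anova_lm

__all__ = [
    "StatResult",
    "PairwiseComparison",
    "RMAnovaResult",
    "RelativeRisk",
    "repeated_measures_anova",
    "two_way_anova",
    "anova_on_ranks",
    "midranks",
    "relative_risk",
    "relative_risk_from_counts",
    "kde_pdf",
]

_INTERACTION_CAVEAT = (
    "rank-transform interaction test: inflated type-I error; a significant "
    "interaction should be interpreted with caution (a null one is reliable)"
)


@dataclass
class StatResult:
    """One tested effect: F statistic, degrees of freedom, p, group summaries."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    group_means: dict[str, float] = field(default_factory=dict)
    diff: float | None = None              # level True − level False
    ci: tuple[float, float] | None = None  # 95% CI for diff
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df": [self.df_num, self.df_den],
            "p": self.p,
            "group_means": self.group_means,
            "diff": self.diff,
            "ci": list(self.ci) if self.ci is not None else None,
            "note": self.note,
        }


@dataclass
class PairwiseComparison:
    """Bonferroni-adjusted paired comparison between two within-subject levels."""

    level_a: str
    level_b: str
    mean_diff: float                    # a − b
    ci: tuple[float, float]             # Bonferroni-adjusted confidence interval
    t: float
    p_adjusted: float


@dataclass
class RMAnovaResult:
    anova: StatResult
    pairwise: list[PairwiseComparison]
    n_subjects: int
    n_dropped: int


def repeated_measures_anova(
    room_means: pd.DataFrame, alpha: float = 0.05
) -> RMAnovaResult:
    """One-within-factor repeated-measures ANOVA over room mean temperatures.

    ``room_means`` holds one row per dwelling and one column per room.
    Dwellings missing any room are dropped (counted in ``n_dropped``). With
    k rooms and n complete dwellings the F test has (k−1, (k−1)(n−1))
    degrees of freedom — no sphericity correction, matching the integer df
    convention. Pairwise room contrasts are paired t tests with Bonferroni
    adjustment over the k(k−1)/2 comparisons; their confidence intervals use
    the adjusted level 1 − alpha/m.
    """
    complete = room_means.dropna()
    n_dropped = len(room_means) - len(complete)
    n, k = complete.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete subjects and 2 levels")

    long = complete.reset_index(names="subject").melt(
        id_vars="subject", var_name="room", value_name="value"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance data raise benign runtime warnings
        table = AnovaRM(long, "value", "subject", within=["room"]).fit().anova_table
    F = float(table.loc["room", "F Value"])
    p = float(table.loc["room", "Pr > F"])
    # identical room profiles leave a 0/0 statistic that surfaces as NaN or
    # round-off noise; report it as no evidence of a room effect
    grand = complete.values.mean()
    scale = 1.0 + abs(grand) + complete.values.std()
    if not np.isfinite(F) or np.abs(complete.mean(axis=0) - grand).max() <= 1e-10 * scale:
        F, p = 0.0, 1.0
    result = StatResult(
        effect="room",
        F=F,
        df_num=int(table.loc["room", "Num DF"]),
        df_den=int(table.loc["room", "Den DF"]),
        p=p,
        group_means={c: float(complete[c].mean()) for c in complete.columns},
    )

    pairs = list(combinations(complete.columns, 2))
    m = len(pairs)
    crit = scipy.stats.t.ppf(1 - alpha / (2 * m), n - 1)
    pairwise = []
    for a, b in pairs:
        d = complete[a].to_numpy() - complete[b].to_numpy()
        sd = d.std(ddof=1)
        se = sd / np.sqrt(n)
        if se == 0:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat = float(d.mean() / se)
            p_raw = float(2 * scipy.stats.t.sf(abs(t_stat), n - 1))
        pairwise.append(
            PairwiseComparison(
                level_a=a,
                level_b=b,
                mean_diff=float(d.mean()),
                ci=(float(d.mean() - crit * se), float(d.mean() + crit * se)),
                t=t_stat,
                p_adjusted=min(1.0, m * p_raw),
            )
        )
    return RMAnovaResult(anova=result, pairwise=pairwise, n_subjects=n, n_dropped=n_dropped)


def _clean_design(
    outcome: Sequence[float], factor_a: Sequence[bool], factor_b: Sequence[bool]
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "a": np.asarray(factor_a, dtype=bool),
            "b": np.asarray(factor_b, dtype=bool),
        }
    )
    df = df[np.isfinite(df["y"])]
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level after cleaning")
    return df


def two_way_anova(
    outcome: Sequence[float],
    factor_a: Sequence[bool],
    factor_b: Sequence[bool],
    *,
    factor_names: tuple[str, str] = ("ltd", "over64"),
    include_interaction: bool = True,
    ss_type: int = 2,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Fixed-effects two-factor ANOVA with interaction on the raw outcome.

    Fits a Gaussian linear model ``y ~ A * B`` and tests each effect with
    Type II sums of squares (Type III via ``ss_type=3``). Missing outcomes
    are dropped before fitting. For each main effect the reported ``diff``
    and ``ci`` are the marginal (cell-mean-averaged) difference between the
    True and False level and its t-based interval. If any design cell is
    empty the interaction is dropped with a warning.
    """
    df = _clean_design(outcome, factor_a, factor_b)
    # an (effectively) constant outcome carries no evidence for any effect;
    # the 0/0 F statistics would otherwise surface as round-off noise
    if df["y"].std() <= 1e-10 * (1.0 + abs(df["y"].mean())):
        effects = [factor_names[0], factor_names[1]]
        if include_interaction:
            effects.append(f"{factor_names[0]}:{factor_names[1]}")
        df_den = len(df) - (4 if include_interaction else 3)
        out = []
        for i, name in enumerate(effects):
            means = (
                {
                    str(level): float(grp.mean())
                    for level, grp in df.groupby("ab"[i], observed=True)["y"]
                }
                if ":" not in name
                else {}
            )
            out.append(
                StatResult(name, 0.0, 1, df_den, 1.0, group_means=means,
                           diff=0.0 if ":" not in name else None,
                           ci=(0.0, 0.0) if ":" not in name else None)
            )
        return out
    cells = df.groupby(["a", "b"], observed=True).size()
    if include_interaction and len(cells) < 4:
        warnings.warn("empty design cell: interaction dropped", stacklevel=2)
        include_interaction = False

    formula = "y ~ C(a) + C(b)"
    if include_interaction:
        formula += " + C(a):C(b)"
    fit = smf.ols(formula, df).fit()
    table = anova_lm(fit, typ=ss_type)
    df_den = int(table.loc["Residual", "df"])
    cov = fit.cov_params()
    crit = scipy.stats.t.ppf(1 - alpha / 2, df_den)

    def marginal_contrast(main: str, inter_name: str) -> tuple[float, tuple[float, float]]:
        c = pd.Series(0.0, index=fit.params.index)
        c[main] = 1.0
        if include_interaction:
            c[inter_name] = 0.5  # average over the other factor's two levels
        diff = float(c @ fit.params)
        se = float(np.sqrt(c @ cov @ c))
        return diff, (diff - crit * se, diff + crit * se)

    name_map = {
        "C(a)": (factor_names[0], "a", "C(a)[T.True]", "C(a)[T.True]:C(b)[T.True]"),
        "C(b)": (factor_names[1], "b", "C(b)[T.True]", "C(a)[T.True]:C(b)[T.True]"),
    }
    results = []
    for row, (label, col, main_param, inter_param) in name_map.items():
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if not np.isfinite(F):  # zero effect and zero residual variance
            F, p = 0.0, 1.0
        diff, ci = marginal_contrast(main_param, inter_param)
        results.append(
            StatResult(
                effect=label,
                F=F,
                df_num=int(table.loc[row, "df"]),
                df_den=df_den,
                p=p,
                group_means={
                    str(level): float(grp.mean())
                    for level, grp in df.groupby(col, observed=True)["y"]
                },
                diff=diff,
                ci=(float(ci[0]), float(ci[1])),
            )
        )
    if include_interaction:
        row = "C(a):C(b)"
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if not np.isfinite(F):
            F, p = 0.0, 1.0
        results.append(
            StatResult(
                effect=f"{factor_names[0]}:{factor_names[1]}",
                F=F,
                df_num=int(table.loc[row, "df"]),
                df_den=df_den,
                p=p,
            )
        )
    return results


def midranks(values: Sequence[float]) -> np.ndarray:
    """Global ranks with ties averaged; rank 1 is the lowest value."""
    return scipy.stats.rankdata(np.asarray(values, dtype=float), method="average")


def anova_on_ranks(
    outcome: Sequence[float],
    factor_a: Sequence[bool],
    factor_b: Sequence[bool],
    **kwargs,
) -> list[StatResult]:
    """Rank-transform factorial ANOVA.

    The outcome is replaced by its midranks over the entire sample and the
    parametric two-way ANOVA is applied to the ranks; ``group_means`` then
    hold group mean ranks and ``diff``/``ci`` are on the rank scale. The
    interaction result carries the type-I-error caution note.
    """
    y = np.asarray(outcome, dtype=float)
    finite = np.isfinite(y)
    ranks = np.full(len(y), np.nan)
    ranks[finite] = midranks(y[finite])
    results = two_way_anova(ranks, factor_a, factor_b, **kwargs)
    for r in results:
        if ":" in r.effect:
            r.note = _INTERACTION_CAVEAT
    return results


@dataclass
class RelativeRisk:
    """Risk ratio P(outcome | exposed) / P(outcome | unexposed)."""

    rr: float
    ci: tuple[float, float] | None
    p_exposed: float
    p_unexposed: float
    table: tuple[int, int, int, int]  # (a, b, c, d): exposed +/−, unexposed +/−

    def to_dict(self) -> dict:
        return {
            "rr": self.rr,
            "ci": list(self.ci) if self.ci is not None else None,
            "p_exposed": self.p_exposed,
            "p_unexposed": self.p_unexposed,
            "table": list(self.table),
        }


def relative_risk_from_counts(
    a: int, b: int, c: int, d: int, alpha: float = 0.05
) -> RelativeRisk:
    """Relative risk from 2×2 counts: exposed (a with outcome, b without)
    vs unexposed (c with outcome, d without); log-normal CI, no continuity
    correction. With a zero outcome cell the CI is undefined (None) and a
    warning is emitted.
    """
    if a + b == 0 or c + d == 0:
        raise ValueError("both exposure groups must be non-empty")
    p1 = a / (a + b)
    p0 = c / (c + d)
    if p0 == 0:
        warnings.warn("no outcomes in the unexposed group: RR infinite, CI undefined")
        return RelativeRisk(float("inf"), None, p1, p0, (a, b, c, d))
    rr = p1 / p0
    if a == 0 or c == 0:
        warnings.warn("zero outcome cell: CI undefined")
        return RelativeRisk(rr, None, p1, p0, (a, b, c, d))
    se_log = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    ci = (float(rr * np.exp(-z * se_log)), float(rr * np.exp(z * se_log)))
    return RelativeRisk(float(rr), ci, p1, p0, (a, b, c, d))


def relative_risk(
    outcome: Sequence[bool], group: Sequence[bool], alpha: float = 0.05
) -> RelativeRisk:
    """Relative risk of a binary outcome for group=True vs group=False."""
    outcome = np.asarray(outcome, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if outcome.shape != group.shape:
        raise ValueError("outcome and group must have equal length")
    a = int((group & outcome).sum())
    b = int((group & ~outcome).sum())
    c = int((~group & outcome).sum())
    d = int((~group & ~outcome).sum())
    return relative_risk_from_counts(a, b, c, d, alpha=alpha)


def kde_pdf(
    values: Sequence[float],
    grid: np.ndarray | None = None,
    bw_method: str | float = "silverman",
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate on a grid.

    Bandwidth follows the normal-reference (Silverman) rule by default. The
    default grid spans the data range extended by four bandwidths on each
    side, so the trapezoid integral of the returned density is 1 to within
    1e-3. Fewer than two values, non-finite values, or zero variance raise
    ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least two finite values")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) input")
    kde = scipy.stats.gaussian_kde(x, bw_method=bw_method)
    bw = float(kde.factor * x.std(ddof=1))
    if grid is None:
        grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    return grid, kde(grid)
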