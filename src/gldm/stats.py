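"""Age-adjusted group comparisons (ANCOVA) with Bonferroni-corrected post hocs.

The behavioural inference is a linear model ``score ~ group + age``; the
group effect is tested with a type-II F test, adjusted group means are
evaluated at the grand mean age, and pairwise post hocs are age-adjusted
contrasts from the full model thresholded at ``family_alpha / n_comparisons``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class DesignError(ValueError):
    """Singular or degenerate model design."""


@dataclass
class AncovaResult:
    f_statistic: float
    df_between: int
    df_residual: int
    p_value: float
    adjusted_group_means: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if self.f_statistic < 0:
            raise ValueError("F statistic must be non-negative")


def _design(group: pd.Series, age: np.ndarray):
    """Full-model design matrix: intercept, treatment-coded group, age."""
    dummies = pd.get_dummies(pd.Series(group).astype("category"), drop_first=True)
    X = np.column_stack(
        [np.ones(len(age)), dummies.to_numpy(dtype=float), np.asarray(age, float)]
    )
    return X, list(dummies.columns)


def ancova(scores, group, age) -> AncovaResult:
    """One-way ANCOVA of ``scores`` on ``group`` controlling for ``age``.

    Returns the type-II F test of the group term, with adjusted group means
    evaluated at the grand mean age and age-adjusted pairwise contrasts
    (two-sided t tests from the full model).
    """
    y = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    group = pd.Series(np.asarray(group)).reset_index(drop=True)
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise DesignError("need at least two groups")
    if group.value_counts().min() < 2:
        raise DesignError("every group needs at least two members")
    if np.any(np.isnan(y)) or np.any(np.isnan(age)):
        raise ValueError("missing values are not supported")

    X_full, dummy_names = _design(group, age)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DesignError("singular design (age collinear with group?)")
    full = sm.OLS(y, X_full).fit()
    # type-II test of the group term: drop all group dummies, keep age
    X_red = np.column_stack([np.ones(len(y)), age])
    red = sm.OLS(y, X_red).fit()
    df_between = len(levels) - 1
    df_resid = int(full.df_resid)
    num = (red.ssr - full.ssr) / df_between
    den = full.ssr / df_resid
    if den == 0:
        f_stat, p = 0.0, 1.0
        if num > 0:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = num / den
        p = float(sps.f.sf(f_stat, df_between, df_resid))

    mean_age = age.mean()
    beta = full.params
    adj = {}
    for lev in levels:
        x = np.zeros(X_full.shape[1])
        x[0] = 1.0
        if lev != levels[0]:
            x[1 + dummy_names.index(lev)] = 1.0
        x[-1] = mean_age
        adj[lev] = float(x @ beta)

    rows = []
    for a, b in combinations(levels, 2):
        x = np.zeros(X_full.shape[1])
        if a != levels[0]:
            x[1 + dummy_names.index(a)] = 1.0
        if b != levels[0]:
            x[1 + dummy_names.index(b)] -= 1.0
        tt = full.t_test(x)
        rows.append(
            dict(
                pair=f"{a} vs {b}",
                estimate=float(np.squeeze(tt.effect)),
                t=float(np.squeeze(tt.tvalue)),
                p_value=float(np.squeeze(tt.pvalue)),
            )
        )
    pairwise = pd.DataFrame(rows)
    return AncovaResult(
        f_statistic=float(max(f_stat, 0.0)),
        df_between=df_between,
        df_residual=df_resid,
        p_value=p,
        adjusted_group_means=adj,
        pairwise=pairwise,
    )


def bonferroni_posthoc(
    p_values, n_comparisons: int = 3, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Threshold pairwise p values at ``family_alpha / n_comparisons``.

    ``p_values`` is a mapping pair-label -> p, or the ``pairwise`` frame
    returned by :func:`ancova`.  The threshold is reported both exactly and
    rounded to 3 decimals (the conventional reporting style, 0.05/3 -> 0.016).
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    threshold = family_alpha / n_comparisons
    if isinstance(p_values, pd.DataFrame):
        items = list(zip(p_values["pair"], p_values["p_value"]))
    else:
        items = list(p_values.items())
    out = pd.DataFrame(
        {
            "pair": [k for k, _ in items],
            "p_value": [v for _, v in items],
            "significant": [v < threshold for _, v in items],
        }
    )
    out.attrs["threshold"] = threshold
    out.attrs["threshold_3dp"] = float(np.floor(threshold * 1000) / 1000)
    return out


def paired_condition_compare(score_a, score_b, age) -> AncovaResult:
    """Within-participant condition contrast with an age covariate.

    Models the per-participant difference a - b on centred age; the F test is
    on the intercept (the age-adjusted condition effect), and the adjusted
    mean difference is the intercept itself.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (len(a) == len(b) == len(age)):
        raise ValueError("score_a, score_b and age must have equal length")
    d = a - b
    X = np.column_stack([np.ones(len(d)), age - age.mean()])
    fit = sm.OLS(d, X).fit()
    tt = fit.t_test(np.array([1.0, 0.0]))
    t = float(np.squeeze(tt.tvalue))
    f_stat = t**2
    if np.isnan(f_stat):  # zero-variance difference
        f_stat, p = 0.0, 1.0
    else:
        p = float(np.squeeze(tt.pvalue))
    return AncovaResult(
        f_statistic=f_stat,
        df_between=1,
        df_residual=int(fit.df_resid),
        p_value=p,
        adjusted_group_means={"difference": float(fit.params[0])},
    )


def group_table(cohort: pd.DataFrame, score_columns, group_col="group", age_col="age") -> pd.DataFrame:
    """Report table: per-group mean (SD) per score, F, df, corrected marker."""
    rows = []
    for col in score_columns:
        sub = cohort.dropna(subset=[col])
        res = ancova(sub[col], sub[group_col], sub[age_col])
        post = bonferroni_posthoc(res.pairwise)
        row = {"score": col}
        for g, grp in sub.groupby(group_col):
            row[f"{g}_mean_sd"] = f"{grp[col].mean():.2f} ({grp[col].std(ddof=1):.2f})"
        row["F"] = round(res.f_statistic, 2)
        row["df"] = f"({res.df_between},{res.df_residual})"
        row["p"] = res.p_value
        row["significant_pairs"] = "; ".join(post.loc[post["significant"], "pair"])
        rows.append(row)
    return pd.DataFrame(rows)
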