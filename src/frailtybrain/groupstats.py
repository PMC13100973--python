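"""Group-difference statistics for cohort description tables.

One-way ANOVA with Tukey HSD post hoc for continuous variables, Pearson
chi-square (no continuity correction) for categorical variables,
covariate-adjusted ANCOVA for the sensitivity analysis, and pooled-SD
Cohen's d effect sizes. Analyses are complete-case per variable and the
n actually used is recorded with every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import CollinearityError, ConfigurationError, DegenerateDataError

__all__ = ["GroupTestResult", "one_way_anova", "chi_square_test", "ancova",
           "cohens_d", "direction_string"]


@dataclass
class GroupTestResult:
    """Result of a group-difference test.

    ``posthoc`` (when present) has one row per group pair with the mean
    difference, Tukey-adjusted p, direction and Cohen's d.
    """

    test: str                      # "anova" | "chi2" | "ancova"
    statistic: float               # F or chi2
    df: tuple[float, float]        # (df_between, df_within) or (df, n)
    p_value: float
    n_used: int
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def direction(self, alpha: float = 0.05) -> str:
        if self.posthoc is None:
            return ""
        return direction_string(self.posthoc, alpha=alpha)

    def summary(self) -> str:
        name = {"anova": "F", "chi2": "chi2", "ancova": "F"}[self.test]
        lines = [f"{self.test}: {name}({self.df[0]:g}, {self.df[1]:g}) = "
                 f"{self.statistic:.3f}, p = {self.p_value:.4g}, n = {self.n_used}"]
        if self.posthoc is not None:
            lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD Cohen's d for two independent samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise DegenerateDataError("Cohen's d needs n >= 2 per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def direction_string(posthoc: pd.DataFrame, alpha: float = 0.05) -> str:
    """Summarise significant pairwise contrasts as e.g. ``FTLD > AD > CU``.

    Orders groups by mean and joins with '>' where the adjacent contrast
    is significant, '&' otherwise.
    """
    means: dict[str, float] = {}
    for _, row in posthoc.iterrows():
        means.setdefault(row["group_a"], row["mean_a"])
        means.setdefault(row["group_b"], row["mean_b"])
    order = sorted(means, key=means.get, reverse=True)
    sig = {frozenset((r["group_a"], r["group_b"])): r["p_adj"] < alpha
           for _, r in posthoc.iterrows()}
    parts = [order[0]]
    for a, b in zip(order, order[1:]):
        parts.append(" > " if sig.get(frozenset((a, b)), False) else " & ")
        parts.append(b)
    return "".join(parts)


def _tukey_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    from itertools import combinations

    res = pairwise_tukeyhsd(values, groups)
    pairs = list(combinations(res.groupsunique, 2))  # statsmodels pair order
    rows = []
    gmeans = {g: values[groups == g].mean() for g in np.unique(groups)}
    for (a, b), diff, p in zip(pairs, res.meandiffs, res.pvalues):
        rows.append({
            "group_a": a, "group_b": b,
            "mean_a": gmeans[a], "mean_b": gmeans[b],
            "diff": float(diff), "p_adj": float(p),
            # sign convention matches diff: positive when group_b > group_a
            "cohens_d": cohens_d(values[groups == b], values[groups == a]),
        })
    return pd.DataFrame(rows)


def one_way_anova(values, groups) -> GroupTestResult:
    """Classic one-way ANOVA F with df (k-1, N-k) plus Tukey HSD post hoc.

    Missing values are dropped pairwise with their group label
    (complete-case per variable).
    """
    values = pd.Series(np.asarray(values, float))
    groups = pd.Series(np.asarray(groups, object))
    ok = values.notna() & groups.notna()
    values, groups = values[ok].to_numpy(), groups[ok].to_numpy()
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ConfigurationError("ANOVA requires >= 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise DegenerateDataError(f"group {g!r} has n < 2")
    f_stat, p = stats.f_oneway(*samples)
    k, n = len(labels), len(values)
    posthoc = _tukey_posthoc(values, groups)
    return GroupTestResult(test="anova", statistic=float(f_stat),
                           df=(k - 1, n - k), p_value=float(p), n_used=n,
                           posthoc=posthoc)


def chi_square_test(table) -> GroupTestResult:
    """Pearson chi-square on an r x c contingency table (counts), without
    continuity correction; df = (r-1)(c-1)."""
    table = pd.DataFrame(table)
    counts = table.to_numpy(float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigurationError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateDataError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return GroupTestResult(test="chi2", statistic=float(chi2),
                           df=(float(df), float(counts.sum())),
                           p_value=float(p), n_used=int(counts.sum()))


def ancova(outcome, groups, covariates: pd.DataFrame) -> GroupTestResult:
    """Group effect on ``outcome`` adjusted for covariates, with Tukey HSD
    and Cohen's d on the covariate-adjusted values.

    The group F is the extra-sum-of-squares test of the group factor on
    top of the covariates. Post hoc comparisons use the outcome with the
    (mean-centred) covariate contribution removed, so pairwise contrasts
    are contrasts of adjusted means.
    """
    outcome = pd.Series(np.asarray(outcome, float)).reset_index(drop=True)
    groups = pd.Series(np.asarray(groups, object)).reset_index(drop=True)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    ok = outcome.notna() & groups.notna() & covariates.notna().all(axis=1)
    y = outcome[ok].to_numpy()
    g = groups[ok].to_numpy()
    C = covariates[ok].to_numpy(float)
    n = len(y)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ConfigurationError("ANCOVA requires >= 2 groups")

    dummies = np.column_stack([(g == lab).astype(float) for lab in labels[1:]])
    X_full = np.column_stack([np.ones(n), C, dummies])
    X_red = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # identify offending covariate columns by incremental rank
        bad = []
        base = np.ones((n, 1))
        for j, col in enumerate(covariates.columns):
            cand = np.column_stack([base, C[:, :j + 1]])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                bad.append(str(col))
        raise CollinearityError(
            f"design matrix is rank deficient (collinear columns: {bad or 'group dummies'})"
        )

    beta_full, ssr_full = _ols_ssr(X_full, y)
    _, ssr_red = _ols_ssr(X_red, y)
    df_num = len(labels) - 1
    df_den = n - X_full.shape[1]
    sst = float(((y - y.mean()) ** 2).sum())
    extra_ss = ssr_red - ssr_full
    if extra_ss <= 1e-10 * max(sst, 1e-300):
        # covariates already explain the outcome (to rounding): no group effect
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (extra_ss / df_num) / (ssr_full / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))

    # covariate-adjusted outcome for post hoc contrasts
    cov_beta = beta_full[1:1 + C.shape[1]]
    y_adj = y - (C - C.mean(axis=0)) @ cov_beta
    posthoc = _tukey_posthoc(y_adj, g)
    return GroupTestResult(test="ancova", statistic=float(f_stat),
                           df=(df_num, df_den), p_value=p, n_used=n,
                           posthoc=posthoc,
                           extra={"covariates": list(covariates.columns)})


def _ols_ssr(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)
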