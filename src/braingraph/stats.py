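"""Group-comparison statistics for network metrics and clinical covariates.

The statistical layer mirrors the conventions of covariate-adjusted
neuroimaging group studies with three groups (ROT / PT / HC):

* chi-square tests for categorical demographics (gender, tinnitus side),
* a Shapiro-Wilk normality gate per group that routes each continuous
  variable either to one-way ANOVA + pooled two-sample t-tests or to
  Kruskal-Wallis + Mann-Whitney U,
* ANCOVA on integrated (AUC) network metrics — a linear model
  ``metric ~ group + age + sex + avg_ht + ht_8k`` with an F-test on the
  group factor — followed by LSD post hoc contrasts (pairwise t-tests on
  covariate-adjusted means using the model's residual variance,
  uncorrected: that is what LSD means),
* Bonferroni correction for nodal / module families,
* Spearman rank correlations with Benjamini-Hochberg FDR adjustment for
  clinical associations.

When the normality gate fails for an AUC metric the covariate adjustment is
run on rank-transformed responses (rank ANCOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_COVARIATES = ("age", "sex", "avg_ht", "ht_8k")

#: Canonical pairwise comparison order used in the output tables.
PAIR_ORDER = (("PT", "ROT"), ("PT", "HC"), ("ROT", "HC"))


@dataclass(frozen=True)
class GroupStatsRow:
    """Omnibus + pairwise result for one metric."""

    metric: str
    statistic: float
    stat_name: str  # "F", "H" or "chi2"
    p_value: float
    pairwise_p: dict = field(default_factory=dict)  # {"PT-ROT": p, ...}
    route: str = ""
    correction: str = "none"
    family_size: int = 1

    def as_dict(self) -> dict:
        out = {"metric": self.metric, "statistic": self.statistic,
               "stat_name": self.stat_name, "p": self.p_value,
               "route": self.route, "correction": self.correction,
               "family_size": self.family_size}
        for k, v in self.pairwise_p.items():
            out[f"p_{k}"] = v
        return out


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    q_value: float
    n: int
    flagged: str = ""


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an R x C contingency table (no continuity correction).

    Returns ``(chi2, df, p)``.  Expected counts come from the product of the
    margins; a zero row or column margin is rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def normality_gate(values, groups, alpha: float = 0.05) -> str:
    """Shapiro-Wilk per group; ``"normal"`` only if every group passes at alpha."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        sample = values[groups == g]
        if len(sample) < 3:
            raise ValueError(f"group {g!r} has n={len(sample)} < 3: cannot test normality")
        if np.ptp(sample) == 0:
            return "non-normal"
        if sps.shapiro(sample).pvalue < alpha:
            return "non-normal"
    return "normal"


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return float(min(1.0, p * m))


def _design(groups: np.ndarray, covariates: pd.DataFrame | None,
            group_levels: list) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded group dummies + covariate columns."""
    n = len(groups)
    cols = [np.ones(n)]
    names = ["intercept"]
    for g in group_levels[1:]:
        cols.append((groups == g).astype(float))
        names.append(f"group[{g}]")
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c].to_numpy(dtype=float)
            cols.append(col)
            names.append(c)
    return np.column_stack(cols), names


def _check_collinear(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # find a column whose removal restores full column rank
        for j in range(x.shape[1] - 1, 0, -1):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column {names[j]!r} is redundant")
        raise ValueError("collinear design matrix")


def ancova_lsd(values, groups, covariates: pd.DataFrame | None = None,
               group_levels: tuple = ("PT", "ROT", "HC")) -> GroupStatsRow:
    """ANCOVA F-test on the group factor plus LSD pairwise contrasts.

    The omnibus F compares the full linear model against the model without
    the group dummies (model reduction).  LSD p-values are two-sided t-tests
    on adjusted group-mean differences using the full model's residual
    variance, with no multiplicity correction.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in group_levels if g in set(groups)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    x_full, names = _design(groups, covariates, levels)
    _check_collinear(x_full, names)
    fit_full = sm.OLS(y, x_full).fit()
    x_red = np.delete(x_full, range(1, len(levels)), axis=1)
    fit_red = sm.OLS(y, x_red).fit()
    q = len(levels) - 1
    df_resid = fit_full.df_resid
    f_stat = ((fit_red.ssr - fit_full.ssr) / q) / (fit_full.ssr / df_resid)
    p = float(sps.f.sf(f_stat, q, df_resid))

    cov_b = fit_full.cov_params()
    beta = fit_full.params
    pairwise: dict[str, float] = {}
    for g1, g2 in combinations(levels, 2):
        c = np.zeros(x_full.shape[1])
        if g1 != levels[0]:
            c[1 + levels[1:].index(g1)] = 1.0
        if g2 != levels[0]:
            c[1 + levels[1:].index(g2)] -= 1.0
        diff = float(c @ beta)
        se = float(np.sqrt(c @ cov_b @ c))
        t = diff / se
        pairwise[f"{g1}-{g2}"] = float(2 * sps.t.sf(abs(t), df_resid))
    return GroupStatsRow(metric="", statistic=float(f_stat), stat_name="F",
                         p_value=p, pairwise_p=pairwise,
                         route="ancova" if covariates is not None else "anova-lm",
                         correction="LSD")


def anova_with_ttests(values, groups,
                      group_levels: tuple = ("PT", "ROT", "HC"),
                      welch: bool = False) -> GroupStatsRow:
    """One-way ANOVA omnibus with pooled-variance pairwise t-tests."""
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in group_levels if g in set(groups)]
    samples = [y[groups == g] for g in levels]
    f_stat, p = sps.f_oneway(*samples)
    pairwise = {}
    for (g1, s1), (g2, s2) in combinations(zip(levels, samples), 2):
        res = sps.ttest_ind(s1, s2, equal_var=not welch)
        pairwise[f"{g1}-{g2}"] = float(res.pvalue)
    return GroupStatsRow(metric="", statistic=float(f_stat), stat_name="F",
                         p_value=float(p), pairwise_p=pairwise, route="anova")


def kruskal_with_mwu(values, groups,
                     group_levels: tuple = ("PT", "ROT", "HC")) -> GroupStatsRow:
    """Kruskal-Wallis omnibus with Mann-Whitney U pairwise tests."""
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in group_levels if g in set(groups)]
    samples = [y[groups == g] for g in levels]
    h_stat, p = sps.kruskal(*samples)
    pairwise = {}
    for (g1, s1), (g2, s2) in combinations(zip(levels, samples), 2):
        res = sps.mannwhitneyu(s1, s2, alternative="two-sided")
        pairwise[f"{g1}-{g2}"] = float(res.pvalue)
    return GroupStatsRow(metric="", statistic=float(h_stat), stat_name="H",
                         p_value=float(p), pairwise_p=pairwise, route="kruskal")


def omnibus_and_pairwise(values, groups, covariates: pd.DataFrame | None = None,
                         route: str = "auto", metric: str = "",
                         correction: str = "none", family_size: int = 1,
                         group_levels: tuple = ("PT", "ROT", "HC"),
                         alpha: float = 0.05) -> GroupStatsRow:
    """Dispatch one metric to the appropriate omnibus + pairwise battery.

    ``route`` is one of ``auto`` (normality gate decides), ``anova``,
    ``kruskal``, ``ancova`` or ``rank-ancova``.  With ``covariates`` given,
    the gate routes to ANCOVA on raw or rank-transformed responses.
    ``correction="bonferroni"`` multiplies the pairwise p-values by
    ``family_size`` — the number of simultaneous tests in the family (e.g.
    90 nodes for nodal metrics, 21 measures for module connectivity) —
    capped at 1.
    """
    values = np.asarray(values, dtype=float)
    if route == "auto":
        gate = normality_gate(values, groups, alpha=alpha)
        if covariates is not None:
            route = "ancova" if gate == "normal" else "rank-ancova"
        else:
            route = "anova" if gate == "normal" else "kruskal"

    if route in ("ancova", "rank-ancova"):
        if covariates is None:
            raise ValueError("ANCOVA routes require covariates")
        y = sps.rankdata(values) if route == "rank-ancova" else values
        row = ancova_lsd(y, groups, covariates, group_levels)
    elif route == "anova":
        row = anova_with_ttests(values, groups, group_levels)
    elif route == "kruskal":
        row = kruskal_with_mwu(values, groups, group_levels)
    else:
        raise ValueError(f"unknown route: {route!r}")

    pairwise = dict(row.pairwise_p)
    corr_tag = row.correction if row.correction != "none" else "none"
    if correction == "bonferroni":
        m = max(1, family_size)
        pairwise = {k: bonferroni(p, m) for k, p in pairwise.items()}
        corr_tag = f"bonferroni(m={m})"
    return GroupStatsRow(metric=metric, statistic=row.statistic,
                         stat_name=row.stat_name, p_value=row.p_value,
                         pairwise_p=pairwise, route=route,
                         correction=corr_tag, family_size=family_size)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_fdr(pairs: list[tuple]) -> list[CorrelationResult]:
    """Spearman rho for each (x, y[, name]) pair with BH-FDR across all pairs.

    Each element of ``pairs`` is ``(x, y)`` or ``(x, y, (x_name, y_name))``.
    Pairs with a constant variable get ``rho = nan`` and a flag; they are
    excluded from the FDR family.
    """
    rows = []
    for k, pair in enumerate(pairs):
        x, y = np.asarray(pair[0], float), np.asarray(pair[1], float)
        names = pair[2] if len(pair) > 2 else (f"x{k}", f"y{k}")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 4:
            raise ValueError(f"pair {names}: need n >= 4, got {len(x)}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((names, np.nan, np.nan, len(x), "constant-variable"))
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append((names, float(rho), float(p), len(x), ""))
    testable = [i for i, r in enumerate(rows) if r[4] == ""]
    q = fdr_bh([rows[i][2] for i in testable])
    q_map = dict(zip(testable, q))
    return [CorrelationResult(x_name=str(nm[0]), y_name=str(nm[1]), rho=rho,
                              p_value=p, q_value=float(q_map.get(i, np.nan)),
                              n=n, flagged=flag)
            for i, (nm, rho, p, n, flag) in enumerate(rows)]


def stats_table(rows: list[GroupStatsRow]) -> pd.DataFrame:
    """Tidy DataFrame from a list of per-metric results."""
    return pd.DataFrame([r.as_dict() for r in rows])
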