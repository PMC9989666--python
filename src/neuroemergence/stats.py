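"""Group-level inference: ANOVA/ANCOVA, permutation t-tests, FDR, effect sizes.

The analysis design is one between-subjects factor (diagnostic group, three
levels) per scalar measure, followed by the three pairwise post-hoc
comparisons tested with two-sided permutation t-tests and controlled with the
Benjamini-Hochberg procedure.  Cohen's d (pairwise) and Hedges' g (summary
statistics) quantify effect sizes; Spearman correlations relate measures
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupedMeasure:
    values: np.ndarray
    group: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.group):
            raise ValueError("values and group labels must have equal length")
        if self.covariates is not None and len(self.covariates) != len(self.values):
            raise ValueError("covariate rows must match subjects")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: tuple[float, ...] | float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardised mean difference."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def one_way_anova(gm: GroupedMeasure) -> TestResult:
    """One-way fixed-effects ANOVA on the group factor."""
    levels = sorted(set(gm.group))
    samples = [gm.values[np.asarray(gm.group) == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 subjects")
    f, p = sps.f_oneway(*samples)
    k = len(levels)
    n = len(gm.values)
    return TestResult(statistic=float(f), p_value=float(p), df=(k - 1, n - k))


def permutation_ttest(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> TestResult:
    """Two-sided permutation test on the two-sample t statistic.

    The p-value uses the add-one estimator (b+1)/(m+1) so it can never be
    exactly zero.  Cohen's d is attached.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled.var(ddof=1), 0.0):
        raise ValueError("zero pooled variance; t statistic undefined")
    t_obs = sps.ttest_ind(a, b).statistic
    rng = np.random.default_rng(seed)
    na, nb = len(a), len(b)
    perms = np.array([rng.permutation(pooled) for _ in range(n_perm)])
    pa, pb = perms[:, :na], perms[:, na:]
    sp2 = ((na - 1) * pa.var(axis=1, ddof=1) + (nb - 1) * pb.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = (pa.mean(axis=1) - pb.mean(axis=1)) / denom
    t_perm = np.nan_to_num(t_perm, nan=np.inf)
    count = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
    p = (count + 1) / (n_perm + 1)
    return TestResult(
        statistic=float(t_obs),
        p_value=float(p),
        df=float(len(a) + len(b) - 2),
        effect_size=cohens_d(a, b),
        effect_size_name="cohens_d",
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def summary_stats_ttest(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance Student t-test from summary statistics, with Hedges' g.

    Hedges' g applies the small-sample bias correction J = 1 - 3/(4 df - 1) to
    the pooled standardised mean difference.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    d = (m1 - m2) / sp
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    return TestResult(
        statistic=float(t),
        p_value=float(p),
        df=float(df),
        effect_size=float(g),
        effect_size_name="hedges_g",
    )


def spearman(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation with tie-corrected ranks and t-approximate p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), df=float(len(x) - 2))


def ancova(gm: GroupedMeasure) -> TestResult:
    """F-test for the group factor after linear covariate adjustment.

    Fits outcome ~ group + covariates by OLS (group dummy-coded) and reports
    the partial F for the group factor.  Constant covariate columns are
    dropped; genuinely collinear designs raise with the offending column.
    """
    if gm.covariates is None or gm.covariates.shape[1] == 0:
        return one_way_anova(gm)
    cov = gm.covariates.copy()
    for col in list(cov.columns):
        if not np.issubdtype(cov[col].dtype, np.number):
            cov[col] = pd.factorize(cov[col])[0].astype(float)
        if np.ptp(cov[col].to_numpy(dtype=float)) == 0:
            cov = cov.drop(columns=[col])
    if cov.shape[1] == 0:
        return one_way_anova(gm)
    group_dummies = pd.get_dummies(pd.Series(gm.group), drop_first=True, dtype=float)
    X_full = pd.concat(
        [group_dummies.reset_index(drop=True), cov.reset_index(drop=True)], axis=1
    )
    X_full.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X_full.to_numpy(dtype=float))
    if rank < X_full.shape[1]:
        for col in X_full.columns[1:]:
            reduced = X_full.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"rank-deficient design: column {col!r} is collinear")
        raise ValueError("rank-deficient design matrix")
    y = gm.values
    full = sm.OLS(y, X_full.to_numpy(dtype=float)).fit()
    X_red = pd.concat([pd.Series(1.0, name="const", index=cov.index), cov], axis=1)
    reduced = sm.OLS(y, X_red.to_numpy(dtype=float)).fit()
    df_num = len(group_dummies.columns)
    df_den = len(y) - X_full.shape[1]
    num = max(reduced.ssr - full.ssr, 0.0) / df_num
    den = full.ssr / df_den
    scale = float(np.var(y)) + 1e-30
    if den <= 1e-12 * scale:  # saturated fit: outcome fully explained by covariates
        f = 0.0 if num <= 1e-12 * scale else np.inf
    else:
        f = num / den
    p = sps.f.sf(f, df_num, df_den)
    return TestResult(statistic=float(f), p_value=float(p), df=(float(df_num), float(df_den)))


def pairwise_posthoc(
    gm: GroupedMeasure,
    comparisons: list[tuple[str, str]] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation t-tests for the pairwise group comparisons, BH-FDR corrected."""
    groups = sorted(set(gm.group))
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    labels = np.asarray(gm.group)
    for i, (ga, gb) in enumerate(comparisons):
        res = permutation_ttest(
            gm.values[labels == ga], gm.values[labels == gb], n_perm=n_perm, seed=seed + i
        )
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "t": res.statistic,
                "p": res.p_value,
                "cohens_d": res.effect_size,
            }
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = bh_fdr(table["p"].to_numpy())
    return table
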