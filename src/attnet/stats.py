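"""Inferential battery: ANOVAs with sphericity/homogeneity corrections,
pairwise t-tests with effect sizes, simple regression, and multiplicity
adjustments.

The mixed repeated-measures ANOVA follows the standard univariate split-plot
decomposition: the between-subjects effect is tested against
subjects-within-groups, the within-subjects effect and the interaction
against the subject x within residual.  Sphericity is assessed with
Mauchly's W on the pooled within-group covariance of the repeated measures;
when violated (or on request) Greenhouse-Geisser epsilon multiplies the
within/interaction degrees of freedom.  Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error).

Homogeneity of variance uses Levene's test (absolute deviations from the
group mean; the median-centered Brown-Forsythe variant is exposed).  When it
rejects, the one-way ANOVA reports the Brown-Forsythe F* ratio with
Satterthwaite-adjusted denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaRow:
    effect: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    partial_eta_sq: float
    correction: str = "none"


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    ss_error: dict[str, float] = field(default_factory=dict)
    notes: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": r.effect,
                    "SS": r.ss,
                    "df1": r.df1,
                    "df2": r.df2,
                    "F": r.F,
                    "p": r.p,
                    "eta_p2": r.partial_eta_sq,
                    "correction": r.correction,
                }
                for r in self.rows
            ]
        )


@dataclass
class SphericityResult:
    mauchly_w: float
    chi_sq: float
    df: int
    p: float
    gg_epsilon: float


@dataclass
class HomogeneityResult:
    levene_stat: float
    df1: int
    df2: int
    p: float
    center: str = "mean"
    brown_forsythe_used: bool = False


@dataclass
class TTestResult:
    label: str
    t: float
    df: float
    p: float
    cohens_d: float
    paired: bool
    correction: str = "none"
    p_adjusted: float | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# homogeneity and one-way ANOVA
# ---------------------------------------------------------------------------


def levene_test(values, groups, center: str = "mean") -> HomogeneityResult:
    """One-way ANOVA on absolute deviations from the group center.

    ``center='median'`` gives the Brown-Forsythe variant of the variance test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("levene_test needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    stat, p = stats.levene(*samples, center=center)
    k, n = len(labels), len(values)
    return HomogeneityResult(
        levene_stat=float(stat), df1=k - 1, df2=n - k, p=float(p), center=center
    )


def _brown_forsythe_means(samples: list[np.ndarray]):
    """Brown-Forsythe (1974) robust F* for equality of means.

    F* = SS_between / sum_i (1 - n_i/N) s_i^2, with Satterthwaite df2.
    """
    n = np.array([len(s) for s in samples], dtype=float)
    N = n.sum()
    means = np.array([s.mean() for s in samples])
    grand = np.concatenate(samples).mean()
    ss_between = float((n * (means - grand) ** 2).sum())
    s2 = np.array([s.var(ddof=1) for s in samples])
    c = (1.0 - n / N) * s2
    denom = c.sum()
    f_star = ss_between / denom
    df1 = len(samples) - 1
    df2 = denom**2 / ((c**2 / (n - 1)).sum())
    p = float(stats.f.sf(f_star, df1, df2))
    return float(f_star), float(df1), float(df2), p


def one_way_anova(
    values,
    groups,
    *,
    robust: bool = False,
    levene_alpha: float = 0.05,
    levene_center: str = "mean",
) -> tuple[AnovaTable, HomogeneityResult]:
    """Classical one-way F with Brown-Forsythe fallback.

    When ``robust`` is set, or Levene's test rejects homogeneity at
    ``levene_alpha``, the Brown-Forsythe F* with Satterthwaite-adjusted
    denominator df is reported instead of the classical F.  Partial eta
    squared always comes from the classical SS decomposition.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    N, k = len(values), len(labels)
    grand = values.mean()
    ss_between = float(sum(len(s) * (s.mean() - grand) ** 2 for s in samples))
    ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    eta = ss_between / (ss_between + ss_within)
    hom = levene_test(values, groups, center=levene_center)
    use_bf = robust or hom.p < levene_alpha
    if use_bf:
        F, df1, df2, p = _brown_forsythe_means(samples)
        hom.brown_forsythe_used = True
        correction = "brown-forsythe"
    else:
        df1, df2 = k - 1, N - k
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
        correction = "none"
    table = AnovaTable(
        rows=[
            AnovaRow(
                effect="group",
                ss=ss_between,
                df1=df1,
                df2=df2,
                F=F,
                p=p,
                partial_eta_sq=eta,
                correction=correction,
            )
        ],
        ss_error={"group": ss_within},
    )
    return table, hom


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _pooled_within_cov(wide: np.ndarray, group_codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled covariance of the repeated measures after removing group means."""
    resid = wide.astype(float).copy()
    for g in np.unique(group_codes):
        sel = group_codes == g
        resid[sel] -= resid[sel].mean(axis=0)
    df_e = wide.shape[0] - len(np.unique(group_codes))
    cov = resid.T @ resid / df_e
    return cov, df_e


def greenhouse_geisser(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-subject covariance matrix.

    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2) with lambda the
    eigenvalues of the covariance projected onto orthonormal contrasts;
    bounded in [1/(k-1), 1], and exactly 1 for k = 2 or compound symmetry.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    C = _orthonormal_contrasts(k)
    A = C @ cov @ C.T
    lam = np.linalg.eigvalsh(A)
    denom = (k - 1) * float((lam**2).sum())
    if denom <= 0:
        import warnings

        warnings.warn("singular within-subject covariance; epsilon floored", RuntimeWarning)
        return 1.0 / (k - 1)
    eps = float(lam.sum()) ** 2 / denom
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def mauchly_test(cov: np.ndarray, df_error: int) -> SphericityResult:
    """Mauchly's sphericity test on a within-subject covariance matrix.

    ``df_error`` is the covariance's error df (N - number of groups).  For
    k = 2 within levels, W = 1 and sphericity holds trivially.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    eps = greenhouse_geisser(cov)
    if k == 2:
        return SphericityResult(1.0, 0.0, 0, 1.0, eps)
    C = _orthonormal_contrasts(k)
    A = C @ cov @ C.T
    lam = np.linalg.eigvalsh(A)
    lam = np.clip(lam, 1e-300, None)
    d = k - 1
    W = float(np.prod(lam) / (lam.mean() ** d))
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * df_error)
    chi2 = -f * df_error * np.log(max(W, 1e-300))
    df = k * (k - 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return SphericityResult(W, float(chi2), df, p, eps)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------


def mixed_rm_anova(
    data: pd.DataFrame,
    *,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "within",
    sphericity_alpha: float = 0.05,
    gg_always: bool = False,
) -> tuple[AnovaTable, SphericityResult]:
    """Split-plot ANOVA for a balanced complete group x within design.

    Returns the between, within and interaction rows (F, df, p, partial eta
    squared) plus the sphericity assessment.  With more than two within
    levels, Greenhouse-Geisser corrected df/p are used for the within and
    interaction tests when Mauchly's test rejects (or always with
    ``gg_always``).  Missing cells are an error; no imputation.
    """
    cols = [subject, between, within, dv]
    df = data[cols].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable")
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("design is incomplete: every subject needs every within level")
    counts = df.groupby([subject, between, within]).size()
    if (counts != 1).any():
        raise ValueError("expected exactly one observation per subject x within cell")
    group_of = wide.index.get_level_values(1).to_numpy()
    group_sizes = pd.Series(group_of).value_counts()
    if group_sizes.nunique() != 1:
        raise ValueError("design must be balanced across groups")
    Y = wide.to_numpy()
    n_subj, k_w = Y.shape
    groups = pd.unique(group_of)
    k_b = len(groups)
    n = n_subj // k_b
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[group_of == g].mean() for g in groups])
    within_means = Y.mean(axis=0)
    cell_means = np.array([Y[group_of == g].mean(axis=0) for g in groups])

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(k_w * ((subj_means - grand) ** 2).sum())
    ss_group = float(n * k_w * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_within_total = ss_total - ss_between_subj
    ss_within = float(n_subj * ((within_means - grand) ** 2).sum())
    ss_inter = float(
        n
        * (
            (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_err_within = ss_within_total - ss_within - ss_inter

    df_group, df_err_b = k_b - 1, k_b * (n - 1)
    df_within, df_inter = k_w - 1, (k_b - 1) * (k_w - 1)
    df_err_w = k_b * (n - 1) * (k_w - 1)

    cov, df_e = _pooled_within_cov(Y, pd.factorize(group_of)[0])
    sph = mauchly_test(cov, df_e)
    apply_gg = k_w > 2 and (gg_always or sph.p < sphericity_alpha)
    eps = sph.gg_epsilon if apply_gg else 1.0

    def row(effect, ss, ss_err, df1, df2, corrected):
        e = eps if corrected else 1.0
        F = (ss / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1 * e, df2 * e))
        return AnovaRow(
            effect=effect,
            ss=ss,
            df1=df1 * e,
            df2=df2 * e,
            F=F,
            p=p,
            partial_eta_sq=ss / (ss + ss_err),
            correction="greenhouse-geisser" if (corrected and apply_gg) else "none",
        )

    rows = []
    if k_b > 1:
        rows.append(row(between, ss_group, ss_subj_within, df_group, df_err_b, False))
    rows.append(row(within, ss_within, ss_err_within, df_within, df_err_w, True))
    if k_b > 1:
        rows.append(
            row(f"{between} * {within}", ss_inter, ss_err_within, df_inter, df_err_w, True)
        )
    table = AnovaTable(
        rows=rows,
        ss_error={"between": ss_subj_within, "within": ss_err_within},
        notes={"ss_total": ss_total, "gg_applied": apply_gg, "epsilon": eps},
    )
    return table, sph


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def _cohens_d_independent(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    return float((x.mean() - y.mean()) / pooled)


def ttest(
    x,
    y,
    *,
    paired: bool = False,
    welch: bool = False,
    label: str = "",
) -> TTestResult:
    """Two-sided t-test with Cohen's d.

    Paired d = mean(diff) / sd(diff); independent d uses the pooled sd.  The
    sign convention is d < 0 when the first mean is below the second.  Welch
    applies the Satterthwaite df (independent samples only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must be the same length")
        diff = x - y
        sd = diff.std(ddof=1)
        d = float(diff.mean() / sd) if sd > 0 else 0.0
        if sd == 0:
            t, p, dof = 0.0, 1.0, len(diff) - 1
        else:
            res = stats.ttest_rel(x, y)
            t, p, dof = float(res.statistic), float(res.pvalue), len(diff) - 1
    else:
        d = _cohens_d_independent(x, y) if (x.var() + y.var()) > 0 else 0.0
        if x.var(ddof=1) + y.var(ddof=1) == 0:
            t, p = 0.0, 1.0
            dof = len(x) + len(y) - 2
        else:
            res = stats.ttest_ind(x, y, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
            if welch:
                vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
                dof = (vx + vy) ** 2 / (
                    vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
                )
            else:
                dof = len(x) + len(y) - 2
    return TTestResult(label=label, t=t, df=float(dof), p=p, cohens_d=d, paired=paired)


def pairwise_ttests(
    data: pd.DataFrame,
    *,
    dv: str = "value",
    factor: str = "group",
    subject: str | None = None,
    paired: bool = False,
    welch: bool = False,
    correction: str = "none",
) -> list[TTestResult]:
    """All pairwise comparisons across levels of ``factor``.

    Paired comparisons align observations by ``subject``.  With
    ``correction='bonferroni'`` adjusted p-values (min(1, m*p)) are attached.
    """
    levels = list(pd.unique(data[factor]))
    results = []
    for a, b in combinations(levels, 2):
        da, db = data[data[factor] == a], data[data[factor] == b]
        if paired:
            if subject is None:
                raise ValueError("paired comparisons need a subject column")
            merged = da.merge(db, on=subject, suffixes=("_a", "_b"))
            x, y = merged[f"{dv}_a"].to_numpy(), merged[f"{dv}_b"].to_numpy()
        else:
            x, y = da[dv].to_numpy(), db[dv].to_numpy()
        res = ttest(x, y, paired=paired, welch=welch, label=f"{a} vs {b}")
        results.append(res)
    if correction == "bonferroni":
        m = len(results)
        for r in results:
            r.correction = "bonferroni"
            r.p_adjusted = min(1.0, r.p * m)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return results


# ---------------------------------------------------------------------------
# regression and multiplicity
# ---------------------------------------------------------------------------


def fc_behavior_regression(x, y) -> RegressionResult:
    """OLS of behavioral change on a connectivity summary (simple regression).

    Reports slope, intercept, Pearson r, R^2 (= r^2) and the slope's
    two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance regression input")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )


def bonferroni_adjust(p_values) -> np.ndarray:
    """min(1, m * p) per value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(1.0, p * len(p))


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (discovery mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    below = ranked <= q * np.arange(1, m + 1) / m
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        mask[order[: k + 1]] = True
    return mask, p_adj
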