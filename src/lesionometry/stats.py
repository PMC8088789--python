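"""Screening and covariate statistics.

The pipeline correlates every white-matter measure with every cognitive task,
keeps only relationships whose Bayes factor (null-over-alternative; values
below 1 favour the alternative) falls under a screening threshold (default
0.2), and examines survivors with an analysis of covariance in which the task
is the dependent variable, group the categorical predictor, and estimated IQ,
years of education and the focal measure are covariates. A measure "explains"
a group difference when it is itself a significant predictor and its
inclusion renders the group effect non-significant.

The Bayes factor uses a default stretched-beta prior on the correlation
(scale 1, i.e. uniform on (-1, 1)) integrated against the exact sampling
density of the Pearson r; it is therefore software-comparable only up to
prior choice. Sample-size helpers invert the noncentral-t power function
(two-sample t-test) and the exact distribution of r (correlation test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import betaln, gammaln, hyp2f1

__all__ = [
    "BfScreenResult",
    "AncovaResult",
    "GroupTestResult",
    "ScreenReport",
    "pearson_r_logpdf",
    "pearson_bf",
    "power_ttest",
    "sample_size_ttest",
    "power_correlation",
    "sample_size_correlation",
    "group_tests",
    "ancova",
    "screen_and_model",
]


# ---------------------------------------------------------------------------
# exact distribution of the Pearson correlation


def pearson_r_logpdf(r, rho: float, n: int):
    """Log of the exact sampling density of the Pearson correlation of a
    bivariate-normal sample of size ``n`` with population correlation ``rho``
    (Hotelling's hypergeometric form)."""
    r = np.asarray(r, dtype=float)
    const = (
        np.log(n - 2)
        + gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - gammaln(n - 0.5)
    )
    return (
        const
        + ((n - 1) / 2.0) * np.log1p(-rho**2)
        + ((n - 4) / 2.0) * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2.0))
    )


@dataclass(frozen=True)
class BfScreenResult:
    """One measure-task correlation with its screening verdict."""

    task: str
    measure: str
    n: int
    r: float
    p: float
    bf: float  # null-over-alternative: < 1 favours the alternative
    threshold: float
    included: bool


def pearson_bf(
    x,
    y,
    prior_scale: float = 1.0,
    threshold: float = 0.2,
    task: str = "",
    measure: str = "",
) -> BfScreenResult:
    """Two-sided Pearson correlation with a default-prior Bayes factor.

    The alternative places a stretched-beta(1/k, 1/k) prior on the population
    correlation (``prior_scale`` = k; scale 1 is uniform). The Bayes factor is
    reported in the null-over-alternative orientation, so values below 1
    favour a non-zero correlation and the screening keeps BF < ``threshold``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    n = len(x)
    if n < 5:
        raise ValueError("Bayesian correlation needs n >= 5 finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    r_obs = float(np.clip(r, -0.999999, 0.999999))  # density is singular at |r|=1

    a = 1.0 / prior_scale

    def integrand(rho):
        lprior = (
            (a - 1) * (np.log1p(rho) + np.log1p(-rho))
            - (2 * a - 1) * np.log(2.0)
            - betaln(a, a)
        )
        return np.exp(pearson_r_logpdf(r_obs, rho, n) + lprior)

    with warnings.catch_warnings():
        # near |r| = 1 the integrand peaks sharply; quad still converges in value
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        num, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    den = float(np.exp(pearson_r_logpdf(r_obs, 0.0, n)))
    bf01 = den / num
    return BfScreenResult(
        task=task,
        measure=measure,
        n=n,
        r=float(r),
        p=float(p),
        bf=float(bf01),
        threshold=threshold,
        included=bool(bf01 < threshold),
    )


# ---------------------------------------------------------------------------
# power and sample size


def power_ttest(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of an independent two-sample t-test with ``n`` per group, from
    the noncentral t distribution (ncp = d * sqrt(n / 2), df = 2n - 2)."""
    if n < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n - 2
    ncp = d * np.sqrt(n / 2.0)
    if tails == 2:
        tc = stats.t.ppf(1 - alpha / 2.0, df)
        return float(1 - stats.nct.cdf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, ncp))


def sample_size_ttest(
    d: float, alpha: float = 0.05, power: float = 0.8, tails: int = 2, n_max: int = 100_000
) -> int:
    """Smallest equal group size whose two-sample t-test power reaches the target."""
    if d <= 0:
        raise ValueError("effect size d must be positive (power unreachable at d = 0)")
    if not 0 < alpha < 1 or not alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    for n in range(2, n_max + 1):
        if power_ttest(n, d, alpha, tails) >= power:
            return n
    raise RuntimeError("sample size search exceeded n_max")


def power_correlation(
    n: int, rho: float, alpha: float = 0.05, tails: int = 2, method: str = "exact"
) -> float:
    """Power of the test of zero correlation at population correlation ``rho``.

    method="exact" integrates the exact sampling density of r beyond the
    critical value implied by the null t-test of r; method="fisher" uses the
    Fisher-z normal approximation.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "fisher":
        se = 1.0 / np.sqrt(n - 3)
        z = np.arctanh(rho) / se
        if tails == 2:
            zc = stats.norm.ppf(1 - alpha / 2.0)
            return float(stats.norm.sf(zc - z) + stats.norm.cdf(-zc - z))
        zc = stats.norm.ppf(1 - alpha)
        return float(stats.norm.sf(zc - z))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    a = alpha / 2.0 if tails == 2 else alpha
    tc = stats.t.ppf(1 - a, n - 2)
    rc = tc / np.sqrt(n - 2 + tc**2)
    f = lambda r: np.exp(pearson_r_logpdf(r, rho, n))
    upper, _ = integrate.quad(f, rc, 1.0, limit=200)
    if tails == 2:
        lower, _ = integrate.quad(f, -1.0, -rc, limit=200)
        return float(upper + lower)
    return float(upper)


def sample_size_correlation(
    r: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: int = 2,
    method: str = "exact",
    n_max: int = 100_000,
) -> int:
    """Smallest total n whose correlation-test power reaches the target."""
    if not 0 < abs(r) < 1:
        raise ValueError("need 0 < |r| < 1")
    for n in range(4, n_max + 1):
        if power_correlation(n, abs(r), alpha, tails, method) >= power:
            return n
    raise RuntimeError("sample size search exceeded n_max")


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupTestResult:
    """Independent two-sample comparison: pooled and Welch variants, the
    reported policy choice, and standardized effect sizes."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    t_pooled: float
    df_pooled: float
    p_pooled: float
    t_welch: float
    df_welch: float
    p_welch: float
    levene_F: float
    levene_p: float
    policy: str       # "pooled" | "welch"
    t: float
    df: float
    p: float
    d: float          # Cohen's d, pooled sd
    g: float          # Hedges' g


def group_tests(values, groups, levene_alpha: float = 0.05) -> GroupTestResult:
    """Two-sample t-test with both variance policies and d/g effect sizes.

    Welch's test is reported when Levene's test (centre = mean) rejects
    variance homogeneity at ``levene_alpha``; the pooled test otherwise.
    Hedges' g applies the small-sample correction 1 - 3 / (4 N - 9).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero within-group variance in both groups")
    tp, pp = stats.ttest_ind(a, b, equal_var=True)
    tw, pw = stats.ttest_ind(a, b, equal_var=False)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    df_w = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    lf, lp = stats.levene(a, b, center="mean")
    policy = "welch" if lp < levene_alpha else "pooled"
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = float((a.mean() - b.mean()) / sp)
    g = float(d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)))
    rep = (tw, df_w, pw) if policy == "welch" else (tp, float(n1 + n2 - 2), pp)
    return GroupTestResult(
        n1=n1, n2=n2, mean1=float(a.mean()), mean2=float(b.mean()),
        t_pooled=float(tp), df_pooled=float(n1 + n2 - 2), p_pooled=float(pp),
        t_welch=float(tw), df_welch=float(df_w), p_welch=float(pw),
        levene_F=float(lf), levene_p=float(lp), policy=policy,
        t=float(rep[0]), df=float(rep[1]), p=float(rep[2]), d=d, g=g,
    )


# ---------------------------------------------------------------------------
# analysis of covariance


@dataclass
class AncovaResult:
    """Type-III-style ANCOVA of one task on group plus covariates."""

    task: str
    n: int
    group_F: float
    group_df: tuple
    group_p: float
    group_eta_sq: float
    covariate_terms: dict          # name -> {"F", "p", "eta_sq", "df"}
    interaction_F: float | None    # group x focal covariate
    interaction_p: float | None
    levene_F: float
    levene_p: float
    model_F: float
    model_df: tuple
    model_p: float
    model_r2: float                # reported as the model's partial eta^2
    collinearity_max_r: float
    focal: str | None = None
    notes: list = field(default_factory=list)


def _fit_rss(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, X).fit()
    return float(model.ssr)


def ancova(
    scores,
    groups,
    covariates: pd.DataFrame | None = None,
    focal: str | None = None,
    alpha: float = 0.05,
    task: str = "",
    collinearity_max: float = 0.8,
) -> AncovaResult:
    """ANCOVA with nested-model (Type-III-style) F tests and partial eta^2.

    Each term's F compares the full linear model against the model with that
    term removed; partial eta^2 = SS_effect / (SS_effect + SS_error). The
    homogeneity-of-slopes check refits with a group x focal-covariate
    interaction and reports its F and p. Levene's test (centre = mean) on the
    dependent variable by group and the maximum absolute pairwise correlation
    among covariates are reported alongside.
    """
    y = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    cov = pd.DataFrame(index=range(len(y))) if covariates is None else covariates.reset_index(drop=True)
    good = np.isfinite(y)
    for c in cov.columns:
        good &= np.isfinite(cov[c].to_numpy(dtype=float))
    y, groups, cov = y[good], groups[good], cov.loc[good]
    n = len(y)
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant covariates dropped from the model: {constant}", stacklevel=2
        )
        cov = cov.drop(columns=constant)
        if focal in constant:
            focal = None
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    counts = [int((groups == l).sum()) for l in labels]
    if min(counts) < 2:
        raise ValueError("every group needs >= 2 members")
    k = len(labels)
    n_terms = (k - 1) + len(cov.columns)
    if n <= n_terms + 2:
        raise ValueError("too few subjects for the model")

    notes: list[str] = []
    G = np.column_stack([(groups == l).astype(float) for l in labels[1:]])
    C = cov.to_numpy(dtype=float) if len(cov.columns) else np.empty((n, 0))
    X_full = np.column_stack([np.ones(n), G, C])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular design matrix")

    max_r = 0.0
    if C.shape[1] >= 2:
        R = np.corrcoef(C, rowvar=False)
        max_r = float(np.abs(R[~np.eye(C.shape[1], dtype=bool)]).max())
        if max_r >= collinearity_max:
            notes.append(
                f"covariate collinearity |r| = {max_r:.3f} exceeds {collinearity_max}"
            )
            warnings.warn(notes[-1], stacklevel=2)

    full = sm.OLS(y, X_full).fit()
    rss_full = float(full.ssr)
    df_resid = int(full.df_resid)

    def term_test(cols_to_drop):
        keep = [c for c in range(X_full.shape[1]) if c not in cols_to_drop]
        rss_red = _fit_rss(y, X_full[:, keep])
        ss_eff = rss_red - rss_full
        df_t = len(cols_to_drop)
        F = (ss_eff / df_t) / (rss_full / df_resid)
        p = float(stats.f.sf(F, df_t, df_resid))
        eta = ss_eff / (ss_eff + rss_full)
        return float(F), (df_t, df_resid), p, float(eta)

    gcols = list(range(1, k))
    gF, gdf, gp, geta = term_test(gcols)
    cov_terms = {}
    for j, name in enumerate(cov.columns):
        col = k + j
        F, dft, p, eta = term_test([col])
        cov_terms[str(name)] = {"F": F, "df": dft, "p": p, "eta_sq": eta}

    inter_F = inter_p = None
    if focal is not None:
        if focal not in cov.columns:
            raise KeyError(f"focal covariate {focal!r} not among covariates")
        fvals = cov[focal].to_numpy(dtype=float)
        inter_cols = G * fvals[:, None]
        X_int = np.column_stack([X_full, inter_cols])
        mod_int = sm.OLS(y, X_int).fit()
        ss_int = rss_full - float(mod_int.ssr)
        df_int = inter_cols.shape[1]
        df_res_int = int(mod_int.df_resid)
        inter_F = float((ss_int / df_int) / (mod_int.ssr / df_res_int))
        inter_p = float(stats.f.sf(inter_F, df_int, df_res_int))

    lf, lp = stats.levene(*[y[groups == l] for l in labels], center="mean")

    return AncovaResult(
        task=task,
        n=n,
        group_F=gF, group_df=gdf, group_p=gp, group_eta_sq=geta,
        covariate_terms=cov_terms,
        interaction_F=inter_F, interaction_p=inter_p,
        levene_F=float(lf), levene_p=float(lp),
        model_F=float(full.fvalue), model_df=(int(full.df_model), df_resid),
        model_p=float(full.f_pvalue), model_r2=float(full.rsquared),
        collinearity_max_r=max_r,
        focal=focal,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# the screening pipeline


@dataclass
class ScreenReport:
    """Per-task screening + covariate-analysis report."""

    tasks: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (BfScreenResult, AncovaResult, GroupTestResult)):
                return clean(vars(obj))
            return obj

        return clean({"config": self.config, "tasks": self.tasks})


def screen_and_model(
    measure_table: pd.DataFrame,
    cohort: pd.DataFrame,
    tasks,
    covariate_names=("iq", "edu"),
    bf_threshold: float = 0.2,
    alpha: float = 0.05,
    prior_scale: float = 1.0,
    group_col: str = "group",
) -> ScreenReport:
    """Run the full screening + covariate stage for each cognitive task.

    For each task every measure column is correlated against the task scores
    (pairwise complete case) with a Bayes factor; measures with BF below the
    threshold enter an ANCOVA alongside the demographic covariates, and the
    report records whether each surviving measure is a unique predictor
    (covariate p < alpha) and whether it attenuates the group effect
    (baseline group p < alpha becoming >= alpha once the measure is added).
    Tasks with no survivor are flagged "no further analyses".
    """
    measure_table, cohort = measure_table.align(cohort, join="inner", axis=0)
    measure_cols = [c for c in measure_table.columns if c != group_col]
    report = ScreenReport(
        config={
            "bf_threshold": bf_threshold,
            "alpha": alpha,
            "prior_scale": prior_scale,
            "covariates": list(covariate_names),
            "n_measures": len(measure_cols),
            "multiple_testing": "BF screening only (no further correction)",
        }
    )
    base_cov = cohort[list(covariate_names)]
    for task in tasks:
        if task not in cohort.columns:
            raise KeyError(f"task {task!r} absent from cohort table")
        y = cohort[task].to_numpy(dtype=float)
        groups = cohort[group_col].to_numpy()
        baseline = ancova(y, groups, base_cov, task=task, alpha=alpha)
        screens = []
        for m in measure_cols:
            x = measure_table[m].to_numpy(dtype=float)
            good = np.isfinite(x) & np.isfinite(y)
            if good.sum() < 5 or x[good].std() == 0:
                continue
            screens.append(
                pearson_bf(x, y, prior_scale, bf_threshold, task=task, measure=m)
            )
        survivors = [s for s in screens if s.included]
        entry = {
            "baseline_ancova": baseline,
            "correlations": screens,
            "n_missing": int((~np.isfinite(y)).sum()),
            "survivors": [s.measure for s in survivors],
            "models": {},
        }
        if not survivors:
            entry["conclusion"] = "no further analyses"
        else:
            for s in survivors:
                cov = base_cov.copy()
                cov[s.measure] = measure_table[s.measure].to_numpy(dtype=float)
                res = ancova(y, groups, cov, focal=s.measure, task=task, alpha=alpha)
                meas_p = res.covariate_terms[s.measure]["p"]
                entry["models"][s.measure] = {
                    "ancova": res,
                    "unique_predictor": bool(meas_p < alpha),
                    "attenuates_group": bool(
                        baseline.group_p < alpha and res.group_p >= alpha
                    ),
                }
            entry["conclusion"] = "survivors examined with covariate models"
        report.tasks[task] = entry
    return report
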