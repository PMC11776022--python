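"""Exposure-outcome analysis layer.

Implements the study-style analyses on a cohort table: tertile contrasts
(ANOVA + Tukey, or Kruskal-Wallis + Bonferroni-corrected pairwise
Mann-Whitney, gated by per-group Shapiro-Wilk normality), jointly-adjusted
linear models with MVPA and sedentary percentage in the same model,
standardized betas, an optional fetal-sex interaction check, country-level
random-intercept mixed models with a likelihood-ratio test for a random
MVPA slope, and the sensitivity re-fits excluding smokers, GDM and PE/PIH.

Fit results are returned as Results-style objects (:class:`ModelFit`,
:class:`TertileResult`, :class:`MixedFit`) carrying estimates, 95% CIs,
standardized betas, p-values and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ModelFit",
    "TertileResult",
    "MixedFit",
    "assign_tertiles",
    "compare_tertiles",
    "fit_adjusted_model",
    "fit_mixed_model",
    "sensitivity_analysis",
    "DEFAULT_EXPOSURES",
    "DEFAULT_COVARIATES",
]

DEFAULT_EXPOSURES = ("mvpa", "st_pct")
DEFAULT_COVARIATES = ("age", "bmi", "gdm", "fetal_sex")


# ---------------------------------------------------------------------------
# Results objects
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """OLS results in the layout of an adjusted-association table.

    ``params`` has one row per term with columns
    ``term, beta, ci_low, ci_high, sb, p`` (``sb`` = standardized beta,
    beta * sd(x)/sd(y); blank for the intercept).
    """

    outcome: str
    params: pd.DataFrame
    n_used: int
    label: str = "main"
    _sm_result: object = field(default=None, repr=False)

    def beta(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "beta"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def summary(self) -> str:
        lines = [f"Adjusted linear model for {self.outcome} "
                 f"({self.label}, n = {self.n_used})",
                 f"{'term':<14}{'beta':>9}{'95% CI':>20}{'SB':>8}{'P':>9}"]
        for _, r in self.params.iterrows():
            sb = f"{r.sb:7.2f}" if np.isfinite(r.sb) else "      -"
            lines.append(
                f"{r.term:<14}{r.beta:9.3f}   ({r.ci_low:7.3f}, {r.ci_high:7.3f})"
                f"{sb:>8}{r.p:9.3g}"
            )
        return "\n".join(lines)


@dataclass
class TertileResult:
    cut_points: tuple[float, float]
    group_sizes: tuple[int, ...]
    test_used: str  # "anova_tukey" | "kw_bonf_mwu"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame  # columns: group_a, group_b, p_adj

    def summary(self) -> str:
        lines = [
            f"Tertile comparison ({self.test_used}); cuts at "
            f"{self.cut_points[0]:.3g} / {self.cut_points[1]:.3g}; "
            f"n = {self.group_sizes}",
            f"omnibus statistic = {self.statistic:.4g}, p = {self.p_value:.4g}",
        ]
        for _, r in self.posthoc.iterrows():
            lines.append(f"  T{int(r.group_a)} vs T{int(r.group_b)}: "
                         f"p_adj = {r.p_adj:.4g}")
        return "\n".join(lines)


@dataclass
class MixedFit:
    outcome: str
    params: pd.DataFrame  # fixed effects, same columns as ModelFit.params
    n_used: int
    cluster_variance: float
    cluster_variance_se: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float

    def summary(self) -> str:
        head = (f"Random-intercept model for {self.outcome} (n = {self.n_used}); "
                f"cluster variance {self.cluster_variance:.3g} "
                f"(SE {self.cluster_variance_se:.3g}); "
                f"LRT random slope: chi2({self.lrt_df}) = "
                f"{self.lrt_statistic:.3g}, p = {self.lrt_p:.3g}")
        return head


# ---------------------------------------------------------------------------
# Tertiles
# ---------------------------------------------------------------------------


def assign_tertiles(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Split values at the 33.33rd / 66.67th percentiles (linear interpolation).

    Ties on a cut point go to the lower group.  Returns integer labels
    1, 2, 3 and the two cut points.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValidationError("need at least 3 one-dimensional values")
    if len(np.unique(v)) < 3:
        raise ValidationError("fewer than 3 distinct values; tertiles undefined")
    c1, c2 = np.percentile(v, [100.0 / 3.0, 200.0 / 3.0])
    if c1 == c2:
        raise ValidationError("degenerate tertile cut points (heavy ties)")
    labels = np.where(v <= c1, 1, np.where(v <= c2, 2, 3))
    return labels, (float(c1), float(c2))


def compare_tertiles(outcome, groups,
                     cut_points: tuple[float, float] = (np.nan, np.nan)
                     ) -> TertileResult:
    """Omnibus + post-hoc contrast of an outcome across tertile groups.

    If every group passes Shapiro-Wilk normality at alpha = 0.05 the path is
    one-way ANOVA with Tukey HSD; otherwise Kruskal-Wallis with pairwise
    Mann-Whitney U, Bonferroni-corrected by the number of pairs.
    """
    outcome = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    samples = [outcome[groups == g] for g in uniq]
    if len(samples) < 2:
        raise ValidationError("need at least 2 non-empty groups")
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs n >= 2")

    def _normal(s):
        if len(s) < 3 or np.ptp(s) == 0:
            return False
        return sps.shapiro(s).pvalue >= 0.05

    pairs = list(itertools.combinations(range(len(samples)), 2))
    if all(_normal(s) for s in samples):
        stat, p = sps.f_oneway(*samples)
        tk = sps.tukey_hsd(*samples)
        rows = [dict(group_a=uniq[i], group_b=uniq[j],
                     p_adj=float(tk.pvalue[i, j])) for i, j in pairs]
        test = "anova_tukey"
    else:
        stat, p = sps.kruskal(*samples)
        m = len(pairs)
        rows = []
        for i, j in pairs:
            pw = sps.mannwhitneyu(samples[i], samples[j],
                                  alternative="two-sided").pvalue
            rows.append(dict(group_a=uniq[i], group_b=uniq[j],
                             p_adj=float(min(1.0, pw * m))))
        test = "kw_bonf_mwu"
    return TertileResult(
        cut_points=(float(cut_points[0]), float(cut_points[1])),
        group_sizes=tuple(len(s) for s in samples),
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        posthoc=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Adjusted linear model
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = df.loc[:, list(terms)].astype(float)
    X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: pd.DataFrame):
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending columns via QR diagonal
        _, r = np.linalg.qr(mat)
        bad = [X.columns[i] for i in range(mat.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")


def fit_adjusted_model(
    cohort: pd.DataFrame,
    outcome: str,
    *,
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    sex_interaction: bool = False,
    label: str = "main",
) -> ModelFit:
    """OLS of ``outcome`` on both exposures plus the adjustment set.

    Complete-case analysis; 95% CIs from the t distribution; standardized
    beta = beta * sd(x) / sd(y).  With ``sex_interaction=True`` the
    exposure-by-sex product terms are added (the effect-modification check).
    """
    terms = list(exposures) + list(covariates)
    work = cohort.loc[:, terms + [outcome]].dropna().copy()
    if sex_interaction:
        if "fetal_sex" not in covariates:
            raise ValidationError("sex_interaction requires fetal_sex covariate")
        for e in exposures:
            work[f"{e}:fetal_sex"] = work[e] * work["fetal_sex"]
            terms.append(f"{e}:fetal_sex")
    n_used = len(work)
    if n_used < len(terms) + 2:
        raise ValidationError(
            f"too few complete cases (n = {n_used}) for {len(terms)} terms"
        )
    X = _design(work, tuple(terms))
    _check_rank(X)
    res = sm.OLS(work[outcome].astype(float), X).fit()
    ci = res.conf_int(alpha=0.05)
    sd_y = work[outcome].std(ddof=1)
    rows = []
    for term in X.columns:
        sb = (
            res.params[term] * work[term].std(ddof=1) / sd_y
            if term != "intercept" and sd_y > 0
            else np.nan
        )
        rows.append(dict(term=term, beta=float(res.params[term]),
                         ci_low=float(ci.loc[term, 0]),
                         ci_high=float(ci.loc[term, 1]),
                         sb=float(sb) if np.isfinite(sb) else np.nan,
                         p=float(res.pvalues[term])))
    return ModelFit(outcome, pd.DataFrame(rows), n_used, label, res)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------


def fit_mixed_model(
    cohort: pd.DataFrame,
    outcome: str,
    cluster: str = "country",
    *,
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> MixedFit:
    """Country-clustered random-intercept model with a random-slope LRT.

    Both the random-intercept and the random-MVPA-slope models are fitted by
    maximum likelihood (not REML) so their likelihoods are comparable; the
    LRT statistic is referred to chi-square with df = 2 (slope variance +
    intercept-slope covariance).  Because the null pins variances to the
    boundary of the parameter space this reference is conservative.
    """
    terms = list(exposures) + list(covariates)
    work = cohort.loc[:, terms + [outcome, cluster]].dropna()
    if work[cluster].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 clusters")
    X = _design(work, tuple(terms))
    _check_rank(X)
    y = work[outcome].astype(float)
    groups = work[cluster]

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        exog_re = work.loc[:, [exposures[0]]].astype(float)
        exog_re.insert(0, "intercept", 1.0)
        try:
            m1 = sm.MixedLM(y, X, groups=groups, exog_re=exog_re).fit(reml=False)
            lrt = max(0.0, 2.0 * (m1.llf - m0.llf))
        except Exception:  # singular random-slope fit on degenerate data
            lrt = 0.0
    lrt_df = 2
    lrt_p = float(sps.chi2.sf(lrt, lrt_df))

    ci = m0.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)
    rows = []
    for term in X.columns:
        sb = (
            m0.fe_params[term] * work[term].std(ddof=1) / sd_y
            if term != "intercept" and sd_y > 0
            else np.nan
        )
        rows.append(dict(term=term, beta=float(m0.fe_params[term]),
                         ci_low=float(ci.loc[term, 0]),
                         ci_high=float(ci.loc[term, 1]),
                         sb=float(sb) if np.isfinite(sb) else np.nan,
                         p=float(m0.pvalues[term])))
    var = float(m0.cov_re.iloc[0, 0])
    var_se = float(np.sqrt(m0.scale) * m0.bse.iloc[-1])
    return MixedFit(outcome, pd.DataFrame(rows), len(work), var, var_se,
                    float(lrt), lrt_df, lrt_p)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------


def sensitivity_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    *,
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> dict[str, ModelFit | None]:
    """Re-fit the adjusted model on each exclusion subset.

    Subsets: no smokers, no GDM (GDM dropped as covariate there — it is
    constant), no PE/PIH.  A subset too small for the model is reported as
    ``None`` rather than raising.
    """
    subsets = {
        "main": cohort,
        "no_smoking": cohort[cohort["smoking"] == 0],
        "no_gdm": cohort[cohort["gdm"] == 0],
        "no_pe_pih": cohort[cohort["pe_pih"] == 0],
    }
    out: dict[str, ModelFit | None] = {}
    for label, sub in subsets.items():
        covs = tuple(c for c in covariates if not (label == "no_gdm" and c == "gdm"))
        try:
            out[label] = fit_adjusted_model(
                sub, outcome, exposures=exposures, covariates=covs, label=label
            )
        except ValidationError:
            out[label] = None
    return out


def plot_sensitivity_forest(fits: dict[str, ModelFit | None],
                            terms: tuple[str, ...] = DEFAULT_EXPOSURES,
                            ax=None):
    """Forest plot of exposure betas with 95% CIs across the re-fits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * len(fits) * len(terms) + 1))
    tab = sensitivity_table(fits, terms).dropna(subset=["term"])
    ys = np.arange(len(tab))[::-1]
    ax.errorbar(tab["beta"], ys,
                xerr=[tab["beta"] - tab["ci_low"], tab["ci_high"] - tab["beta"]],
                fmt="o", capsize=3)
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.analysis} / {r.term}" for r in tab.itertuples()])
    ax.set_xlabel("beta (95% CI)")
    return ax


def sensitivity_table(fits: dict[str, ModelFit | None],
                      terms: tuple[str, ...] = DEFAULT_EXPOSURES) -> pd.DataFrame:
    """Long-format table (analysis, term, beta, ci_low, ci_high, p, n)."""
    rows = []
    for label, fit in fits.items():
        if fit is None:
            rows.append(dict(analysis=label, term=None, beta=np.nan,
                             ci_low=np.nan, ci_high=np.nan, p=np.nan, n=0))
            continue
        p = fit.params.set_index("term")
        for t in terms:
            rows.append(dict(analysis=label, term=t, beta=p.loc[t, "beta"],
                             ci_low=p.loc[t, "ci_low"], ci_high=p.loc[t, "ci_high"],
                             p=p.loc[t, "p"], n=fit.n_used))
    return pd.DataFrame(rows)
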