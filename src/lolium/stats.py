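"""Treatment inference chain for genotype-by-CO2 trait tables.

Implements the analysis contract used throughout the pipeline:

* trait comparisons between CO2 treatments with mixed-effects models
  (treatment + chamber fixed, genotype random intercept, REML),
  Satterthwaite degrees of freedom, and a documented model-selection
  decision tree — robust re-estimation when residual diagnostics fail,
  plain (optionally heteroscedasticity-consistent) regression when the
  genotype variance component collapses to ~0;
* pairwise status-group contrasts with Benjamini-Hochberg adjustment;
* mixed-model ANCOVA trait relationships with marginal/conditional R2
  from the variance components;
* per-genotype CO2 responses, cross-treatment rank concordance,
  Spearman correlograms;
* multiple regression predictor attribution ("neat" analysis: the
  increase in R2 each predictor contributes on top of all others),
  with VIF collinearity screening and residual diagnostics;
* germination contingency tests (Fisher exact / chi-square).

Chambers are nested in treatments; with both fitted as fixed effects a
four-level chamber factor would be aliased with treatment, so chamber
enters as its within-treatment replicate contrast (one column per
treatment), which spans the same subspace at full rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .mixed import HUBER_TUNING_DEFAULT, fit_random_intercept
from .traits import TREATMENTS, percent_response

__all__ = [
    "ModelResult",
    "RelationshipFit",
    "NeatResult",
    "compare_treatments",
    "compare_status_groups",
    "fit_relationship",
    "genotype_mean_responses",
    "rank_concordance",
    "correlogram",
    "neat_analysis",
    "germination_test",
    "significance_stars",
]

#: Diagnostic alpha for the robust-fallback trigger.
DIAGNOSTIC_ALPHA = 0.05
#: Genotype variance is treated as ~0 below this fraction of the
#: residual variance, switching to plain regression.
NEGLIGIBLE_VARIANCE_RATIO = 1e-8
#: Predictors with a variance inflation factor above this are flagged
#: as collinear in the neat analysis.
VIF_CUTOFF = 10.0


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


@dataclass
class ModelResult:
    """Treatment comparison for one trait."""

    response: str
    estimate: float  # high CO2 minus ambient, chamber-adjusted
    se: float
    t_value: float
    df: float
    p_value: float
    treatment_means: dict[str, tuple[float, float, float]]  # mean, lo, hi
    model_path: str  # mixed | robust_mixed | ols | ols_hc
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class RelationshipFit:
    """Mixed-ANCOVA relationship between two traits."""

    response: str
    covariate: str
    slopes: dict[str, float]
    intercepts: dict[str, float]
    slope_ci: dict[str, tuple[float, float]]
    slope_p: dict[str, float]
    marginal_r2: dict[str, float]
    conditional_r2: dict[str, float]
    interaction_p: float | None = None


@dataclass
class NeatResult:
    """Predictor attribution for a multiple regression."""

    response: str
    predictors: list[str]
    std_coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    delta_r2: dict[str, float]
    full_r2: float
    vif: dict[str, float]
    collinear_flagged: list[str]
    diagnostics: dict[str, float] = field(default_factory=dict)


def _centered_chamber_cols(
    df: pd.DataFrame, within: pd.Series | None = None
) -> tuple[list[np.ndarray], list[str]]:
    """Sum-to-zero chamber contrasts, optionally nested in ``within``.

    Centering makes the other coefficients chamber-averaged quantities
    instead of baseline-chamber contrasts.
    """
    cols, names = [], []
    strata = within if within is not None else pd.Series("", index=df.index)
    for stratum in strata.unique():
        mask = (strata == stratum).to_numpy()
        chambers = np.sort(df.loc[mask, "chamber_id"].unique())
        m = len(chambers)
        for ch in chambers[1:]:
            col = ((df["chamber_id"] == ch).to_numpy(float) - 1.0 / m) * mask
            cols.append(col)
            names.append(f"chamber[{ch}]")
    return cols, names


def _design_treatment_chamber(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment + centered within-treatment chamber contrasts."""
    treat = (df["treatment"] == TREATMENTS[1]).to_numpy(float)
    cols = [np.ones(len(df)), treat]
    names = ["intercept", "treatment"]
    ch_cols, ch_names = _centered_chamber_cols(df, df["treatment"])
    return np.column_stack(cols + ch_cols), names + ch_names


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, np.nan, np.nan
    half = sps.t.ppf(0.5 + level / 2, len(x) - 1) * sps.sem(x)
    return m, m - half, m + half


def _ols_paths(y, X, names, response, means, diag) -> ModelResult:
    """Plain-regression fallback when the genotype variance is ~0."""
    ols = sm.OLS(y, X).fit()
    lm = het_breuschpagan(ols.resid, X)
    diag["breusch_pagan_p"] = float(lm[1])
    j = names.index("treatment")
    if lm[1] < DIAGNOSTIC_ALPHA:
        robust = sm.OLS(y, X).fit(cov_type="HC3")
        path = "ols_hc"
        est, se = robust.params[j], robust.bse[j]
        t = est / se
        p = 2 * sps.t.sf(abs(t), robust.df_resid)
        df = float(robust.df_resid)
    else:
        path = "ols"
        est, se = ols.params[j], ols.bse[j]
        t, p, df = ols.tvalues[j], ols.pvalues[j], float(ols.df_resid)
    return ModelResult(
        response=response, estimate=float(est), se=float(se), t_value=float(t),
        df=df, p_value=float(p), treatment_means=means, model_path=path,
        diagnostics=diag,
    )


def compare_treatments(data: pd.DataFrame, trait: str) -> ModelResult:
    """Test the CO2-treatment effect on one trait.

    Decision tree, following the model-selection contract:

    1. fit the mixed model (treatment + chamber fixed, genotype random,
       REML); if the genotype variance component is negligible relative
       to the residual, refit as plain regression, with an HC3
       covariance if its residuals are heteroscedastic;
    2. otherwise run Shapiro-Wilk (residual normality) and Levene by
       treatment (homoscedasticity) at alpha = 0.05 on the conditional
       residuals: both pass -> report the mixed model with
       Satterthwaite df; either fails -> Huber-type robust
       re-estimation, whose t is reported with the Satterthwaite df of
       the regular fit.
    """
    df = data.dropna(subset=[trait, "treatment", "chamber_id", "genotype_id"])
    present = set(df["treatment"].unique())
    if not set(TREATMENTS) <= present:
        missing = set(TREATMENTS) - present
        raise ValueError(f"treatment arm(s) {sorted(missing)} missing for {trait!r}")
    if df["genotype_id"].nunique() < 2:
        raise ValueError("need at least two genotypes")

    y = df[trait].to_numpy(float)
    X, names = _design_treatment_chamber(df)
    means = {
        arm: _mean_ci(df.loc[df["treatment"] == arm, trait].to_numpy(float))
        for arm in TREATMENTS
    }
    c = np.zeros(X.shape[1])
    c[names.index("treatment")] = 1.0

    if np.allclose(y, y[0]):
        # perfectly constant response: degenerate-variance path
        return ModelResult(
            response=trait, estimate=0.0, se=0.0, t_value=0.0,
            df=float(len(y) - X.shape[1]), p_value=1.0, treatment_means=means,
            model_path="ols", diagnostics={"genotype_variance": 0.0},
        )

    fit = fit_random_intercept(y, X, df["genotype_id"].to_numpy())
    diag = {
        "genotype_variance": fit.sigma2_group,
        "residual_variance": fit.sigma2_resid,
    }
    if fit.sigma2_group < NEGLIGIBLE_VARIANCE_RATIO * fit.sigma2_resid:
        return _ols_paths(y, X, names, trait, means, diag)

    resid = fit.resid_conditional()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(sps.shapiro(resid).pvalue) if len(resid) <= 5000 else float(
            sps.normaltest(resid).pvalue
        )
    groups_resid = [resid[(df["treatment"] == arm).to_numpy()] for arm in TREATMENTS]
    levene_p = float(sps.levene(*groups_resid).pvalue)
    diag["shapiro_p"] = shapiro_p
    diag["levene_p"] = levene_p

    est, se, t, dof, p = fit.ttest(c)
    diag["gls_estimate"] = est
    diag["gls_se"] = se
    if shapiro_p >= DIAGNOSTIC_ALPHA and levene_p >= DIAGNOSTIC_ALPHA:
        return ModelResult(
            response=trait, estimate=est, se=se, t_value=t, df=dof, p_value=p,
            treatment_means=means, model_path="mixed", diagnostics=diag,
        )
    rob = fit.robust_refit(HUBER_TUNING_DEFAULT)
    j = names.index("treatment")
    t_rob = float(rob.params[j] / rob.bse[j])
    p_rob = 2 * sps.t.sf(abs(t_rob), dof)
    return ModelResult(
        response=trait, estimate=float(rob.params[j]), se=float(rob.bse[j]),
        t_value=t_rob, df=dof, p_value=float(p_rob), treatment_means=means,
        model_path="robust_mixed", diagnostics=diag,
    )


def compare_status_groups(data: pd.DataFrame, trait: str) -> pd.DataFrame:
    """All pairwise status contrasts within each treatment, BH-adjusted.

    For each treatment a mixed model with status + chamber fixed and
    genotype random is fit; least-squares-mean differences between
    every status pair are tested with Satterthwaite df, and p-values
    are Benjamini-Hochberg adjusted over the contrast family of that
    treatment.
    """
    df = data.dropna(subset=[trait, "status", "genotype_id", "chamber_id"])
    out_rows = []
    for arm in TREATMENTS:
        sub = df[df["treatment"] == arm]
        levels = sorted(sub["status"].unique())
        if len(levels) < 2:
            raise ValueError(f"need at least two status groups in {arm}")
        cols = [np.ones(len(sub))]
        names = ["intercept"]
        for lev in levels[1:]:
            cols.append((sub["status"] == lev).to_numpy(float))
            names.append(lev)
        ch_cols, ch_names = _centered_chamber_cols(sub)
        cols.extend(ch_cols)
        names.extend(ch_names)
        X = np.column_stack(cols)
        fit = fit_random_intercept(
            sub[trait].to_numpy(float), X, sub["genotype_id"].to_numpy()
        )
        rows = []
        for a, b in combinations(levels, 2):
            c = np.zeros(X.shape[1])
            if a in names:
                c[names.index(a)] = -1.0
            if b in names:
                c[names.index(b)] = 1.0
            est, se, t, dof, p = fit.ttest(c)
            rows.append((arm, a, b, est, se, t, dof, p))
        pvals = [r[-1] for r in rows]
        padj = multipletests(pvals, method="fdr_bh")[1]
        for r, pa in zip(rows, padj):
            out_rows.append((*r, float(pa)))
    return pd.DataFrame(
        out_rows,
        columns=[
            "treatment", "status_a", "status_b", "estimate", "se", "t_value",
            "df", "p_value", "p_adjusted",
        ],
    )


def _relationship_one_arm(
    sub: pd.DataFrame, response: str, covariate: str
) -> tuple[float, float, tuple[float, float], float, float, float]:
    cols = [np.ones(len(sub)), sub[covariate].to_numpy(float)]
    names = ["intercept", covariate]
    ch_cols, ch_names = _centered_chamber_cols(sub)
    X = np.column_stack(cols + ch_cols)
    names.extend(ch_names)
    fit = fit_random_intercept(
        sub[response].to_numpy(float), X, sub["genotype_id"].to_numpy()
    )
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    est, se, t, dof, p = fit.ttest(c)
    half = sps.t.ppf(0.975, dof) * se
    marg, cond = fit.r2_nakagawa()
    return est, float(fit.beta[0]), (est - half, est + half), p, marg, cond


def fit_relationship(
    data: pd.DataFrame,
    response: str,
    covariate: str,
    by_treatment: bool = True,
) -> RelationshipFit:
    """Mixed-model ANCOVA of one trait on another.

    Chamber is a fixed covariate and genotype a random intercept.
    Marginal R2 is var(fixed predictions) over the total of fixed,
    random-intercept and residual variances; conditional R2 adds the
    random-intercept variance to the numerator. With ``by_treatment``
    the relationship is fit per treatment arm and a joint model with a
    treatment x covariate interaction supplies the interaction p-value;
    otherwise a single pooled fit is returned under the key 'pooled'.
    """
    df = data.dropna(subset=[response, covariate, "genotype_id", "chamber_id"])
    if len(df) < 10:
        raise ValueError("need at least 10 complete pairs")
    if float(np.std(df[covariate])) == 0.0:
        raise ValueError(f"covariate {covariate!r} is constant")

    slopes, intercepts, cis, ps, margs, conds = {}, {}, {}, {}, {}, {}
    if by_treatment:
        for arm in TREATMENTS:
            sub = df[df["treatment"] == arm]
            if len(sub) < 10:
                continue
            s, b0, ci, p, marg, cond = _relationship_one_arm(sub, response, covariate)
            slopes[arm], intercepts[arm], cis[arm] = s, b0, ci
            ps[arm], margs[arm], conds[arm] = p, marg, cond
        # joint interaction model
        x = df[covariate].to_numpy(float)
        treat = (df["treatment"] == TREATMENTS[1]).to_numpy(float)
        X = np.column_stack([np.ones(len(df)), x, treat, x * treat])
        fit = fit_random_intercept(
            df[response].to_numpy(float), X, df["genotype_id"].to_numpy()
        )
        c = np.zeros(4)
        c[3] = 1.0
        *_, inter_p = fit.ttest(c)
        interaction_p = float(inter_p)
    else:
        s, b0, ci, p, marg, cond = _relationship_one_arm(df, response, covariate)
        slopes["pooled"], intercepts["pooled"], cis["pooled"] = s, b0, ci
        ps["pooled"], margs["pooled"], conds["pooled"] = p, marg, cond
        interaction_p = None

    return RelationshipFit(
        response=response, covariate=covariate, slopes=slopes,
        intercepts=intercepts, slope_ci=cis, slope_p=ps, marginal_r2=margs,
        conditional_r2=conds, interaction_p=interaction_p,
    )


def genotype_mean_responses(
    data: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-genotype treatment means +/- SE and percent CO2 responses.

    Genotypes missing a treatment arm are dropped with a warning. The
    SE is the plain standard error of the per-plant means in each arm.
    """
    traits = traits or ["DW", "A_op"]
    rows = []
    for gid, sub in data.groupby("genotype_id"):
        arms = {arm: sub[sub["treatment"] == arm] for arm in TREATMENTS}
        if any(len(a) == 0 for a in arms.values()):
            warnings.warn(f"genotype {gid} missing a treatment arm; excluded")
            continue
        row: dict = {"genotype_id": gid, "status": sub["status"].iloc[0]}
        for trait in traits:
            vals = {arm: arms[arm][trait].dropna().to_numpy(float) for arm in TREATMENTS}
            if any(len(v) == 0 for v in vals.values()):
                row[f"{trait}_response_pct"] = np.nan
                continue
            m_a, m_h = float(vals[TREATMENTS[0]].mean()), float(vals[TREATMENTS[1]].mean())
            row[f"{trait}_mean_ambient"] = m_a
            row[f"{trait}_mean_high"] = m_h
            row[f"{trait}_se_ambient"] = (
                float(sps.sem(vals[TREATMENTS[0]])) if len(vals[TREATMENTS[0]]) > 1 else np.nan
            )
            row[f"{trait}_se_high"] = (
                float(sps.sem(vals[TREATMENTS[1]])) if len(vals[TREATMENTS[1]]) > 1 else np.nan
            )
            row[f"{trait}_response_pct"] = percent_response(m_a, m_h)
        rows.append(row)
    return pd.DataFrame(rows)


def rank_concordance(means_ambient, means_high) -> tuple[float, float]:
    """Cross-treatment rank stability of genotype means.

    Returns Spearman's rho (average ties) and the R2 of the
    rank-on-rank least-squares regression. With no ties the two
    coincide as R2 = rho^2.
    """
    a = np.asarray(means_ambient, dtype=float)
    h = np.asarray(means_high, dtype=float)
    if a.shape != h.shape or a.size < 3:
        raise ValueError("need at least 3 paired genotype means")
    rho = float(sps.spearmanr(a, h).statistic)
    ra, rh = sps.rankdata(a), sps.rankdata(h)
    r = float(np.corrcoef(ra, rh)[0, 1])
    return rho, r * r


def correlogram(data: pd.DataFrame, traits: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrix with p-values over complete cases.

    Returns (rho matrix, p matrix); plot stars from the p matrix with
    :func:`significance_stars`. Rows with any missing trait are dropped
    first (complete-case analysis).
    """
    sub = data[traits].dropna()
    if len(sub) < 5:
        raise ValueError("need at least 5 complete rows")
    k = len(traits)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        res = sps.spearmanr(sub[traits[i]], sub[traits[j]])
        rho[i, j] = rho[j, i] = res.statistic
        pmat[i, j] = pmat[j, i] = res.pvalue
    return (
        pd.DataFrame(rho, index=traits, columns=traits),
        pd.DataFrame(pmat, index=traits, columns=traits),
    )


def neat_analysis(
    data: pd.DataFrame,
    response: str = "DW",
    predictors: list[str] | None = None,
    vif_cutoff: float = VIF_CUTOFF,
) -> NeatResult:
    """Standardized multiple regression with per-predictor delta-R2.

    All variables are z-scored; the full model gives standardized
    coefficients, and each predictor's contribution is the drop in R2
    when it alone is removed (equivalently the increase it brings to a
    model already containing all the others). Predictors whose variance
    inflation factor exceeds ``vif_cutoff`` are flagged as collinear
    (they stay in the model; exclusion is the caller's decision, since
    which member of a collinear set to keep is a domain judgement).
    Residual diagnostics (Durbin-Watson, Breusch-Pagan, normality,
    maximum Cook's distance) are reported alongside.
    """
    predictors = predictors or ["tiller_count", "A_op", "WUE_op", "C_mass", "CN_ratio", "LMA"]
    sub = data[[response, *predictors]].dropna().astype(float)
    if len(sub) < len(predictors) + 2:
        raise ValueError("not enough complete cases for the regression")
    z = (sub - sub.mean()) / sub.std(ddof=1)
    yz = z[response].to_numpy()
    Xz = z[predictors].to_numpy()

    # collinearity screen on the standardized design
    Xc = sm.add_constant(Xz)
    vif = {}
    flagged = []
    for j, name in enumerate(predictors):
        v = float(variance_inflation_factor(Xc, j + 1))
        vif[name] = v
        if not np.isfinite(v) or v > vif_cutoff:
            flagged.append(name)
    rank = np.linalg.matrix_rank(Xz)
    if rank < Xz.shape[1]:
        corr = np.corrcoef(Xz.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"perfect collinearity between {predictors[i]!r} and {predictors[j]!r}"
        )

    full = sm.OLS(yz, Xc).fit()
    full_r2 = float(full.rsquared)
    delta = {}
    for j, name in enumerate(predictors):
        reduced = sm.OLS(yz, sm.add_constant(np.delete(Xz, j, axis=1))).fit()
        delta[name] = float(max(full_r2 - reduced.rsquared, 0.0))

    influence = full.get_influence()
    diagnostics = {
        "durbin_watson": float(durbin_watson(full.resid)),
        "breusch_pagan_p": float(het_breuschpagan(full.resid, Xc)[1]),
        "residual_normality_p": float(sps.shapiro(full.resid).pvalue),
        "max_cooks_distance": float(np.max(influence.cooks_distance[0])),
    }
    return NeatResult(
        response=response,
        predictors=list(predictors),
        std_coefficients={n: float(full.params[j + 1]) for j, n in enumerate(predictors)},
        coefficient_p={n: float(full.pvalues[j + 1]) for j, n in enumerate(predictors)},
        delta_r2=delta,
        full_r2=full_r2,
        vif=vif,
        collinear_flagged=flagged,
        diagnostics=diagnostics,
    )


def germination_test(counts: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Fisher exact (2x2) and chi-square tests on a germination table.

    ``counts`` has one row per group (treatment or chamber) and columns
    (germinated, failed). The chi-square statistic is Pearson's without
    continuity correction, reported for any 2xk table; Fisher's exact
    p accompanies it for 2x2 tables.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("counts must be a k x 2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, chi2_p, dof, _ = sps.chi2_contingency(table, correction=False)
    out = {"chi2": float(chi2), "chi2_p": float(chi2_p), "chi2_df": float(dof)}
    if table.shape[0] == 2:
        out["fisher_p"] = float(sps.fisher_exact(table).pvalue)
        out["fisher_odds_ratio"] = float(sps.fisher_exact(table).statistic)
    return out
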