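"""Random-intercept linear mixed-model helpers.

The trait comparisons and ANCOVAs all use the same model family: fixed
effects X plus a single random intercept per genotype,

    y = X b + Z u + e,   u ~ N(0, s2_g I),  e ~ N(0, s2_e I).

For this one-random-intercept family the REML criterion collapses, via
per-group Woodbury identities, to a one-dimensional profile over the
variance ratio s2_g / s2_e, so the fit here is a deterministic bounded
scalar optimization (validated against statsmodels MixedLM in the test
suite). On top of the fitted components:

* Satterthwaite degrees of freedom for a fixed-effect contrast c'b.
  With g(theta) = Var(c'b) = c' (X' V^-1 X)^-1 c and theta =
  (s2_g, s2_e), the approximation is df = 2 g^2 / (grad_g' A grad_g),
  where A is the asymptotic covariance of theta from the observed REML
  information (numerical Hessian of the REML log-likelihood, which has
  a cheap closed form for a single random intercept via Woodbury).
* A Huber-type robust re-estimation of the fixed effects: the data are
  whitened with the REML covariance (exact V^-1/2 per group), then the
  fixed effects are re-fit by Huber M-estimation (statsmodels RLM,
  default tuning constant 1.345). Its t-statistic is reported with the
  Satterthwaite df of the corresponding non-robust model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["RandomInterceptFit", "fit_random_intercept", "HUBER_TUNING_DEFAULT"]

HUBER_TUNING_DEFAULT = 1.345


@dataclass
class RandomInterceptFit:
    """REML fit of y = Xb + (1|group) + e with inference helpers."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    converged: bool

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta

    def resid_marginal(self) -> np.ndarray:
        return self.y - self.fitted_fixed

    def resid_conditional(self) -> np.ndarray:
        """Residuals after subtracting BLUPs of the group intercepts."""
        r = self.resid_marginal()
        out = r.copy()
        for idx in _group_indices(self.groups).values():
            n_i = len(idx)
            shrink = self.sigma2_group * n_i / (self.sigma2_resid + n_i * self.sigma2_group)
            out[idx] = r[idx] - shrink * r[idx].mean()
        return out

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Estimate and SE of c'b."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        return est, se

    def satterthwaite_df(self, c: np.ndarray) -> float:
        c = np.asarray(c, dtype=float)
        theta = np.array([self.sigma2_group, self.sigma2_resid])

        def gfun(th):
            xtvx, _, _ = _gls_crossprods(self.X, self.y, self.groups, th[0], th[1])
            return float(c @ np.linalg.inv(xtvx) @ c)

        g0 = gfun(theta)
        grad = _num_grad(gfun, theta)
        hess = _num_hess(
            lambda th: _reml_loglik(self.X, self.y, self.groups, th[0], th[1]), theta
        )
        # asymptotic covariance of the variance components; fall back to
        # a residual-df answer if the information matrix is singular
        try:
            acov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return float(len(self.y) - self.X.shape[1])
        denom = float(grad @ acov @ grad)
        if denom <= 0:
            return float(len(self.y) - self.X.shape[1])
        df = 2.0 * g0**2 / denom
        return float(np.clip(df, 1.0, len(self.y) - self.X.shape[1]))

    def ttest(self, c: np.ndarray) -> tuple[float, float, float, float, float]:
        """(estimate, se, t, satterthwaite df, p) for contrast c'b."""
        est, se = self.contrast(c)
        df = self.satterthwaite_df(c)
        t = est / se
        p = 2.0 * sps.t.sf(abs(t), df)
        return est, se, t, df, p

    def whiten(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact V^-1/2 transform of (X, y), group by group."""
        se = np.sqrt(self.sigma2_resid)
        gamma = self.sigma2_group / self.sigma2_resid
        Xw = self.X.astype(float).copy()
        yw = self.y.astype(float).copy()
        for idx in _group_indices(self.groups).values():
            n_i = len(idx)
            b = (1.0 / np.sqrt(1.0 + n_i * gamma) - 1.0) / n_i
            for arr in (Xw, yw):
                block = arr[idx]
                mean = block.mean(axis=0)
                arr[idx] = (block + n_i * b * mean) / se
        return Xw, yw

    def robust_refit(self, tuning: float = HUBER_TUNING_DEFAULT):
        """Huber M-estimate of the fixed effects on whitened data."""
        Xw, yw = self.whiten()
        rlm = sm.RLM(yw, Xw, M=sm.robust.norms.HuberT(t=tuning))
        return rlm.fit()

    def r2_nakagawa(self) -> tuple[float, float]:
        """(marginal, conditional) R2 from the variance components.

        Marginal: variance of the fixed-effect predictions over the
        total (fixed + random intercept + residual); conditional adds
        the random-intercept variance to the numerator.
        """
        var_f = float(np.var(self.fitted_fixed))
        total = var_f + self.sigma2_group + self.sigma2_resid
        return var_f / total, (var_f + self.sigma2_group) / total


def _group_indices(groups: np.ndarray) -> dict:
    idx: dict = {}
    for i, gid in enumerate(groups):
        idx.setdefault(gid, []).append(i)
    return {k: np.asarray(v) for k, v in idx.items()}


def _gls_crossprods(X, y, groups, s2g, s2e):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y via per-group Woodbury identities."""
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for idx in _group_indices(groups).values():
        Xi, yi = X[idx], y[idx]
        n_i = len(idx)
        a = s2g / (s2e + n_i * s2g)
        sx, sy = Xi.sum(axis=0), yi.sum()
        xtvx += (Xi.T @ Xi - a * np.outer(sx, sx)) / s2e
        xtvy += (Xi.T @ yi - a * sx * sy) / s2e
        ytvy += (yi @ yi - a * sy * sy) / s2e
    return xtvx, xtvy, ytvy


def _reml_loglik(X, y, groups, s2g, s2e) -> float:
    if s2e <= 0 or s2g < 0:
        return -np.inf
    logdet_v = 0.0
    for idx in _group_indices(groups).values():
        n_i = len(idx)
        logdet_v += (n_i - 1) * np.log(s2e) + np.log(s2e + n_i * s2g)
    xtvx, xtvy, ytvy = _gls_crossprods(X, y, groups, s2g, s2e)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - xtvy @ beta
    return -0.5 * (logdet_v + logdet_x + ypy)


def _num_grad(f, x, rel_step=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = rel_step * max(abs(x[i]), 1e-10)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0 if i == 0 else 1e-12)
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _num_hess(f, x, rel_step=1e-4):
    n = len(x)
    h = np.array([rel_step * max(abs(xi), 1e-8) for xi in x])
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
            xpp[i] += h[i]; xpp[j] += h[j]
            xpm[i] += h[i]; xpm[j] -= h[j]
            xmp[i] -= h[i]; xmp[j] += h[j]
            xmm[i] -= h[i]; xmm[j] -= h[j]
            if min(xpm[j], xmp[i], xmm[i], xmm[j]) < 0:
                # forward-difference fallback near the boundary s2g=0
                H[i, j] = H[j, i] = (
                    f(xpp) - f(_setpos(x, i, h[i])) - f(_setpos(x, j, h[j])) + f0
                ) / (h[i] * h[j])
            else:
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H


def _setpos(x, i, hi):
    out = x.copy()
    out[i] += hi
    return out


def _profiled_reml_criterion(gamma: float, X, y, groups, group_sizes) -> float:
    """Negative REML log-likelihood profiled over beta and s2_e.

    gamma = s2_g / s2_e. For fixed gamma the GLS estimate of beta and
    the REML estimate s2_e = y'Py / (n - p) are closed-form, leaving a
    one-dimensional criterion in gamma.
    """
    n, p = X.shape
    xtvx, xtvy, ytvy = _gls_crossprods(X, y, groups, gamma, 1.0)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    q = ytvy - xtvy @ beta
    if q <= 0:
        return np.inf
    logdet_v = float(np.sum(np.log1p(group_sizes * gamma)))
    return 0.5 * (logdet_v + logdet_x + (n - p) * np.log(q / (n - p)))


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> RandomInterceptFit:
    """Profiled REML fit of the single-random-intercept model.

    With one variance ratio gamma = s2_g / s2_e, the REML criterion is
    one-dimensional after profiling out the fixed effects and the
    residual variance, so the fit is a deterministic bounded scalar
    optimization over log(gamma) (bracketed against the gamma = 0
    boundary). Agrees with lme4 / statsmodels MixedLM REML estimates.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    sizes = np.array([len(v) for v in _group_indices(groups).values()], dtype=float)

    def crit_log(u: float) -> float:
        return _profiled_reml_criterion(np.exp(u), X, y, groups, sizes)

    res = minimize_scalar(crit_log, bounds=(-30.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    # compare against the boundary (no genotype variance)
    if _profiled_reml_criterion(0.0, X, y, groups, sizes) <= res.fun:
        gamma = 0.0
    n, p = X.shape
    xtvx, xtvy, ytvy = _gls_crossprods(X, y, groups, gamma, 1.0)
    beta = np.linalg.solve(xtvx, xtvy)
    s2e = float((ytvy - xtvy @ beta) / (n - p))
    s2g = gamma * s2e
    cov_beta = np.linalg.inv(xtvx) * s2e
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_group=s2g,
        sigma2_resid=s2e,
        X=X,
        y=y,
        groups=groups,
        converged=bool(np.isfinite(res.fun)),
    )
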