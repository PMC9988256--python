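"""Linear mixed models for the atlas design: muscle as fixed effect,
individual as random intercept, optional per-observation precision weights.

The model for response y (a cell-type eigenvector score, a gene's
log-expression, a module eigengene, or a histology metric) is

    y_ij = mu + muscle_j + u_i + e_ij,   u_i ~ N(0, s_u^2),
    e_ij ~ N(0, s_e^2 / w_ij)

fitted by REML.  Weights are absorbed exactly by scaling the response, the
fixed design and the random-intercept column by sqrt(w); the transformed
covariance is then I + theta * z_g z_g' per individual (rank one), so the
restricted likelihood is profiled down to a one-dimensional optimisation
over the variance ratio theta = s_u^2 / s_e^2 with closed-form GLS at each
step.  The muscle term is tested with a Wald F statistic on containment
denominator degrees of freedom (n_obs - n_individuals - rank deficit of the
fixed design); pairwise muscle contrasts use Tukey's studentized-range
adjustment over all muscle pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LMMResult:
    fvalue: float
    pvalue: float
    qvalue: float | None = None
    contrasts: pd.DataFrame | None = None
    var_individual: float = np.nan
    var_residual: float = np.nan
    ddf: float = np.nan
    ndf: int = 0
    singular: bool = False
    fallback_fixed: bool = False
    degenerate: bool = False
    ddf_method: str = "containment"
    muscle_means: pd.Series | None = None


def _design(muscle: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(muscle))
    X = np.ones((len(muscle), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (muscle == lev).to_numpy(float)
    return X, levels


@lru_cache(maxsize=64)
def _tukey_table(k: int, df: float) -> tuple[np.ndarray, np.ndarray]:
    """Log survival function of the studentized range on a q grid.

    scipy evaluates the studentized-range SF by numerical integration, which
    is far too slow to call per gene; within one analysis k and the
    denominator df are constant, so a cached interpolation table is exact
    enough (log-scale interpolation, relative error ~1e-3)."""
    q = np.concatenate([np.linspace(0.0, 8.0, 161),
                        np.linspace(8.1, 30.0, 220)])
    with np.errstate(over="ignore", invalid="ignore"):
        sf = stats.studentized_range.sf(q, k, df)
    return q, np.log(np.clip(sf, 1e-300, 1.0))


def _tukey_p(tstat: float, k: int, df: float) -> float:
    if k < 2 or not np.isfinite(df) or df <= 0:
        return np.nan
    q = np.sqrt(2.0) * abs(tstat)
    grid, log_sf = _tukey_table(k, round(float(df), 6))
    return float(np.clip(np.exp(np.interp(q, grid, log_sf)), 0.0, 1.0))


class _ProfiledLMM:
    """Profiled (restricted) likelihood of the weighted random-intercept
    model after the sqrt(w) row transform."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                 sw: np.ndarray):
        self.n, self.p = X.shape
        self.y, self.X = y, X
        codes, _ = pd.factorize(groups)
        self.n_groups = codes.max() + 1
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        # per-group rank-one pieces: u_g = X_g' s_g, t_g = y_g' s_g, q_g = s_g's_g
        self.u = np.zeros((self.n_groups, self.p))
        self.t = np.zeros(self.n_groups)
        self.q = np.zeros(self.n_groups)
        for g in range(self.n_groups):
            m = codes == g
            s = sw[m]
            self.u[g] = X[m].T @ s
            self.t[g] = y[m] @ s
            self.q[g] = s @ s

    def _gls(self, theta: float):
        c = theta / (1.0 + theta * self.q)           # per-group shrinkage
        xtvx = self.xtx - (self.u.T * c) @ self.u
        xtvy = self.xty - self.u.T @ (c * self.t)
        ytvy = self.yty - float(c @ (self.t ** 2))
        beta = np.linalg.solve(xtvx, xtvy)
        rss = max(ytvy - float(beta @ xtvy), 1e-300)
        return beta, xtvx, rss

    def neg2_reml(self, theta: float) -> float:
        beta, xtvx, rss = self._gls(theta)
        nmp = self.n - self.p
        sigma2 = rss / nmp
        logdet_v = float(np.log1p(theta * self.q).sum())
        sign, logdet_x = np.linalg.slogdet(xtvx)
        return (nmp * (1.0 + np.log(2.0 * np.pi * sigma2))
                + logdet_v + logdet_x)

    def neg2_ml(self, theta: float) -> float:
        _, _, rss = self._gls(theta)
        sigma2 = rss / self.n
        logdet_v = float(np.log1p(theta * self.q).sum())
        return self.n * (1.0 + np.log(2.0 * np.pi * sigma2)) + logdet_v

    def fit(self, reml: bool = True):
        obj = self.neg2_reml if reml else self.neg2_ml
        # optimise over log(theta) with a boundary check at theta = 0
        res = optimize.minimize_scalar(
            lambda lt: obj(np.exp(lt)), bounds=(-18.0, 12.0), method="bounded",
            options={"xatol": 1e-8})
        theta = float(np.exp(res.x))
        if obj(0.0) <= res.fun:
            theta = 0.0
        beta, xtvx, rss = self._gls(theta)
        dof = (self.n - self.p) if reml else self.n
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(xtvx)
        return beta, cov, theta, sigma2, -0.5 * obj(theta)


def fit_muscle_lmm(
    y,
    metadata: pd.DataFrame,
    weights=None,
) -> LMMResult:
    """REML fit of ``y ~ muscle + (1 | individual)`` with optional weights.

    ``y`` is a per-sample vector aligned with ``metadata`` (index = sample).
    Returns the muscle-term F test (containment denominator df), all
    pairwise muscle contrasts with Tukey-adjusted p-values, and the
    individual/residual variance components.  Singular random-effect fits
    (theta at the zero boundary) are flagged, not raised; with fewer than
    two individuals the model falls back to fixed effects with a warning.
    """
    y = pd.Series(np.asarray(y, float), index=metadata.index)
    muscle = metadata["muscle"]
    indiv = metadata["individual"]
    k = muscle.nunique()
    if k < 2:
        raise ValueError("need at least two muscles")
    if muscle.value_counts().min() < 2:
        raise ValueError("each muscle needs at least two observations")
    if weights is not None:
        weights = np.asarray(weights, float)
        if (weights <= 0).any() or not np.isfinite(weights).all():
            raise ValueError("weights must be positive and finite")

    n = len(y)
    X, levels = _design(muscle)
    p = X.shape[1]
    pairs = list(itertools.combinations(range(k), 2))

    if np.ptp(y.to_numpy()) == 0:
        contrasts = pd.DataFrame(
            [(levels[a], levels[b], 0.0, 0.0, 0.0, 1.0) for a, b in pairs],
            columns=["muscle_a", "muscle_b", "estimate", "se", "tstat", "p_adj"])
        return LMMResult(fvalue=0.0, pvalue=1.0, contrasts=contrasts,
                         var_individual=0.0, var_residual=0.0,
                         ddf=float(n - p), ndf=k - 1, degenerate=True,
                         muscle_means=pd.Series(y.iloc[0], index=levels))

    sw = np.sqrt(weights) if weights is not None else np.ones(n)
    endog = sw * y.to_numpy()
    exog = sw[:, None] * X

    n_groups = indiv.nunique()
    fallback = n_groups < 2
    if fallback:
        warnings.warn("fewer than two individuals; fixed-effects fallback")
        xtx = exog.T @ exog
        beta = np.linalg.solve(xtx, exog.T @ endog)
        resid = endog - exog @ beta
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * np.linalg.inv(xtx)
        theta, var_ind, var_res = 0.0, 0.0, sigma2
    else:
        model = _ProfiledLMM(endog, exog, indiv.to_numpy(), sw)
        beta, cov, theta, sigma2, _ = model.fit(reml=True)
        var_ind, var_res = theta * sigma2, sigma2
    singular = (not fallback) and theta < 1e-8

    ddf = float(n - p - (0 if fallback else n_groups - 1))
    ddf = max(ddf, 1.0)

    # Wald F for the muscle term (all non-intercept coefficients zero)
    lb = beta[1:]
    lvl = cov[1:, 1:]
    try:
        fval = float(lb @ np.linalg.solve(lvl, lb)) / (p - 1)
    except np.linalg.LinAlgError:
        fval = 0.0
    fval = max(fval, 0.0)
    pval = float(stats.f.sf(fval, p - 1, ddf))

    means = pd.Series(
        [beta[0] if j == 0 else beta[0] + beta[j] for j in range(k)],
        index=levels)
    rows = []
    for a, b in pairs:
        c = np.zeros(p)
        if a > 0:
            c[a] = 1.0
        if b > 0:
            c[b] -= 1.0
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        t = est / se if se > 0 else 0.0
        rows.append((levels[a], levels[b], est, se, t, _tukey_p(t, k, ddf)))
    contrasts = pd.DataFrame(rows, columns=[
        "muscle_a", "muscle_b", "estimate", "se", "tstat", "p_adj"])

    return LMMResult(fvalue=fval, pvalue=pval, contrasts=contrasts,
                     var_individual=var_ind, var_residual=var_res,
                     ddf=ddf, ndf=p - 1, singular=singular,
                     fallback_fixed=fallback, muscle_means=means)


def random_effect_lrt(y, metadata: pd.DataFrame, weights=None) -> tuple[float, float]:
    """Likelihood-ratio test of the individual random intercept.

    ML fit of the mixed model vs the fixed-effects model; the p-value uses
    the 0.5*chi2_0 + 0.5*chi2_1 boundary mixture.
    """
    y = pd.Series(np.asarray(y, float), index=metadata.index)
    X, _ = _design(metadata["muscle"])
    sw = np.sqrt(np.asarray(weights, float)) if weights is not None \
        else np.ones(len(y))
    endog, exog = sw * y.to_numpy(), sw[:, None] * X
    model = _ProfiledLMM(endog, exog, metadata["individual"].to_numpy(), sw)
    _, _, _, _, llf_full = model.fit(reml=False)
    llf_null = -0.5 * model.neg2_ml(0.0)
    lr = max(2.0 * (llf_full - llf_null), 0.0)
    p = 0.5 * stats.chi2.sf(lr, 1) + (0.5 if lr == 0 else 0.0)
    return float(lr), float(p)
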