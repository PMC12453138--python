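"""Smooth temporal trend fitting for diversity-metric series.

Every metric series is (age in years BP, value) pairs. Trends are fitted as
penalized B-spline smooths (generalized additive models) with a
family chosen for the response type: Poisson for counts, switching to
negative binomial or Tweedie under overdispersion; Gaussian for unbounded
real series; binomial or beta regression for proportions in [0, 1]. Count
responses that are averages (mean alpha, adjusted gamma, zeta) can be rounded
to whole numbers before fitting to retain count-like mean–variance scaling.

Series too short for a smooth (fewer than 5 points) fall back to a linear
fit in the same family. The trend test reported is a deviance-based
comparison against the intercept-only model of the same family: a chi-square
statistic where the dispersion is fixed (Poisson, binomial, negative
binomial) and an F-type statistic where it is estimated (Gaussian, Tweedie);
beta regression uses a likelihood-ratio test. Smoothing penalty weights are
selected by grid search on an AIC with effective degrees of freedom, so
fitted shapes — not any specific published F/edf values, which are
smoother-implementation dependent — are the reproducible quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "TrendFit",
    "fit_trend",
    "select_family",
    "classify_trend",
    "FAMILIES",
]

FAMILIES = ("poisson", "negative_binomial", "tweedie", "gaussian", "binomial", "beta")

# families whose dispersion is fixed at 1 (trend test uses chi-square)
_FIXED_SCALE = {"poisson", "binomial", "negative_binomial"}


@dataclass
class TrendFit:
    metric: str
    family: str
    effective_complexity: float  # edf-analogue: trace of the influence matrix
    test_statistic: float
    statistic_name: str  # "chi2" | "F" | "LR"
    p_value: float
    r2_adj: float  # deviance-based adjusted pseudo-R^2
    curve: pd.DataFrame  # columns: age, fit, lower95, upper95
    n_obs: int
    is_linear: bool
    dispersion: float  # Pearson chi2 / residual df
    notes: str = ""

    def direction(self, alpha: float = 0.05) -> str:
        """'increasing' / 'decreasing' / 'flat' — change toward the present.

        Age runs backwards (older = larger), so a metric increases over time
        when its fitted value at the youngest age exceeds that at the oldest.
        """
        if not np.isfinite(self.p_value) or self.p_value >= alpha:
            return "flat"
        young = self.curve.loc[self.curve["age"].idxmin(), "fit"]
        old = self.curve.loc[self.curve["age"].idxmax(), "fit"]
        if np.isclose(young, old):
            return "flat"
        return "increasing" if young > old else "decreasing"


def _nb_alpha_moment(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion: var = mu + alpha mu^2."""
    num = ((y - mu) ** 2 - mu) / np.maximum(mu**2, 1e-12)
    return float(np.clip(np.mean(num), 1e-4, 100.0))


def _make_family(name: str, y=None, mu=None):
    if name == "poisson":
        return sm.families.Poisson()
    if name == "negative_binomial":
        alpha = _nb_alpha_moment(y, mu) if y is not None and mu is not None else 1.0
        return sm.families.NegativeBinomial(alpha=alpha)
    if name == "tweedie":
        return sm.families.Tweedie(var_power=1.5)
    if name == "gaussian":
        return sm.families.Gaussian()
    if name == "binomial":
        return sm.families.Binomial()
    raise ValueError(f"unknown GLM family {name!r}")


def _validate(ages, values, family: str):
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1-d arrays of equal length")
    if not (np.isfinite(ages).all() and np.isfinite(values).all()):
        raise ValueError("non-finite ages or values")
    if family in {"binomial", "beta"} and ((values < 0) | (values > 1)).any():
        raise ValueError(f"{family} family requires responses in [0, 1]")
    if family in {"poisson", "negative_binomial"} and (values < 0).any():
        raise ValueError(f"{family} family requires non-negative responses")
    order = np.argsort(-ages)  # oldest first
    return ages[order], values[order]


def _beta_compress(y: np.ndarray) -> np.ndarray:
    """Smithson–Verkuilen compression of [0,1] onto (0,1) for beta regression."""
    n = len(y)
    return (y * (n - 1) + 0.5) / n


_GRID = np.logspace(-3, 5, 9)


def _fit_gam(x, y, family_name: str, spline_df: int):
    """Penalized B-spline GAM with penalty weight chosen by effective-df AIC."""
    bs = BSplines(x[:, None], df=[spline_df], degree=[3])
    exog = np.ones((len(y), 1))
    mu0 = np.full_like(y, max(y.mean(), 1e-8), dtype=float)
    fam = _make_family(family_name, y, mu0)
    if family_name == "negative_binomial":
        # refine the moment alpha against a preliminary Poisson smooth
        pre = GLMGam(y, exog=exog, smoother=bs, alpha=[1.0],
                     family=sm.families.Poisson()).fit()
        fam = sm.families.NegativeBinomial(alpha=_nb_alpha_moment(y, pre.fittedvalues))
    best = None
    for a in _GRID:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = GLMGam(y, exog=exog, smoother=bs, alpha=[a], family=fam).fit()
            except Exception:
                continue
        edf = float(res.hat_matrix_trace)
        llf = res.llf if np.isfinite(res.llf) else -0.5 * res.deviance
        aic = -2.0 * llf + 2.0 * edf
        if best is None or aic < best[0]:
            best = (aic, res, bs)
    if best is None:
        raise RuntimeError("GAM fit failed at every penalty weight")
    return best[1], best[2]


def _deviance_test(res, family_name: str, edf: float, n: int):
    """Trend test against the intercept-only model of the same family."""
    dev, null_dev = float(res.deviance), float(res.null_deviance)
    df_num = max(edf - 1.0, 1e-8)
    df_den = max(n - edf, 1e-8)
    if null_dev <= 1e-12:  # constant series: nothing to explain
        return 0.0, "chi2" if family_name in _FIXED_SCALE else "F", 1.0
    if family_name in _FIXED_SCALE:
        stat = max(null_dev - dev, 0.0)
        p = float(stats.chi2.sf(stat, df_num))
        return stat, "chi2", p
    scale = max(float(res.pearson_chi2) / df_den, 1e-12)
    stat = max(null_dev - dev, 0.0) / df_num / scale
    p = float(stats.f.sf(stat, df_num, df_den))
    return stat, "F", p


def _pseudo_r2_adj(dev: float, null_dev: float, edf: float, n: int) -> float:
    if null_dev <= 1e-12:
        return 0.0
    return float(1.0 - (dev / max(n - edf, 1e-8)) / (null_dev / (n - 1)))


def fit_trend(
    ages,
    values,
    family: str = "gaussian",
    rounding: bool = False,
    metric: str = "",
    linear: bool = False,
    spline_df: int | None = None,
    n_curve: int = 100,
) -> TrendFit:
    """Fit a smooth temporal trend to one metric series.

    ``rounding=True`` rounds the response to the nearest whole number before
    a count-family fit. Series with fewer than 5 observations (or
    ``linear=True``) use a linear predictor in the same family; the fallback
    is reported on the fit. The fitted curve (with a pointwise 95% band on
    the mean) covers the observed age range only.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    x, y = _validate(ages, values, family)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if rounding:
        y = np.rint(y)
    if np.ptp(np.rint(y) if rounding else y) == 0.0:
        # constant response: nothing to fit, report a flat trend directly
        yc = float((np.rint(y) if rounding else y)[0])
        grid0 = np.linspace(x.min(), x.max(), n_curve)
        return TrendFit(
            metric=metric, family=family, effective_complexity=1.0,
            test_statistic=0.0,
            statistic_name="chi2" if family in _FIXED_SCALE else "F",
            p_value=1.0, r2_adj=0.0,
            curve=pd.DataFrame({"age": grid0, "fit": yc, "lower95": yc, "upper95": yc}),
            n_obs=n, is_linear=True, dispersion=0.0,
            notes="constant series",
        )
    notes = []
    use_linear = linear or n < 5
    if not linear and n < 5:
        notes.append("fewer than 5 observations: linear fallback")
    grid = np.linspace(x.min(), x.max(), n_curve)
    z = (x - x.mean()) / max(x.std(), 1e-12)  # scaled predictor for linear fits
    zg = (grid - x.mean()) / max(x.std(), 1e-12)

    if family == "beta":
        yb = _beta_compress(y) if ((y <= 0) | (y >= 1)).any() else y
        if ((y <= 0) | (y >= 1)).any():
            notes.append("boundary proportions compressed into (0,1)")
        if use_linear:
            X, Xg = np.column_stack([np.ones(n), z]), np.column_stack([np.ones(len(zg)), zg])
        else:
            df_s = spline_df or min(6, n - 2)
            bs = BSplines(x[:, None], df=[df_s], degree=[3])
            X = np.column_stack([np.ones(n), bs.basis])
            Xg = np.column_stack([np.ones(len(grid)), bs.transform(grid[:, None])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BetaModel(yb, X).fit(disp=False)
            null = BetaModel(yb, np.ones((n, 1))).fit(disp=False)
        k_mean = X.shape[1]
        lr = max(2.0 * (res.llf - null.llf), 0.0)
        p = float(stats.chi2.sf(lr, k_mean - 1))
        eta = Xg @ res.params[:k_mean]
        cov = np.asarray(res.cov_params())[:k_mean, :k_mean]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
        expit = lambda v: 1.0 / (1.0 + np.exp(-v))
        fit_curve = expit(eta)
        lo, hi = expit(eta - 1.96 * se), expit(eta + 1.96 * se)
        resid = yb - expit(X @ res.params[:k_mean])
        r2 = 1.0 - np.var(resid) / max(np.var(yb), 1e-12)
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k_mean, 1e-8)
        return TrendFit(
            metric=metric, family="beta", effective_complexity=float(k_mean),
            test_statistic=lr, statistic_name="LR", p_value=p, r2_adj=float(r2_adj),
            curve=pd.DataFrame({"age": grid, "fit": fit_curve, "lower95": lo, "upper95": hi}),
            n_obs=n, is_linear=use_linear,
            dispersion=float(np.var(resid)), notes="; ".join(notes),
        )

    res = None
    if not use_linear:
        df_s = spline_df or min(6, max(4, n - 2))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res, bs = _fit_gam(x, y, family, df_s)
        except RuntimeError:
            # e.g. an exact fit makes penalized IRLS report perfect separation
            use_linear = True
            notes.append("smooth fit degenerate: linear fallback")
    if use_linear:
        X = np.column_stack([np.ones(n), z])
        fam = _make_family(family, y, np.full(n, max(y.mean(), 1e-8)))
        if family == "negative_binomial":
            pre = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            fam = sm.families.NegativeBinomial(alpha=_nb_alpha_moment(y, pre.fittedvalues))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit()
        edf = 2.0
        pred = res.get_prediction(np.column_stack([np.ones(len(zg)), zg]))
        sf = pred.summary_frame(alpha=0.05)
    else:
        edf = float(res.hat_matrix_trace)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = res.get_prediction(exog=np.ones((len(grid), 1)),
                                      exog_smooth=grid[:, None])
            sf = pred.summary_frame(alpha=0.05)
    stat, stat_name, p = _deviance_test(res, family, edf, n)
    disp = float(res.pearson_chi2) / max(n - edf, 1e-8)
    curve = pd.DataFrame(
        {
            "age": grid,
            "fit": sf["mean"].to_numpy(),
            "lower95": sf["mean_ci_lower"].to_numpy(),
            "upper95": sf["mean_ci_upper"].to_numpy(),
        }
    )
    fam_label = family
    if family == "negative_binomial":
        fam_label = f"negative_binomial(alpha={res.model.family.alpha:.3g})"
    return TrendFit(
        metric=metric, family=fam_label, effective_complexity=edf,
        test_statistic=float(stat), statistic_name=stat_name, p_value=p,
        r2_adj=_pseudo_r2_adj(float(res.deviance), float(res.null_deviance), edf, n),
        curve=curve, n_obs=n, is_linear=use_linear, dispersion=disp,
        notes="; ".join(notes),
    )


def select_family(
    ages,
    values,
    candidate: str = "poisson",
    threshold: float = 1.5,
    rounding: bool = False,
    metric: str = "",
    **kw,
) -> TrendFit:
    """Fit a count series, escalating the family under overdispersion.

    The candidate (Poisson) fit is kept when its Pearson dispersion statistic
    is at most ``threshold``; otherwise the negative binomial and then the
    Tweedie family are tried, returning the first adequately dispersed fit,
    or the best-dispersed fit with a warning note when none is adequate.
    Degenerate (constant) series fall back to a Gaussian linear fit.
    """
    y = np.rint(np.asarray(values, dtype=float)) if rounding else np.asarray(values, dtype=float)
    if np.allclose(y, y[0] if len(y) else 0.0):
        fit = fit_trend(ages, values, family="gaussian", metric=metric, linear=True, **kw)
        fit.notes = (fit.notes + "; " if fit.notes else "") + \
            "degenerate (constant) series: gaussian fallback"
        return fit
    trail = []
    best = None
    for fam in (candidate, "negative_binomial", "tweedie"):
        fit = fit_trend(ages, values, family=fam, rounding=rounding, metric=metric, **kw)
        trail.append(f"{fam}: dispersion {fit.dispersion:.2f}")
        if best is None or abs(fit.dispersion - 1.0) < abs(best.dispersion - 1.0):
            best = fit
        if fit.dispersion <= threshold:
            fit.notes = (fit.notes + "; " if fit.notes else "") + " -> ".join(trail)
            return fit
    best.notes = (best.notes + "; " if best.notes else "") + \
        "no family adequately dispersed; best kept: " + " -> ".join(trail)
    return best


def classify_trend(ages, values, family: str = "gaussian", linear: bool = True,
                   alpha: float = 0.05, rounding: bool = False) -> str:
    """Convenience direction classifier: 'increasing'/'decreasing'/'flat'."""
    fit = fit_trend(ages, values, family=family, linear=linear, rounding=rounding)
    return fit.direction(alpha=alpha)
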