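"""Model-fitting kernel shared by every analysis stage.

Implements the small set of likelihood-based fits the pipeline relies on:

* binomial (logit-link) GLM by iteratively reweighted least squares, with a
  vectorized multi-dataset Newton solver used by the sliding-window scan,
* profile-likelihood odds-ratio intervals (asymmetric, from inverting the
  likelihood-ratio test along the slope),
* McFadden's pseudo-R-squared,
* ordinary least squares with t statistics,
* NB2 negative-binomial GLM (log link, variance mu + mu^2/k) via statsmodels,
* likelihood-ratio tests between nested maximum-likelihood fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "GlmFit",
    "OddsRatio",
    "LmFit",
    "NbFit",
    "LrtResult",
    "fit_binomial_glm",
    "batch_logistic",
    "profile_odds_ratio",
    "mcfadden_r2",
    "fit_linear_model",
    "fit_negbin_glm",
    "likelihood_ratio_test",
]

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-10
SEPARATION_BETA = 30.0  # |slope| on a standardized covariate


class FitError(ValueError):
    """Raised when a model cannot be fitted on the given data."""


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: -log(1 + exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y > 0.5, -eta, eta))))


def _null_loglik(y: np.ndarray) -> float:
    n = len(y)
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def _is_separated_1d(y: np.ndarray, x: np.ndarray) -> bool:
    """Complete separation check for a single covariate: after sorting by x,
    the classes occupy disjoint covariate ranges."""
    if y.min() == y.max():
        return False
    x0, x1 = x[y < 0.5], x[y > 0.5]
    return bool(x0.max() < x1.min() or x1.max() < x0.min())


@dataclass
class GlmFit:
    """Binomial GLM fit (logit link)."""

    params: np.ndarray          # [intercept, slopes...]
    bse: np.ndarray
    loglik: float
    null_loglik: float
    fitted: np.ndarray          # fitted probabilities
    converged: bool
    separation: bool
    y: np.ndarray
    X: np.ndarray               # design incl. intercept column
    names: tuple[str, ...]

    @property
    def nobs(self) -> int:
        return len(self.y)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.names

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Fitted probability at new covariate values (single-covariate fit)."""
        x_new = np.asarray(x_new, dtype=float)
        if self.n_params != 2:
            raise FitError("predict(x) requires a single-covariate fit")
        return expit(self.params[0] + self.params[1] * x_new)

    def summary(self) -> str:
        lines = [f"Binomial GLM (logit), n={self.nobs}, loglik={self.loglik:.4f}"]
        for name, b, se in zip(self.names, self.params, self.bse):
            lines.append(f"  {name:>12s}  coef={b: .6g}  se={se:.4g}")
        if self.separation:
            lines.append("  [complete separation detected: estimates diverge]")
        return "\n".join(lines)


@dataclass(frozen=True)
class OddsRatio:
    """Odds ratio per unit covariate with profile-likelihood bounds."""

    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.lower < self.point < self.upper):
            raise FitError(
                f"odds-ratio interval must bracket the point estimate: "
                f"{self.lower} < {self.point} < {self.upper} fails"
            )


def fit_binomial_glm(y: Sequence[float], x: Sequence[float] | np.ndarray | None,
                     names: Sequence[str] | None = None) -> GlmFit:
    """Maximum-likelihood logit fit by IRLS (Newton with step halving).

    ``x`` is a covariate vector, a (n, k) covariate matrix, or None for an
    intercept-only fit; an intercept column is always prepended.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise FitError("responses must be 0/1")
    n = len(y)
    if n < 3:
        raise FitError("need at least 3 observations")
    if x is None:
        X = np.ones((n, 1))
        covnames: tuple[str, ...] = ("intercept",)
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if len(x) != n:
            raise FitError("x and y lengths differ")
        sds = x.std(axis=0)
        if np.any(sds == 0) and y.min() != y.max():
            raise FitError("constant covariate with varying response: slope undefined")
        X = np.column_stack([np.ones(n), x])
        if names is None:
            covnames = ("intercept",) + tuple(f"x{j + 1}" for j in range(x.shape[1]))
        else:
            covnames = ("intercept",) + tuple(names)
    if y.min() == y.max():
        raise FitError("response takes a single value: degenerate fit")

    separated = X.shape[1] == 2 and _is_separated_1d(y, X[:, 1])

    beta = np.zeros(X.shape[1])
    ll = _bernoulli_loglik(y, X @ beta)
    converged = False
    for _ in range(MAX_IRLS_ITER):
        eta = np.clip(X @ beta, -35, 35)
        p = expit(eta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee a monotone log-likelihood
        new_ll = -np.inf
        for _h in range(30):
            cand = beta + step
            new_ll = _bernoulli_loglik(y, X @ cand)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if abs(new_ll - ll) < IRLS_TOL * (abs(ll) + 1.0) and np.max(np.abs(grad)) < 1e-8:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = np.clip(X @ beta, -35, 35)
    p = expit(eta)
    w = p * (1 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(len(beta), np.nan)

    if X.shape[1] > 1:
        sds = X[:, 1:].std(axis=0)
        if np.any(np.abs(beta[1:]) * sds > SEPARATION_BETA):
            separated = True

    return GlmFit(
        params=beta,
        bse=bse,
        loglik=float(_bernoulli_loglik(y, X @ beta)),
        null_loglik=_null_loglik(y),
        fitted=p,
        converged=converged or separated,
        separation=separated,
        y=y,
        X=X,
        names=covnames,
    )


def batch_logistic(y: np.ndarray, covariates: np.ndarray,
                   max_iter: int = 60) -> dict[str, np.ndarray]:
    """Fit many single-covariate logit GLMs sharing the response.

    ``covariates`` has shape (W, n): one row per candidate covariate (window),
    sharing the 0/1 response ``y`` of length n.  A damped Newton iteration is
    run simultaneously for all W fits.  Returns arrays ``b0``, ``b1``,
    ``loglik``, ``converged``, ``separated`` of length W.
    """
    y = np.asarray(y, dtype=float)
    Xc = np.asarray(covariates, dtype=float)
    W, n = Xc.shape
    if len(y) != n:
        raise FitError("response length does not match covariate rows")
    b0 = np.zeros(W)
    b1 = np.zeros(W)
    sds = Xc.std(axis=1)
    # centre each covariate for conditioning; un-centre at the end
    mus = Xc.mean(axis=1)
    Z = Xc - mus[:, None]
    max_step = 5.0
    grad_norm = np.full(W, np.inf)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * Z, -35, 35)
        p = expit(eta)
        r = y[None, :] - p
        g0 = r.sum(axis=1)
        g1 = (r * Z).sum(axis=1)
        w = p * (1 - p)
        h00 = w.sum(axis=1)
        h01 = (w * Z).sum(axis=1)
        h11 = (w * Z * Z).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(det <= 1e-300, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.clip(np.nan_to_num(d0), -max_step, max_step)
        scale = np.where(sds > 0, sds, 1.0)
        d1 = np.clip(np.nan_to_num(d1), -max_step / scale, max_step / scale)
        b0 += d0
        b1 += d1
        grad_norm = np.maximum(np.abs(g0), np.abs(g1))
        if np.all(grad_norm < 1e-9):
            break
    eta = np.clip(b0[:, None] + b1[:, None] * Z, -35, 35)
    ll = -np.sum(np.logaddexp(0.0, np.where(y[None, :] > 0.5, -eta, eta)), axis=1)
    separated = np.abs(b1) * sds > SEPARATION_BETA
    converged = (grad_norm < 1e-6) | separated
    return {
        "b0": b0 - b1 * mus,
        "b1": b1,
        "loglik": ll,
        "converged": converged,
        "separated": separated,
    }


def _profile_loglik(y: np.ndarray, x: np.ndarray, b1: float) -> float:
    """Log-likelihood maximized over the intercept at a fixed slope.

    The covariate is centred internally (the profile of the slope is
    invariant to covariate shifts, which the intercept absorbs)."""
    offset = b1 * (x - x.mean())
    pbar = min(max(y.mean(), 1e-9), 1 - 1e-9)
    b0 = float(np.log(pbar / (1 - pbar)))
    ll = _bernoulli_loglik(y, offset + b0)
    for _ in range(200):
        eta = np.clip(offset + b0, -35, 35)
        p = expit(eta)
        g = np.sum(y - p)
        h = np.sum(p * (1 - p))
        if h <= 0:
            break
        step = g / h
        improved = False
        new_ll = ll
        for _h in range(50):
            new_ll = _bernoulli_loglik(y, offset + b0 + step)
            if new_ll >= ll - 1e-13:
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        b0 += step
        if abs(new_ll - ll) < 1e-13 * (abs(ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    return ll


def profile_odds_ratio(fit: GlmFit, level: float = 0.95) -> OddsRatio:
    """Profile-likelihood CI for the odds ratio of a single-covariate fit.

    The bounds are exp of the slope values at which the profile deviance
    rises by the chi-square(1) quantile above its minimum; asymmetric when
    the likelihood surface is skewed.
    """
    if fit.n_params != 2:
        raise FitError("profile odds ratio requires a single-covariate fit")
    if fit.separation:
        raise FitError("profile interval undefined under complete separation")
    y, x = fit.y, fit.X[:, 1]
    bhat = float(fit.params[1])
    llhat = fit.loglik
    q = sps.chi2.ppf(level, 1)
    target = llhat - q / 2.0

    se = fit.bse[1]
    if not np.isfinite(se) or se <= 0:
        se = 1.0 / max(x.std(), 1e-6)

    def g(b1: float) -> float:
        return _profile_loglik(y, x, b1) - target

    from scipy.optimize import brentq

    bounds = []
    for direction in (-1.0, 1.0):
        step = se
        b_out = bhat
        found = False
        for _ in range(60):
            b_out = b_out + direction * step
            if g(b_out) < 0:
                found = True
                break
            step *= 1.6
        if not found:
            side = "lower" if direction < 0 else "upper"
            raise FitError(f"profile interval fails to bracket on the {side} side")
        lo, hi = sorted((b_out - direction * step, b_out))
        bounds.append(brentq(g, lo, hi, xtol=1e-10))
    lower, upper = sorted(bounds)
    return OddsRatio(point=float(np.exp(bhat)), lower=float(np.exp(lower)),
                     upper=float(np.exp(upper)), level=level)


def mcfadden_r2(fit) -> float:
    """McFadden's pseudo-R-squared, 1 - loglik/null_loglik."""
    ll0 = fit.null_loglik
    if ll0 == 0.0:
        raise FitError("null log-likelihood is zero: pseudo-R2 undefined")
    return float(1.0 - fit.loglik / ll0)


@dataclass(frozen=True)
class LmFit:
    """Simple linear regression with a t test on the slope."""

    slope: float
    intercept: float
    slope_se: float
    resid_se: float
    t: float
    pvalue: float
    df_resid: int
    nobs: int

    def predict(self, x_new) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x_new, dtype=float)

    def summary(self) -> str:
        return (f"OLS: slope={self.slope:.6g} (se {self.slope_se:.3g}), "
                f"t_(1,{self.df_resid})={self.t:.3f}, p={self.pvalue:.4g}")


def fit_linear_model(y: Sequence[float], x: Sequence[float]) -> LmFit:
    """OLS of y on x with the classical t statistic (df = n - 2)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise FitError("need at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise FitError("constant covariate")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    df = n - 2
    rss = float(np.sum(resid ** 2))
    resid_se = float(np.sqrt(rss / df)) if df > 0 else 0.0
    slope_se = float(resid_se / np.sqrt(sxx))
    if slope_se == 0.0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / slope_se
        p = float(2 * sps.t.sf(abs(t), df))
    return LmFit(slope=slope, intercept=intercept, slope_se=slope_se,
                 resid_se=resid_se, t=float(t), pvalue=p, df_resid=df, nobs=n)


@dataclass
class NbFit:
    """NB2 negative-binomial GLM fit (log link, variance mu + mu^2/k)."""

    coefficients: dict[str, float]
    bse: dict[str, float]
    k: float                       # dispersion (size); variance = mu + mu^2/k
    loglik: float
    converged: bool
    large_k: bool                  # effectively Poisson
    nobs: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        # fixed-effect parameter count; dispersion is common to nested pairs
        return len(self.coefficients)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def summary(self) -> str:
        lines = [f"NB2 GLM, n={self.nobs}, k={self.k:.4g}, loglik={self.loglik:.4f}"]
        for name, b in self.coefficients.items():
            lines.append(f"  {name:>16s}  coef={b: .6g}  exp(coef)={np.exp(b):.4g}"
                         f"  se={self.bse[name]:.4g}")
        return "\n".join(lines)


def fit_negbin_glm(y: Sequence[int], design: pd.DataFrame | None) -> NbFit:
    """Joint ML fit of an NB2 GLM over coefficients and dispersion.

    ``design`` holds the covariates (no intercept column; one is added).
    Pass None for an intercept-only model.
    """
    import statsmodels.api as sm

    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        if np.any(np.asarray(y, dtype=float) % 1 != 0) or np.any(np.asarray(y, float) < 0):
            raise FitError("responses must be non-negative integers")
        y = np.asarray(y, dtype=int)
    n = len(y)
    if design is None or design.shape[1] == 0:
        X = pd.DataFrame({"intercept": np.ones(n)})
    else:
        X = design.copy().astype(float)
        X.insert(0, "intercept", 1.0)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise FitError(f"collinear design: {list(X.columns)}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X.to_numpy(), loglike_method="nb2")
        # start from a Poisson GLM plus a small dispersion guess; also skips
        # the library's internal preliminary fit, which re-enables warnings
        try:
            pois = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
            start0 = np.append(np.asarray(pois.params, dtype=float), 0.1)
        except Exception:
            start0 = None
        res = None
        for method in ("bfgs", "nm", "newton"):
            try:
                start = start0 if res is None else res.params
                res = model.fit(method=method, maxiter=2000, disp=0,
                                start_params=start)
            except Exception:
                continue
            if res.mle_retvals.get("converged", False):
                break
        if res is None:
            raise FitError("negative-binomial fit failed")
        params = np.asarray(res.params, dtype=float)
        all_bse = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)
        converged = bool(res.mle_retvals.get("converged", False))
    alpha = max(float(params[-1]), 1e-12)
    coefs = dict(zip(X.columns, params[:-1]))
    bse = dict(zip(X.columns, all_bse[:-1]))
    k = 1.0 / alpha
    mu = np.exp(np.clip(X.to_numpy() @ params[:-1], -30, 30))
    return NbFit(
        coefficients=coefs,
        bse=bse,
        k=k,
        loglik=llf,
        converged=converged,
        large_k=k > 1e4,
        nobs=n,
        fitted=mu,
    )


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of nested maximum-likelihood fits."""

    statistic: float   # 2 * (loglik_full - loglik_reduced)
    df: int
    pvalue: float


def likelihood_ratio_test(full, reduced) -> LrtResult:
    """2*(l_full - l_reduced) against chi-square with df = parameter difference.

    Both fits must be ML fits on identical rows; ``reduced`` must be nested
    in ``full`` (checked via term names when both expose them).
    """
    if full.nobs != reduced.nobs:
        raise FitError("models fitted on different row sets")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise FitError("reduced model has more parameters than the full model")
    f_names = getattr(full, "term_names", None)
    r_names = getattr(reduced, "term_names", None)
    if f_names is not None and r_names is not None:
        if not set(r_names) <= set(f_names):
            raise FitError("reduced model terms are not a subset of the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise FitError(f"negative LR statistic ({stat:.3g}): models not nested?")
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return LrtResult(statistic=float(stat), df=df, pvalue=p)
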