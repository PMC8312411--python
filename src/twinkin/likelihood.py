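"""Full-information maximum-likelihood (FIML) machinery shared by all models.

Every model in the package reduces to sums of multivariate-normal
log-densities over twin pairs: a complete pair contributes the joint density
of its observed phenotype vector, a singleton the marginal of the observed
subvector — no imputation, no listwise deletion.  Two evaluators cover the
two structural cases:

* a constant expected covariance per zygosity group (classical models):
  rows are grouped by missingness pattern and evaluated vectorised;
* a per-pair expected covariance (moderation models, where path
  coefficients depend on each twin's own moderator value): batched linear
  algebra over stacks of small matrices.

All likelihoods are reported on the −2·log L scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

_LOG2PI = float(np.log(2.0 * np.pi))
#: objective value used to reject an infeasible/singular trial point
REJECT = 1e12


def mvn_m2ll_pattern(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """−2 log-likelihood of rows of ``y`` under N(mu_i, sigma), nan = missing.

    ``y`` and ``mu`` are (n, k); ``sigma`` is a single (k, k) covariance.
    Rows with all entries missing contribute nothing.  Returns ``REJECT``
    (a large finite penalty) if any needed sub-covariance is not positive
    definite, so optimizers can continue past infeasible trial points.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if not (np.all(np.isfinite(sigma)) and np.all(np.isfinite(mu))):
        return REJECT
    k = y.shape[1]
    obs = ~np.isnan(y)
    total = 0.0
    # group rows by missingness pattern; each pattern costs one factorization
    codes = obs @ (1 << np.arange(k))
    for code in np.unique(codes):
        mask = codes == code
        pattern = obs[np.argmax(mask)]
        m = int(pattern.sum())
        if m == 0:
            continue
        sub = sigma[np.ix_(pattern, pattern)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return REJECT
        resid = (y[mask][:, pattern] - mu[mask][:, pattern]).T
        z = solve_triangular(chol, resid, lower=True)
        logdet = 2.0 * float(np.log(np.diag(chol)).sum())
        n_rows = int(mask.sum())
        total += n_rows * (m * _LOG2PI + logdet) + float((z * z).sum())
    return float(total)


def mvn_m2ll_batched(y: np.ndarray, mu: np.ndarray, sigmas: np.ndarray) -> float:
    """−2 log L with a distinct covariance per row (complete rows only).

    ``y``/``mu`` are (n, k); ``sigmas`` is (n, k, k).  2×2 systems use the
    closed form; larger ones batched Cholesky.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if not (np.all(np.isfinite(sigmas)) and np.all(np.isfinite(mu))):
        return REJECT
    n, k = y.shape
    r = y - mu
    if k == 1:
        v = sigmas.reshape(n)
        if np.any(v <= 0):
            return REJECT
        return float(np.sum(_LOG2PI + np.log(v) + r[:, 0] ** 2 / v))
    if k == 2:
        v1, v2, c = sigmas[:, 0, 0], sigmas[:, 1, 1], sigmas[:, 0, 1]
        det = v1 * v2 - c * c
        if np.any(det <= 0) or np.any(v1 <= 0):
            return REJECT
        quad = (v2 * r[:, 0] ** 2 - 2 * c * r[:, 0] * r[:, 1] + v1 * r[:, 1] ** 2) / det
        return float(np.sum(2 * _LOG2PI + np.log(det) + quad))
    try:
        chol = np.linalg.cholesky(sigmas)
    except np.linalg.LinAlgError:
        return REJECT
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    z = np.linalg.solve(chol, r[:, :, None])[:, :, 0]
    return float(np.sum(k * _LOG2PI + logdet + (z * z).sum(axis=1)))


# ---------------------------------------------------------------------------
# optimization


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``estimates`` holds named, interpretable quantities (standardized
    variance shares, correlations, means-model coefficients); ``params`` the
    raw optimizer vector.  ``ci`` is filled lazily by profile-likelihood
    routines.  The AIC identity ``aic = minus2ll + 2 * n_params`` always
    holds.
    """

    estimates: dict
    minus2ll: float
    n_params: int
    converged: bool
    gradient_norm: float
    params: np.ndarray
    param_names: list[str]
    spec: object = None
    ci: dict = field(default_factory=dict)
    n_restarts_agreeing: int = 1
    _objective: Callable | None = None
    _bounds: list | None = None
    _estimator: Callable | None = None

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    def __getitem__(self, name):
        return self.estimates[name]


def multistart_minimize(fun, x0, bounds, n_restarts: int = 5, seed=0,
                        jitter: float = 0.1, tol: float = 1e-9):
    """Quasi-Newton minimization from jittered starts; returns the best.

    Ties are broken by lowest objective, then lowest gradient norm.  The
    first start is ``x0`` itself; subsequent starts perturb it within
    bounds.  Also reports how many converged starts agree with the best
    objective within 1e-3 (a multimodality diagnostic).
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    results = []
    for i in range(max(1, n_restarts)):
        start = x0.copy()
        if i > 0:
            scale = np.where(np.isfinite(hi - lo), (hi - lo), 1.0) * jitter
            start = np.clip(start + rng.normal(0, 1, size=start.shape) * scale, lo, hi)
        res = optimize.minimize(fun, start, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 5000, "ftol": tol,
                                         "gtol": 1e-9 if tol < 1e-10 else 1e-8})
        results.append(res)
    best = min(results, key=lambda r: (r.fun, float(np.abs(r.jac).max())))
    agree = sum(1 for r in results if r.fun <= best.fun + 1e-3)
    return best, agree


def profile_ci(objective, x_mle: np.ndarray, m2ll_min: float, index: int,
               bounds, level: float = 0.95, step: float | None = None,
               max_expand: int = 60):
    """Profile-likelihood confidence interval for one raw parameter.

    Finds the values of parameter ``index`` at which the profiled −2 log L
    rises by the χ²₁ quantile for ``level`` (3.841 at 95%), re-optimizing
    all other parameters at each trial value.  Endpoints clipped at the
    parameter's bounds are returned as the bound itself (boundary-limited,
    matching the reporting convention of zero lower limits for variance
    shares).
    """
    from scipy.stats import chi2

    crit = float(chi2.ppf(level, df=1))
    lo, hi = bounds[index]
    lo = -np.inf if lo is None else lo
    hi = np.inf if hi is None else hi
    free = [i for i in range(len(x_mle)) if i != index]
    free_bounds = [bounds[i] for i in free]

    def profiled(v: float) -> float:
        if not free:
            x = x_mle.copy()
            x[index] = v
            return objective(x)
        def fun(theta):
            x = x_mle.copy()
            x[free] = theta
            x[index] = v
            return objective(x)
        res = optimize.minimize(fun, x_mle[free], method="L-BFGS-B",
                                bounds=free_bounds,
                                options={"maxiter": 500, "ftol": 1e-10})
        return float(res.fun)

    target = m2ll_min + crit
    if step is None:
        width = hi - lo
        step = 0.02 * width if np.isfinite(width) else max(0.1, 0.1 * abs(x_mle[index]))

    def search(direction: int) -> float:
        v_prev, f_prev = float(x_mle[index]), m2ll_min
        s = step
        for _ in range(max_expand):
            v = v_prev + direction * s
            clipped = False
            if v <= lo:
                v, clipped = lo, True
            if v >= hi:
                v, clipped = hi, True
            f = profiled(v)
            if f >= target:
                try:
                    return float(optimize.brentq(
                        lambda u: profiled(u) - target, min(v_prev, v), max(v_prev, v),
                        xtol=1e-5))
                except ValueError:
                    return v
            if clipped:
                return v  # boundary-limited endpoint
            v_prev, f_prev = v, f
            s *= 1.6
        return v_prev

    return search(-1), search(+1)


def _looks_nested(full: FitResult, reduced: FitResult) -> bool:
    """Heuristic nesting check on parameter-name sets.

    Some constrained models rename parameters on reparameterization (a
    shared share ``h`` replacing ``h_m``/``h_f``); such known aliases are
    expanded before the subset test.
    """
    aliases = {"h": {"h_m", "h_f"}, "g": {"g_m", "g_f"}, "u": {"u_m", "u_f"}}
    red = set()
    for n in reduced.param_names:
        red |= aliases.get(n, {n})
    fullset = set()
    for n in full.param_names:
        fullset |= aliases.get(n, {n})
    return red <= fullset or reduced.n_params == 0


def lrt(full: FitResult, reduced: FitResult, check_nesting: bool = True):
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns ``(delta_chi2, delta_df, p)`` with the naive χ² reference
    distribution (no boundary mixture correction).  Optimizer noise can
    make the difference marginally negative; it is floored at 0.
    """
    from scipy.stats import chi2

    ddf = full.n_params - reduced.n_params
    if ddf < 0:
        raise ValueError("reduced model has more parameters than full model")
    if check_nesting and full.param_names and reduced.param_names:
        ft = getattr(full.spec, "trait", None)
        rt = getattr(reduced.spec, "trait", None)
        if ft is not None and rt is not None and ft != rt:
            raise ValueError("models fitted to different traits are not nested")
        same_family = (
            getattr(full.spec, "family", None) is not None
            and getattr(full.spec, "family", None) == getattr(reduced.spec, "family", None)
            and getattr(full.spec, "trait", None) == getattr(reduced.spec, "trait", None)
        )
        if not (_looks_nested(full, reduced) or same_family
                or getattr(full.spec, "family", None) == "saturated"):
            raise ValueError("models do not look nested (parameter sets not subset-related)")
    dchi = max(0.0, reduced.minus2ll - full.minus2ll)
    if ddf == 0:
        return dchi, 0, (1.0 if dchi < 1e-6 else 0.0)
    return dchi, ddf, float(chi2.sf(dchi, df=ddf))
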