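"""Censored Weibull accelerated-failure-time model on gastrointestinal plastic load.

The event axis is not time but the amount of plastic in the gut: an animal
that died of ingestion (KD/PD) is a failure observed exactly at its load,
and an animal that died of something else (KND) is right-censored at its
load — its lethal threshold is only known to exceed what it carried.

With load ``p``, covariates ``x`` and parameters ``(beta, sigma)`` the model
is the standard Weibull AFT: the survival function is

    S(p | x) = exp(-(p * exp(-x @ beta))**(1 / sigma))

so the probability of death by load ``p`` (the cumulative incidence) is
``1 - S(p | x)``.  Larger ``x @ beta`` means a larger lethal load.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, data only in :meth:`WeibullAFT.fit`, fitted attributes with a
trailing underscore.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import LoadMetric, PlasticCategory, Taxon

__all__ = [
    "AFTModelSpec",
    "LoadObservation",
    "AFTFit",
    "WeibullAFT",
    "negative_log_likelihood",
    "fit_aft",
    "model_aic",
    "select_best_model",
    "bootstrap_fits",
]


@dataclass(frozen=True)
class AFTModelSpec:
    """Which taxon / plastic-category subset / load metric / covariates to model.

    ``categories=None`` means TOTAL: all categories pooled.
    Covariate names are drawn from {"individual_length", "species_mean_length"}.
    """

    taxon: Taxon
    categories: frozenset[PlasticCategory] | None = None
    metric: LoadMetric = LoadMetric.PIECE_COUNT
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")

    @property
    def label(self) -> str:
        cats = "total" if self.categories is None else "+".join(
            sorted(c.value for c in self.categories)
        )
        cov = ("|" + ",".join(self.covariates)) if self.covariates else ""
        return f"{self.taxon.value}:{cats}:{self.metric.value}{cov}"


@dataclass(frozen=True)
class LoadObservation:
    """One model-ready observation: load, event indicator and covariates."""

    p: float
    event: int
    x: tuple[float, ...] = ()
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.p < 0:
            raise ValueError("load must be nonnegative")
        if self.event == 1 and self.p <= 0:
            raise ValueError("an event requires a strictly positive load")


@dataclass
class AFTFit:
    """Result of one maximum-likelihood fit.

    ``beta`` is aligned as (intercept, *covariates).  ``covariate_profile``
    is the event-weighted mean covariate vector of the fitted data, the
    default profile at which thresholds and curves are evaluated.
    """

    beta: np.ndarray
    sigma: float
    loglik: float
    aic: float
    n_events: int
    n_censored: int
    converged: bool
    spec: AFTModelSpec | None = None
    covariate_se: np.ndarray | None = None
    covariate_p: np.ndarray | None = None
    covariate_profile: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # sigma always counted

    def to_json(self) -> str:
        d = {
            "beta": list(map(float, self.beta)),
            "sigma": float(self.sigma),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_events": self.n_events,
            "n_censored": self.n_censored,
            "converged": self.converged,
            "covariate_se": None
            if self.covariate_se is None
            else list(map(float, self.covariate_se)),
            "covariate_p": None
            if self.covariate_p is None
            else list(map(float, self.covariate_p)),
            "covariate_profile": list(map(float, self.covariate_profile)),
            "spec": None if self.spec is None else self.spec.label,
        }
        return json.dumps(d, sort_keys=True)


def _as_arrays(
    observations: Sequence[LoadObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.asarray([o.p for o in observations], dtype=float)
    event = np.asarray([o.event for o in observations], dtype=bool)
    n_cov = len(observations[0].x) if observations else 0
    X = np.asarray([o.x for o in observations], dtype=float).reshape(len(observations), n_cov)
    return p, event, X


def negative_log_likelihood(
    beta: ArrayLike,
    log_sigma: float,
    observations: Sequence[LoadObservation],
) -> float:
    """Negative log-likelihood of the right-censored Weibull AFT.

    With z = p * exp(-x @ beta) and k = 1/sigma, an event contributes
    -log f(p) where f(p) = (k/p) z^k exp(-z^k); a censored observation
    contributes -log S(p) = z^k.  A zero-load censored observation
    contributes exactly 0 (S(0) = 1).
    """
    if len(observations) == 0:
        raise ValueError("observations must be nonempty")
    p, event, X = _as_arrays(observations)
    if np.any(event & (p <= 0)):
        raise ValueError("events must have strictly positive loads")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    theta = np.concatenate([beta, [float(log_sigma)]])
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameters must be finite")
    return float(_nll_grad(theta, p, event, X)[0])


def _nll_grad(
    theta: np.ndarray, p: np.ndarray, event: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray]:
    """Vectorized NLL and its analytic gradient w.r.t. (beta, log sigma)."""
    beta, s = theta[:-1], theta[-1]
    pos = p > 0
    if np.any(event & ~pos):
        raise ValueError("events must have strictly positive loads")
    with np.errstate(over="ignore", invalid="ignore"):
        k = np.exp(-s)  # shape = 1/sigma
        xb = X @ beta[1:] + beta[0] if len(beta) > 1 else np.full(p.shape, beta[0])
        logz = np.where(pos, np.log(np.where(pos, p, 1.0)) - xb, 0.0)
        u = np.where(pos, np.exp(k * logz), 0.0)  # z^k, 0 at p == 0

        # NLL = sum(u) + sum_events(s - k*logz + log p)
        nll = u.sum() + np.sum(s - k * logz[event] + np.log(p[event]))

        # d/dbeta_j: k * sum_i x_ij (event_i - u_i)
        resid = event.astype(float) - u
        Xfull = np.column_stack([np.ones_like(p), X])
        g_beta = k * (Xfull.T @ resid)
        # d/ds: sum_events(1 + k*logz) - k * sum(u * logz)
        g_s = np.sum(1.0 + k * logz[event]) - k * np.sum(u * logz)
        grad = np.concatenate([g_beta, [g_s]])
    if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
        return 1e300, np.zeros_like(grad)
    return float(nll), grad


class WeibullAFT(BaseEstimator):
    """Right-censored Weibull accelerated-failure-time regression on plastic load.

    Parameters
    ----------
    fix_sigma : float or None
        If given, the Weibull scale parameter sigma is held fixed at this
        value (``fix_sigma=1`` is the censored-exponential submodel) and only
        the regression coefficients are estimated.
    n_starts : int
        Number of jittered restarts tried before declaring non-convergence.
    tol : float
        Gradient-norm tolerance for the convergence flag.
    max_iter : int
        Iteration cap per optimizer start.

    Attributes
    ----------
    intercept_ : float
        beta_0, the log load scale at x = 0.
    coef_ : ndarray of shape (n_covariates,)
        Covariate coefficients beta_1..beta_n.
    sigma_ : float
        Weibull AFT scale (shape parameter k = 1/sigma_).
    log_likelihood_, aic_ : float
    n_events_, n_censored_ : int
    converged_ : bool
    se_ : ndarray of shape (1 + n_covariates,)
        Standard errors of (intercept, *coef) from the inverse observed
        information.
    p_values_ : ndarray
        Two-sided Wald p-values aligned with ``se_``.

    Examples
    --------
    >>> import numpy as np
    >>> aft = WeibullAFT(fix_sigma=1.0)
    >>> loads, events = np.array([2., 4., 6.]), np.array([1, 1, 0])
    >>> aft.fit(np.empty((3, 0)), np.column_stack([loads, events]))
    WeibullAFT(fix_sigma=1.0)
    >>> float(np.exp(aft.intercept_))  # censored-exponential MLE: (2+4+6)/2
    6.0
    """

    def __init__(
        self,
        fix_sigma: float | None = None,
        n_starts: int = 3,
        tol: float = 1e-6,
        max_iter: int = 500,
    ) -> None:
        self.fix_sigma = fix_sigma
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter

    # -- scikit-learn plumbing -------------------------------------------------
    def _validate_y(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of [load, event]")
        p, event = y[:, 0], y[:, 1].astype(bool)
        if np.any(p < 0):
            raise ValueError("loads must be nonnegative")
        if np.any(event & (p <= 0)):
            raise ValueError("events must have strictly positive loads")
        return p, event

    def fit(self, X: ArrayLike, y: ArrayLike) -> "WeibullAFT":
        """Fit by maximum likelihood over (beta, log sigma).

        ``X`` is the (n, n_covariates) covariate matrix (zero columns allowed);
        ``y`` is an (n, 2) array whose columns are load and event indicator.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        p, event = self._validate_y(y)
        if X.shape[0] != p.shape[0]:
            raise ValueError("X and y have mismatched lengths")
        n_events = int(event.sum())
        if n_events < 1:
            raise ValueError("at least one event is required")
        if X.shape[1] and np.linalg.matrix_rank(np.column_stack([np.ones(len(p)), X])) < X.shape[1] + 1:
            raise ValueError("covariate matrix (with intercept) is rank deficient")

        fixed = self.fix_sigma is not None
        if fixed and self.fix_sigma <= 0:
            raise ValueError("fix_sigma must be positive")
        n_beta = X.shape[1] + 1
        beta0_init = float(np.log(np.mean(p[event])))
        init = np.zeros(n_beta + 1)
        init[0] = beta0_init
        if fixed:
            init[-1] = np.log(self.fix_sigma)

        if fixed:
            s_fixed = float(np.log(self.fix_sigma))

            def fun(b: np.ndarray) -> tuple[float, np.ndarray]:
                nll, g = _nll_grad(np.concatenate([b, [s_fixed]]), p, event, X)
                return nll, g[:-1]

            free_init = init[:-1]
        else:

            def fun(th: np.ndarray) -> tuple[float, np.ndarray]:
                return _nll_grad(th, p, event, X)

            free_init = init

        best = None
        rng = np.random.default_rng(0)  # deterministic jitter for restarts
        for start in range(max(1, self.n_starts)):
            x0 = free_init if start == 0 else free_init + rng.normal(0, 0.3, free_init.shape)
            res = optimize.minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "gtol": self.tol * 1e-2},
            )
            if best is None or res.fun < best.fun:
                best = res
            if np.linalg.norm(res.jac) < self.tol:
                best = res if res.fun <= best.fun else best
                break

        theta = np.concatenate([best.x, [s_fixed]]) if fixed else best.x
        nll, grad = _nll_grad(theta, p, event, X)
        free_grad = grad[:-1] if fixed else grad
        self.converged_ = bool(np.linalg.norm(free_grad) < max(self.tol, 1e-4 * (1 + abs(nll))))

        self.intercept_ = float(theta[0])
        self.coef_ = np.asarray(theta[1:-1], dtype=float)
        self.sigma_ = float(np.exp(theta[-1]))
        self.log_likelihood_ = -float(nll)
        self.n_events_ = n_events
        self.n_censored_ = int(len(p) - n_events)
        k_params = n_beta + 1  # sigma counted even when held fixed
        self.aic_ = 2.0 * k_params - 2.0 * self.log_likelihood_

        self._set_se(theta, p, event, X, fixed)
        # event-weighted mean covariate profile: default evaluation point for
        # thresholds of multivariate models
        self.covariate_profile_ = (
            X[event].mean(axis=0) if X.shape[1] else np.empty(0)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _set_se(
        self, theta: np.ndarray, p: np.ndarray, event: np.ndarray,
        X: np.ndarray, fixed: bool,
    ) -> None:
        """SEs for beta from the observed information (numerical Hessian of NLL)."""
        n_free = len(theta) - (1 if fixed else 0)
        free = theta[:n_free]

        def g(th_free: np.ndarray) -> np.ndarray:
            th = np.concatenate([th_free, theta[n_free:]])
            return _nll_grad(th, p, event, X)[1][:n_free]

        h = 1e-5
        H = np.empty((n_free, n_free))
        for j in range(n_free):
            e = np.zeros(n_free)
            e[j] = h
            H[:, j] = (g(free + e) - g(free - e)) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            se = np.sqrt(np.where(var > 0, var, np.nan))
        except np.linalg.LinAlgError:
            se = np.full(n_free, np.nan)
        n_beta = len(theta) - 1
        se_beta = se[:n_beta]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = theta[:n_beta] / se_beta
            pvals = 2 * stats.norm.sf(np.abs(z))
        self.se_ = se_beta
        self.p_values_ = pvals

    # -- prediction ------------------------------------------------------------
    def _linpred(self, X: ArrayLike | None) -> np.ndarray:
        check_is_fitted(self, "sigma_")
        if self.n_features_in_ == 0:
            return np.asarray(self.intercept_)
        if X is None:
            X = self.covariate_profile_
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("covariate length mismatch")
        return self.intercept_ + X @ self.coef_

    def predict_mortality(self, load: ArrayLike, X: ArrayLike | None = None) -> np.ndarray:
        """Cumulative incidence 1 - S(load | x): probability of death by ``load``."""
        load = np.asarray(load, dtype=float)
        if np.any(load < 0):
            raise ValueError("load must be nonnegative")
        eta = self._linpred(X)
        z = load * np.exp(-eta)
        pos = z > 0
        zk = np.where(pos, np.exp(np.log(np.where(pos, z, 1.0)) / self.sigma_), 0.0)
        return 1.0 - np.exp(-zk)

    def predict_threshold(self, q: float, X: ArrayLike | None = None) -> np.ndarray:
        """Load at which the cumulative incidence reaches ``q`` (e.g. LD50 at q=0.5)."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        eta = self._linpred(X)
        return np.exp(eta) * (-np.log1p(-q)) ** self.sigma_


# ---------------------------------------------------------------------------
# Functional wrappers over the estimator
# ---------------------------------------------------------------------------


def _obs_to_xy(observations: Sequence[LoadObservation]) -> tuple[np.ndarray, np.ndarray]:
    p, event, X = _as_arrays(observations)
    return X, np.column_stack([p, event.astype(float)])


def fit_aft(
    observations: Sequence[LoadObservation],
    spec: AFTModelSpec | None = None,
    options: dict | None = None,
) -> AFTFit:
    """Maximum-likelihood fit of the censored Weibull AFT for one model spec."""
    options = dict(options or {})
    est = WeibullAFT(
        fix_sigma=options.get("fix_sigma"),
        n_starts=options.get("n_starts", 3),
        tol=options.get("tol", 1e-6),
        max_iter=options.get("max_iter", 500),
    )
    X, y = _obs_to_xy(observations)
    est.fit(X, y)
    beta = np.concatenate([[est.intercept_], est.coef_])
    return AFTFit(
        beta=beta,
        sigma=est.sigma_,
        loglik=est.log_likelihood_,
        aic=est.aic_,
        n_events=est.n_events_,
        n_censored=est.n_censored_,
        converged=est.converged_,
        spec=spec,
        covariate_se=est.se_,
        covariate_p=est.p_values_,
        covariate_profile=est.covariate_profile_,
    )


def model_aic(fit: AFTFit) -> float:
    """Akaike information criterion, 2k - 2 loglik with k = len(beta) + 1."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def select_best_model(fits: Sequence[AFTFit], selection_config: dict | None = None) -> AFTFit:
    """Lowest-AIC converged fit; covariate models must earn their keep.

    A model with covariates is eligible only if every added covariate has a
    finite standard error and Wald p below ``alpha`` (default 0.05).  Ties on
    AIC break toward fewer parameters.
    """
    cfg = dict(selection_config or {})
    alpha = cfg.get("alpha", 0.05)
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")

    def eligible(f: AFTFit) -> bool:
        if len(f.beta) == 1:
            return True
        if f.covariate_se is None or f.covariate_p is None:
            return False
        se, pv = f.covariate_se[1:], f.covariate_p[1:]
        return bool(np.all(np.isfinite(se)) and np.all(pv < alpha))

    pool = [f for f in converged if eligible(f)]
    if not pool:  # fall back to converged intercept-only fits
        pool = [f for f in converged if len(f.beta) == 1]
    if not pool:
        raise ValueError("no eligible fits to select from")
    return min(pool, key=lambda f: (f.aic, f.n_params))


def bootstrap_fits(
    observations: Sequence[LoadObservation],
    spec: AFTModelSpec | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    options: dict | None = None,
) -> list[AFTFit]:
    """Case-resampling bootstrap: refit on ``n_boot`` resamples of individuals.

    Resamples with zero events, or fits that fail to converge, are dropped
    (a warning is raised if more than 20% are lost).  Reproducible from seed.
    """
    n = len(observations)
    rng = np.random.default_rng(seed)
    fits: list[AFTFit] = []
    n_dropped = 0
    obs_arr = np.asarray(observations, dtype=object)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = list(obs_arr[idx])
        if not any(o.event for o in sample):
            n_dropped += 1
            continue
        try:
            f = fit_aft(sample, spec=spec, options=options)
        except (ValueError, np.linalg.LinAlgError):
            n_dropped += 1
            continue
        if not f.converged:
            n_dropped += 1
            continue
        fits.append(f)
    if n_boot and n_dropped > 0.2 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap resamples dropped "
            "(non-convergence or zero events)",
            RuntimeWarning,
        )
    return fits
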