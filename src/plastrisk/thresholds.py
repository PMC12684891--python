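"""Mortality-probability curves and lethal-load thresholds (LD50/LD90 analogues).

Inverting the Weibull AFT cumulative incidence 1 - exp(-(p e^{-x beta})^{1/sigma})
at probability q gives the load

    p_q = exp(x @ beta) * (-ln(1 - q))**sigma

so p90 / p50 = (ln 10 / ln 2)**sigma exactly.  Confidence intervals come from
the percentile method over case-resampling bootstrap refits.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from numpy.typing import ArrayLike

from .aft import AFTFit
from .core import LoadMetric

__all__ = [
    "ThresholdEstimate",
    "MortalityCurve",
    "mortality_probability",
    "invert_threshold",
    "threshold_with_ci",
    "absolute_threshold",
    "mortality_curve",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Load at mortality probability q with a bootstrap percentile CI."""

    q: float
    point: float
    ci_low: float
    ci_high: float
    n_boot_used: int
    metric: LoadMetric | None = None
    covariate_profile: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.point <= 0:
            raise ValueError("threshold must be positive")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


@dataclass(frozen=True)
class MortalityCurve:
    """Pointwise cumulative incidence with a bootstrap envelope."""

    load: np.ndarray
    probability: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.probability) < -1e-12):
            raise ValueError("probability must be nondecreasing")


def _eta(fit: AFTFit, x: ArrayLike | None) -> float:
    n_cov = len(fit.beta) - 1
    if n_cov == 0:
        return float(fit.beta[0])
    xv = np.asarray(
        fit.covariate_profile if x is None else x, dtype=float
    ).ravel()
    if xv.shape[0] != n_cov:
        raise ValueError("covariate length mismatch")
    return float(fit.beta[0] + fit.beta[1:] @ xv)


def mortality_probability(fit: AFTFit, p: ArrayLike, x: ArrayLike | None = None) -> np.ndarray:
    """Cumulative incidence of death at load ``p`` under a fitted model."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("load must be nonnegative")
    z = p * np.exp(-_eta(fit, x))
    pos = z > 0
    zk = np.where(pos, np.exp(np.log(np.where(pos, z, 1.0)) / fit.sigma), 0.0)
    return 1.0 - np.exp(-zk)


def invert_threshold(fit: AFTFit, q: float, x: ArrayLike | None = None) -> float:
    """Load at which the cumulative incidence reaches ``q``."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(np.exp(_eta(fit, x)) * (-np.log1p(-q)) ** fit.sigma)


def threshold_with_ci(
    full_fit: AFTFit,
    boot_fits: list[AFTFit],
    q: float,
    x: ArrayLike | None = None,
) -> ThresholdEstimate:
    """Point threshold from the full fit; 2.5/97.5 percentile CI from bootstrap refits."""
    if not boot_fits:
        raise ValueError("at least one bootstrap fit is required")
    if x is None:
        x = full_fit.covariate_profile
    point = invert_threshold(full_fit, q, x)
    boot_vals = np.array([invert_threshold(f, q, x) for f in boot_fits])
    lo, hi = np.percentile(boot_vals, [2.5, 97.5])
    return ThresholdEstimate(
        q=q,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot_used=len(boot_fits),
        metric=None if full_fit.spec is None else full_fit.spec.metric,
        covariate_profile=tuple(np.asarray(x, dtype=float).ravel()),
    )


def absolute_threshold(per_length_threshold: float, body_length_cm: float) -> float:
    """Scale a per-cm-body-length threshold to an absolute amount for one animal.

    Product rounded half-up to two decimals for reporting (cm^3 for volume
    metrics, cm for the fishing-debris length metric).
    """
    if per_length_threshold <= 0 or body_length_cm <= 0:
        raise ValueError("inputs must be positive")
    raw = Decimal(repr(per_length_threshold)) * Decimal(repr(body_length_cm))
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mortality_curve(
    full_fit: AFTFit,
    boot_fits: list[AFTFit],
    load_grid: ArrayLike,
    x: ArrayLike | None = None,
) -> MortalityCurve:
    """Cumulative incidence over a load grid with a pointwise bootstrap envelope."""
    grid = np.asarray(load_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("load grid must be nonempty")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ValueError("load grid must be strictly increasing")
    if np.any(grid < 0):
        raise ValueError("load grid must be nonnegative")
    if x is None:
        x = full_fit.covariate_profile
    prob = mortality_probability(full_fit, grid, x)
    if boot_fits:
        boot = np.vstack([mortality_probability(f, grid, x) for f in boot_fits])
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    else:
        lo = hi = prob.copy()
    lo = np.minimum(lo, prob)
    hi = np.maximum(hi, prob)
    return MortalityCurve(load=grid, probability=prob, band_low=lo, band_high=hi)
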