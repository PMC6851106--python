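"""Median-effect dose-response model.

The median-effect equation relates the affected fraction fa of a system to
dose D through the median dose Dm (the dose giving fa = 0.5) and the shape
parameter m::

    fa / fu = (D / Dm)^m,        fu = 1 - fa

which linearizes exactly as

    log10[fa / (1 - fa)] = m * log10(D) - m * log10(Dm)

so ordinary least squares on (log10 D, log10 fa/(1-fa)) recovers m as the
slope and Dm as 10^(-intercept/slope).  Any logarithm base gives the same
(Dm, m); base 10 is used so that plots match the conventional
median-effect plot.

In the gastroprotection setting the affected fraction is the fractional
reduction of mean gastric lesion area relative to the ethanol-only
control group, computed at the group level (one dose-effect curve per
treatment); per-animal areas are retained for bootstrap resampling.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .study import AffectedFraction, DoseResponseStudy

__all__ = [
    "MedianEffectModel",
    "compute_fa",
    "fit_median_effect",
    "predict_fa",
    "dose_for_fa",
]

DEFAULT_CLAMP_EPS = 0.01


def compute_fa(
    study: DoseResponseStudy, clamp_eps: float = DEFAULT_CLAMP_EPS
) -> list[AffectedFraction]:
    """Affected fractions per dose level from group mean lesion areas.

    fa(D) = 1 - mean treated area(D) / mean control area, clamped into
    [clamp_eps, 1 - clamp_eps] because fa in {0, 1} has no log-odds.
    Duplicate doses are pooled by mean area; the dose-0 control group only
    defines the denominator.
    """
    if not 0.0 < clamp_eps <= 0.05:
        raise ValueError("clamp_eps must lie in (0, 0.05]")
    if not study.control_mask.any():
        raise ValueError(f"missing control: study {study.treatment_id!r} has no dose-0 records")
    control_mean = float(study.control_areas.mean())
    if control_mean <= 0.0:
        raise ValueError(f"degenerate control: control mean area is 0 in {study.treatment_id!r}")
    out: list[AffectedFraction] = []
    for dose in study.dose_levels:
        group = study.group_areas(dose)
        raw = 1.0 - float(group.mean()) / control_mean
        fa = float(np.clip(raw, clamp_eps, 1.0 - clamp_eps))
        if fa != raw:
            warnings.warn(
                f"fa at dose {dose:g} mg/kg clamped from {raw:.4g} to {fa:.4g}",
                stacklevel=2,
            )
        out.append(AffectedFraction(dose=float(dose), fa=fa, n_animals=len(group), clamped=fa != raw))
    return out


class MedianEffectModel(RegressorMixin, BaseEstimator):
    """Median-effect regression estimator.

    ``fit`` takes doses (mg/kg, strictly positive) and affected fractions
    in (0, 1) and performs the exact log-linearization above.

    Parameters
    ----------
    min_points : int
        Minimum number of distinct positive doses required (the line has
        two parameters, so at least three points are needed for a
        meaningful r^2).

    Attributes
    ----------
    m_ : float
        Shape parameter (slope of the median-effect plot).  m = 1 marks a
        hyperbolic, m > 1 a sigmoidal and m < 1 a flat-sigmoidal curve.
    dm_ : float
        Median dose, 10^(-intercept/slope), mg/kg.
    slope_, intercept_ : float
        Raw regression coefficients (slope_ == m_).
    r_squared_ : float
        Coefficient of determination of the linearized fit.
    n_points_ : int
        Number of dose levels used.
    increasing_ : bool
        False flags a non-positive slope (dose-response not monotone
        increasing); the fit is still returned.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).reshape(-1)
        fa = np.asarray(y, dtype=float).reshape(-1)
        if doses.shape != fa.shape:
            raise ValueError("doses and fa must have the same length")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any((fa <= 0) | (fa >= 1)):
            raise ValueError("fa values must lie strictly inside (0, 1)")
        if len(np.unique(doses)) < self.min_points:
            raise ValueError(f"need at least {self.min_points} distinct positive doses")
        x = np.log10(doses)
        yy = np.log10(fa / (1.0 - fa))
        res = stats.linregress(x, yy)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.m_ = self.slope_
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = int(len(doses))
        self.increasing_ = self.slope_ > 0
        if not self.increasing_:
            warnings.warn(
                "median-effect slope is non-positive; dose-response is not "
                "monotone increasing",
                stacklevel=2,
            )
        self.dm_ = float(10.0 ** (-self.intercept_ / self.slope_))
        return self

    def predict(self, X) -> np.ndarray:
        """Affected fraction at dose: fa = (D/Dm)^m / (1 + (D/Dm)^m)."""
        check_is_fitted(self, "dm_")
        doses = np.asarray(X, dtype=float).reshape(-1)
        if np.any(doses <= 0):
            raise ValueError("dose must be positive")
        ratio = (doses / self.dm_) ** self.m_
        return ratio / (1.0 + ratio)

    def dose_for(self, fa) -> np.ndarray | float:
        """Dose producing affected fraction fa: Dx = Dm * (fa/(1-fa))^(1/m)."""
        check_is_fitted(self, "dm_")
        fa_arr = np.asarray(fa, dtype=float)
        if np.any((fa_arr <= 0) | (fa_arr >= 1)):
            raise ValueError("fa must lie strictly inside (0, 1)")
        dx = self.dm_ * (fa_arr / (1.0 - fa_arr)) ** (1.0 / self.m_)
        return float(dx) if np.isscalar(fa) or fa_arr.ndim == 0 else dx

    @classmethod
    def from_params(cls, dm: float, m: float) -> "MedianEffectModel":
        """Build a fitted model directly from (Dm, m), e.g. published values."""
        if dm <= 0 or m <= 0:
            raise ValueError("Dm and m must be positive")
        model = cls()
        model.m_ = float(m)
        model.slope_ = float(m)
        model.dm_ = float(dm)
        model.intercept_ = -float(m) * np.log10(dm)
        model.r_squared_ = float("nan")
        model.n_points_ = 0
        model.increasing_ = True
        return model

    def summary(self) -> dict:
        check_is_fitted(self, "dm_")
        return {
            "Dm": self.dm_,
            "m": self.m_,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "n_points": self.n_points_,
            "increasing": self.increasing_,
        }


def fit_median_effect(points: Sequence[AffectedFraction]) -> MedianEffectModel:
    """Fit the median-effect line to per-dose affected fractions."""
    points = list(points)
    if len(points) < 3:
        raise ValueError("need at least 3 dose levels for a median-effect fit")
    doses = np.array([p.dose for p in points])
    fa = np.array([p.fa for p in points])
    return MedianEffectModel().fit(doses, fa)


def fit_study(study: DoseResponseStudy, clamp_eps: float = DEFAULT_CLAMP_EPS) -> MedianEffectModel:
    """Convenience: compute affected fractions and fit in one call."""
    return fit_median_effect(compute_fa(study, clamp_eps=clamp_eps))


def predict_fa(fit: MedianEffectModel, dose) -> float | np.ndarray:
    """fa at ``dose`` under ``fit``; strictly increasing in dose."""
    result = fit.predict(np.atleast_1d(dose))
    return float(result[0]) if np.isscalar(dose) else result


def dose_for_fa(fit: MedianEffectModel, fa) -> float | np.ndarray:
    """Inverse of :func:`predict_fa`."""
    return fit.dose_for(fa)
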