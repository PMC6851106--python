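"""Constant-ratio combination analysis: design, fitting, combination index.

The combination index (CI) referenced to Loewe additivity for a two-drug
combination at affected fraction fa is

    CI = D1/Dx1 + D2/Dx2

where (D1, D2) is the split of the combination's total dose reaching fa
(from the combination's own median-effect fit, divided by the fixed dose
ratio) and Dx_i = Dm_i * (fa/(1-fa))^(1/m_i) is the dose of drug i alone
reaching the same fa.  CI < 1 marks synergism (superadditivity), CI = 1
additivity, CI > 1 antagonism (subadditivity).

The "1:1" design is equipotent: component doses stand in the ratio
Dm1:Dm2, so each drug contributes equal potency and the additive
expectation for the combination's total median dose is (Dm1 + Dm2)/2.
At fa = 0.5 the CI therefore reduces to Dm_comb / ((Dm1 + Dm2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .median_effect import MedianEffectModel, compute_fa, fit_median_effect
from .study import CombinationDesign, CombinationStudy

__all__ = [
    "DEFAULT_CI_BANDS",
    "CHOU_CI_BANDS",
    "CIResult",
    "build_design",
    "fit_combination",
    "theoretical_dm",
    "combination_index",
    "ci_curve",
    "classify_ci",
]

#: Default additivity band (low, high): CI < low -> synergism,
#: low <= CI <= high -> additive, CI > high -> antagonism.  The width
#: acknowledges that CI estimated from in-vivo dose-response fits carries
#: substantial propagation error; a strict band is available as
#: CHOU_CI_BANDS.
DEFAULT_CI_BANDS: tuple[float, float] = (0.90, 1.30)
CHOU_CI_BANDS: tuple[float, float] = (0.90, 1.10)

CANONICAL_FA = (0.1, 0.5, 0.9)


def build_design(
    dm1: float,
    dm2: float,
    levels: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    drug1_id: str = "drug1",
    drug2_id: str = "drug2",
) -> CombinationDesign:
    """Equipotent constant-ratio dose ladder: level k doses (k*Dm1, k*Dm2)."""
    return CombinationDesign(drug1_id, drug2_id, float(dm1), float(dm2), tuple(float(k) for k in levels))


def fit_combination(study: CombinationStudy, clamp_eps: float = 0.01) -> MedianEffectModel:
    """Median-effect fit of the combination on TOTAL dose D1 + D2."""
    points = compute_fa(study.to_total_dose_study(), clamp_eps=clamp_eps)
    return fit_median_effect(points)


def theoretical_dm(dm1: float, dm2: float) -> float:
    """Loewe-additive expectation for the equipotent combination's total Dm.

    Solving D1/Dm1 + D2/Dm2 = 1 with D1:D2 = Dm1:Dm2 gives a total dose of
    (Dm1 + Dm2)/2.
    """
    if dm1 <= 0 or dm2 <= 0:
        raise ValueError("median doses must be positive")
    return (dm1 + dm2) / 2.0


def _dose_split(ratio: tuple[float, float]) -> tuple[float, float]:
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 <= 0 or r2 <= 0:
        raise ValueError("dose ratio components must be positive")
    total = r1 + r2
    return r1 / total, r2 / total


def combination_index(
    fa: float,
    comb_fit: MedianEffectModel,
    fit1: MedianEffectModel,
    fit2: MedianEffectModel,
    ratio: tuple[float, float] | None = None,
) -> float:
    """CI at one affected fraction for a constant-ratio combination.

    ``ratio`` is the fixed (D1, D2) dose ratio; by default the equipotent
    (Dm1, Dm2) ratio of the single-drug fits.
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly inside (0, 1)")
    if ratio is None:
        ratio = (fit1.dm_, fit2.dm_)
    share1, share2 = _dose_split(ratio)
    total = comb_fit.dose_for(fa)
    d1, d2 = total * share1, total * share2
    return float(d1 / fit1.dose_for(fa) + d2 / fit2.dose_for(fa))


def classify_ci(ci: float, bands: tuple[float, float] = DEFAULT_CI_BANDS) -> str:
    """Label a CI value as synergism / additive / antagonism."""
    low, high = bands
    if not (0.0 < low <= 1.0 <= high):
        raise ValueError("bands must satisfy 0 < low <= 1 <= high")
    if ci < low:
        return "synergism"
    if ci > high:
        return "antagonism"
    return "additive"


@dataclass
class CIResult:
    """Combination-index curve over an fa grid plus canonical points."""

    fa_grid: np.ndarray
    ci_values: np.ndarray
    ci_at: dict[float, float]
    labels: list[str]
    bands: tuple[float, float] = DEFAULT_CI_BANDS

    def label_at(self, fa: float) -> str:
        return classify_ci(self.ci_at[fa], self.bands)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fa": self.fa_grid, "ci": self.ci_values, "label": self.labels})


def ci_curve(
    comb_fit: MedianEffectModel,
    fit1: MedianEffectModel,
    fit2: MedianEffectModel,
    ratio: tuple[float, float] | None = None,
    fa_grid: Sequence[float] | None = None,
    bands: tuple[float, float] = DEFAULT_CI_BANDS,
) -> CIResult:
    """Evaluate the CI on a grid of affected fractions.

    The canonical fa levels {0.1, 0.5, 0.9} are always evaluated and
    returned in ``ci_at`` regardless of the grid.
    """
    if fa_grid is None:
        fa_grid = np.linspace(0.05, 0.95, 91)
    fa_grid = np.asarray(fa_grid, dtype=float)
    if fa_grid.size == 0:
        raise ValueError("fa grid is empty")
    if np.any((fa_grid <= 0) | (fa_grid >= 1)):
        raise ValueError("fa grid must lie strictly inside (0, 1)")
    ci_values = np.array(
        [combination_index(f, comb_fit, fit1, fit2, ratio) for f in fa_grid]
    )
    ci_at = {f: combination_index(f, comb_fit, fit1, fit2, ratio) for f in CANONICAL_FA}
    labels = [classify_ci(c, bands) for c in ci_values]
    return CIResult(fa_grid=fa_grid, ci_values=ci_values, ci_at=ci_at, labels=labels, bands=bands)


def combination_report(
    comb_fits: dict[tuple[str, str], MedianEffectModel],
    single_fits: dict[str, MedianEffectModel],
    bands: tuple[float, float] = DEFAULT_CI_BANDS,
) -> pd.DataFrame:
    """Summary table: Dm Exp, Dm Theo, m and CI at fa = 0.1/0.5/0.9 per pair."""
    rows = []
    for (d1, d2), cfit in comb_fits.items():
        f1, f2 = single_fits[d1], single_fits[d2]
        result = ci_curve(cfit, f1, f2, bands=bands)
        row = {
            "drug1": d1,
            "drug2": d2,
            "dm_exp": cfit.dm_,
            "dm_theo": theoretical_dm(f1.dm_, f2.dm_),
            "m": cfit.m_,
        }
        for fa in CANONICAL_FA:
            key = f"ci_{int(round(fa * 100))}"
            row[key] = result.ci_at[fa]
            row[key + "_label"] = classify_ci(result.ci_at[fa], bands)
        rows.append(row)
    return pd.DataFrame(rows)
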