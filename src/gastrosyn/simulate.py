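"""Synthetic-data generators with known ground truth.

Every generator is a measurable forward model of the equations the rest
of the package fits, so noiseless round-trips are exact to numerical
tolerance and all randomness flows from a single seed.

* Single-drug studies: per-animal lesion areas whose group means follow
  the median-effect curve, with multiplicative lognormal noise (areas are
  positive and right-skewed; a truncated-normal alternative is available
  behind a flag).
* Combination studies: constant-ratio (equipotent) dose ladders whose
  affected fractions solve the combination-index equation for a
  prescribed constant CI (1 = Loewe additive; > 1 antagonistic; < 1
  synergistic).  An fa-dependent CI profile can be injected via a
  callable.
* Rheology: power-law frequency sweeps A * omega^n for suspension and
  mucin, with the mixture equal to their sum plus an injected synergy
  offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .study import CombinationDesign, CombinationStudy, DoseResponseStudy, FrequencySweep

__all__ = [
    "GeneratorConfig",
    "generate_single_drug",
    "generate_combination",
    "generate_rheology",
]

#: Default multiplicative noise (sd of log area).
DEFAULT_SIGMA_LOG = 0.15
DEFAULT_N_PER_GROUP = 6  # "at least six repetitions" per group
DEFAULT_CONTROL_AREA = 100.0  # mm^2, ethanol-only lesion scale
DEFAULT_LEVELS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for one synthetic dose-response study."""

    dm_true: float  # mg/kg
    m_true: float
    control_area_mean: float = DEFAULT_CONTROL_AREA  # mm^2
    area_noise_sigma_log: float = DEFAULT_SIGMA_LOG
    n_per_group: int = DEFAULT_N_PER_GROUP
    dose_levels: tuple[float, ...] | None = None  # mg/kg; None -> ladder on dm_true
    seed: int | None = 0
    noise: str = "lognormal"  # or "truncnorm"
    treatment_id: str = "drug"

    def __post_init__(self) -> None:
        if self.dm_true <= 0 or self.m_true <= 0:
            raise ValueError("dm_true and m_true must be positive")
        if self.control_area_mean <= 0:
            raise ValueError("control_area_mean must be positive")
        if self.area_noise_sigma_log < 0:
            raise ValueError("area_noise_sigma_log must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if self.noise not in ("lognormal", "truncnorm"):
            raise ValueError("noise must be 'lognormal' or 'truncnorm'")

    @property
    def doses(self) -> np.ndarray:
        if self.dose_levels is not None:
            return np.asarray(self.dose_levels, dtype=float)
        return self.dm_true * np.asarray(DEFAULT_LEVELS)


def _fa_true(dose: np.ndarray, dm: float, m: float) -> np.ndarray:
    ratio = (np.asarray(dose, dtype=float) / dm) ** m
    return ratio / (1.0 + ratio)


def _noisy_areas(rng, mean: float, n: int, sigma: float, noise: str) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, mean)
    if noise == "lognormal":
        return mean * np.exp(rng.normal(0.0, sigma, size=n))
    # truncated normal on (0, inf) with matching relative scale
    a = -1.0 / sigma  # truncation at zero in standardized units
    return mean * (1.0 + sigma * sps.truncnorm.rvs(a, np.inf, size=n, random_state=rng))


def generate_single_drug(config: GeneratorConfig) -> DoseResponseStudy:
    """Forward-simulate one single-drug study (control group included)."""
    rng = np.random.default_rng(config.seed)
    doses_out: list[float] = []
    areas_out: list[np.ndarray] = []
    ids: list[str] = []
    # ethanol-only control
    areas_out.append(
        _noisy_areas(rng, config.control_area_mean, config.n_per_group,
                     config.area_noise_sigma_log, config.noise)
    )
    doses_out.extend([0.0] * config.n_per_group)
    ids.extend(f"C{i + 1}" for i in range(config.n_per_group))
    for level, dose in enumerate(config.doses, start=1):
        fa = float(_fa_true(dose, config.dm_true, config.m_true))
        mean = config.control_area_mean * (1.0 - fa)
        areas_out.append(
            _noisy_areas(rng, mean, config.n_per_group, config.area_noise_sigma_log, config.noise)
        )
        doses_out.extend([float(dose)] * config.n_per_group)
        ids.extend(f"D{level}-{i + 1}" for i in range(config.n_per_group))
    return DoseResponseStudy(
        treatment_id=config.treatment_id,
        animal_ids=ids,
        doses=np.asarray(doses_out),
        areas=np.concatenate(areas_out),
    )


def _solve_fa_for_ci(
    total: float,
    share1: float,
    dm1: float,
    m1: float,
    dm2: float,
    m2: float,
    target: Callable[[float], float],
    eps: float = 1e-9,
) -> float:
    """fa at which the combination's CI equals the target (monotone root)."""

    def g(fa: float) -> float:
        rho = fa / (1.0 - fa)
        dx1 = dm1 * rho ** (1.0 / m1)
        dx2 = dm2 * rho ** (1.0 / m2)
        return total * share1 / dx1 + total * (1.0 - share1) / dx2 - target(fa)

    lo, hi = eps, 1.0 - eps
    glo, ghi = g(lo), g(hi)
    if glo < 0.0:  # even tiny fa over-shoots the target CI
        warnings.warn("CI root below fa grid; clamped to lower bound", stacklevel=3)
        return lo
    if ghi > 0.0:
        warnings.warn("CI root above fa grid; clamped to upper bound", stacklevel=3)
        return hi
    return float(optimize.brentq(g, lo, hi, xtol=1e-14, rtol=1e-14))


def generate_combination(
    config1: GeneratorConfig,
    config2: GeneratorConfig,
    interaction_ci: float | Callable[[float], float] = 1.0,
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_per_group: int | None = None,
    control_area_mean: float | None = None,
    area_noise_sigma_log: float | None = None,
    seed: int | None = 0,
    noise: str = "lognormal",
) -> CombinationStudy:
    """Forward-simulate an equipotent constant-ratio combination study.

    ``interaction_ci`` is the constant combination index the generated
    responses satisfy at every dose level (or a callable fa -> CI for
    fa-dependent profiles).  With interaction_ci = 1 the combination is
    exactly Loewe additive.
    """
    if callable(interaction_ci):
        target = interaction_ci
    else:
        if interaction_ci <= 0:
            raise ValueError("interaction_ci must be positive")
        ci_val = float(interaction_ci)
        target = lambda fa: ci_val  # noqa: E731
    n = n_per_group if n_per_group is not None else config1.n_per_group
    control_mean = control_area_mean if control_area_mean is not None else config1.control_area_mean
    sigma = area_noise_sigma_log if area_noise_sigma_log is not None else config1.area_noise_sigma_log
    rng = np.random.default_rng(seed)

    design = CombinationDesign(
        config1.treatment_id, config2.treatment_id,
        config1.dm_true, config2.dm_true, tuple(float(k) for k in levels),
    )
    share1 = design.dm1 / (design.dm1 + design.dm2)

    ids: list[str] = [f"C{i + 1}" for i in range(n)]
    d1 = [0.0] * n
    d2 = [0.0] * n
    areas = [_noisy_areas(rng, control_mean, n, sigma, noise)]
    for level, (dose1, dose2) in enumerate(design.doses, start=1):
        total = dose1 + dose2
        fa = _solve_fa_for_ci(
            total, share1, config1.dm_true, config1.m_true,
            config2.dm_true, config2.m_true, target,
        )
        mean = control_mean * (1.0 - fa)
        areas.append(_noisy_areas(rng, mean, n, sigma, noise))
        d1.extend([dose1] * n)
        d2.extend([dose2] * n)
        ids.extend(f"K{level}-{i + 1}" for i in range(n))
    return CombinationStudy(
        design=design,
        animal_ids=ids,
        dose1=np.asarray(d1),
        dose2=np.asarray(d2),
        areas=np.concatenate(areas),
    )


def generate_rheology(
    omegas: Sequence[float] | None = None,
    suspension_elastic: tuple[float, float] = (4.0, 0.18),  # (amplitude Pa, exponent)
    suspension_viscous: tuple[float, float] = (7.0, 0.22),
    mucin_elastic: tuple[float, float] = (1.5, 0.25),
    mucin_viscous: tuple[float, float] = (3.0, 0.28),
    synergy_offset: float | Callable[[np.ndarray], np.ndarray] = 0.0,
    synergy_offset_viscous: float | Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[FrequencySweep, FrequencySweep, FrequencySweep]:
    """Power-law sweeps for suspension, mucin, and their mixture.

    The mixture equals the component sum plus the synergy offset
    (elastic; the viscous offset defaults to the same).  Defaults mimic a
    weak viscous-dominant gel measured from 1 to 100 rad/s at 37 degC.
    """
    if omegas is None:
        # instrument-like sweep over 1-100 rad/s containing the
        # conventional reporting frequencies 2.5, 5 and 10 rad/s
        omegas = (1.0, 1.6, 2.5, 4.0, 5.0, 6.3, 10.0, 16.0, 25.0, 40.0, 63.0, 100.0)
    omega = np.asarray(omegas, dtype=float)
    if np.any(np.diff(omega) <= 0) or np.any(omega <= 0):
        raise ValueError("omegas must be positive and strictly increasing")
    rng = np.random.default_rng(seed)

    def offset_values(off) -> np.ndarray:
        if callable(off):
            return np.asarray(off(omega), dtype=float)
        return np.full_like(omega, float(off))

    def power_law(params: tuple[float, float]) -> np.ndarray:
        amplitude, exponent = params
        return amplitude * omega**exponent

    def jitter(values: np.ndarray) -> np.ndarray:
        if noise_sigma == 0.0:
            return values
        return values * np.exp(rng.normal(0.0, noise_sigma, size=values.shape))

    sus_el, sus_vi = power_law(suspension_elastic), power_law(suspension_viscous)
    muc_el, muc_vi = power_law(mucin_elastic), power_law(mucin_viscous)
    off_el = offset_values(synergy_offset)
    off_vi = offset_values(synergy_offset if synergy_offset_viscous is None else synergy_offset_viscous)
    mix_el = sus_el + muc_el + off_el
    mix_vi = sus_vi + muc_vi + off_vi
    if np.any(mix_el < 0) or np.any(mix_vi < 0):
        raise ValueError("synergy offset drives mixture moduli negative")
    sus = FrequencySweep("suspension", omega, jitter(sus_el), jitter(sus_vi))
    muc = FrequencySweep("mucin", omega, jitter(muc_el), jitter(muc_vi))
    mix = FrequencySweep("mixture", omega, jitter(mix_el), jitter(mix_vi))
    return sus, muc, mix
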