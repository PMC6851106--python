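"""Typed containers for dose-response, combination, and rheology data.

Units are fixed throughout the package: doses in mg/kg, gastric damage
areas in mm^2, angular frequency in rad/s, moduli in Pa.  No unit
inference is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseStudy",
    "AffectedFraction",
    "CombinationDesign",
    "CombinationStudy",
    "FrequencySweep",
]

_RATIO_RTOL = 1e-9


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class DoseResponseStudy:
    """Per-animal lesion areas for one treatment plus its vehicle control.

    Records with ``dose == 0`` are the ethanol-only control animals; they
    define the denominator of the affected fraction but never enter the
    median-effect regression.
    """

    treatment_id: str
    animal_ids: list[str]
    doses: np.ndarray  # mg/kg, >= 0
    areas: np.ndarray  # mm^2, >= 0

    def __post_init__(self) -> None:
        self.doses = _as_float_array(self.doses, "doses")
        self.areas = _as_float_array(self.areas, "areas")
        self.animal_ids = [str(a) for a in self.animal_ids]
        n = len(self.animal_ids)
        if not (len(self.doses) == len(self.areas) == n):
            raise ValueError("animal_ids, doses and areas must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(self.areas < 0):
            raise ValueError("damage areas must be non-negative")

    @property
    def control_mask(self) -> np.ndarray:
        return self.doses == 0.0

    @property
    def control_areas(self) -> np.ndarray:
        return self.areas[self.control_mask]

    @property
    def dose_levels(self) -> np.ndarray:
        """Sorted distinct positive doses."""
        return np.unique(self.doses[self.doses > 0])

    def group_mean_areas(self) -> pd.Series:
        """Mean damage area per dose level (duplicate doses pooled)."""
        return pd.Series(self.areas).groupby(pd.Series(self.doses)).mean()

    def group_areas(self, dose: float) -> np.ndarray:
        return self.areas[self.doses == dose]

    def scaled_doses(self, factor: float) -> "DoseResponseStudy":
        return DoseResponseStudy(
            self.treatment_id, list(self.animal_ids), self.doses * factor, self.areas.copy()
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, treatment_id: str | None = None) -> "DoseResponseStudy":
        if treatment_id is None:
            ids = frame["treatment"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds several treatments; pass treatment_id")
            treatment_id = str(ids[0])
        else:
            frame = frame[frame["treatment"].astype(str) == str(treatment_id)]
        return cls(
            treatment_id=str(treatment_id),
            animal_ids=frame["animal_id"].astype(str).tolist(),
            doses=frame["dose_mg_per_kg"].to_numpy(dtype=float),
            areas=frame["damage_area_mm2"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment_id,
                "animal_id": self.animal_ids,
                "dose_mg_per_kg": self.doses,
                "damage_area_mm2": self.areas,
            }
        )


@dataclass(frozen=True)
class AffectedFraction:
    """Group-level affected fraction at one dose.

    ``fa`` is the fractional reduction of mean lesion area relative to the
    ethanol-only control; ``fu = 1 - fa`` is the unaffected fraction.
    """

    dose: float  # mg/kg, > 0
    fa: float  # in (0, 1) after clamping
    n_animals: int
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fa < 1.0:
            raise ValueError("fa must lie strictly inside (0, 1)")
        if self.dose <= 0:
            raise ValueError("dose must be positive")

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


@dataclass(frozen=True)
class CombinationDesign:
    """Fixed-ratio (equipotent "1:1") combination dose ladder.

    Each level multiplies both drugs' median doses by the same factor k, so
    the dose ratio D1:D2 is constant and equal to Dm1:Dm2 along the
    diagonal of the design.
    """

    drug1_id: str
    drug2_id: str
    dm1: float
    dm2: float
    ratio_levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if self.dm1 <= 0 or self.dm2 <= 0:
            raise ValueError("median doses must be positive")
        if any(k <= 0 for k in self.ratio_levels):
            raise ValueError("ratio levels must be positive")

    @property
    def doses(self) -> list[tuple[float, float]]:
        return [(k * self.dm1, k * self.dm2) for k in self.ratio_levels]

    @property
    def total_doses(self) -> np.ndarray:
        return np.array([k * (self.dm1 + self.dm2) for k in self.ratio_levels])

    @property
    def dose_ratio(self) -> float:
        """Constant D1/D2 ratio along the diagonal."""
        return self.dm1 / self.dm2


@dataclass
class CombinationStudy:
    """Per-animal outcomes of a constant-ratio combination experiment."""

    design: CombinationDesign
    animal_ids: list[str]
    dose1: np.ndarray
    dose2: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.dose1 = _as_float_array(self.dose1, "dose1")
        self.dose2 = _as_float_array(self.dose2, "dose2")
        self.areas = _as_float_array(self.areas, "areas")
        self.animal_ids = [str(a) for a in self.animal_ids]
        n = len(self.animal_ids)
        if not (len(self.dose1) == len(self.dose2) == len(self.areas) == n):
            raise ValueError("columns must have equal length")
        treated = (self.dose1 > 0) & (self.dose2 > 0)
        if np.any((self.dose1 > 0) != (self.dose2 > 0)):
            raise ValueError("component doses must be jointly zero (control) or jointly positive")
        if treated.any():
            ratios = self.dose1[treated] / self.dose2[treated]
            if not np.allclose(ratios, ratios[0], rtol=_RATIO_RTOL, atol=0.0):
                raise ValueError("dose1:dose2 ratio must be constant across records")

    @property
    def control_areas(self) -> np.ndarray:
        return self.areas[(self.dose1 == 0) & (self.dose2 == 0)]

    def to_total_dose_study(self) -> DoseResponseStudy:
        """View the combination as a single pseudo-drug dosed at D1 + D2."""
        return DoseResponseStudy(
            treatment_id=f"{self.design.drug1_id}+{self.design.drug2_id}",
            animal_ids=list(self.animal_ids),
            doses=self.dose1 + self.dose2,
            areas=self.areas.copy(),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CombinationStudy":
        d1 = frame["dose1_mg_per_kg"].to_numpy(dtype=float)
        d2 = frame["dose2_mg_per_kg"].to_numpy(dtype=float)
        treated = d1 > 0
        drug1 = str(frame["drug1"].iloc[0])
        drug2 = str(frame["drug2"].iloc[0])
        if treated.any():
            dm1 = float(np.max(d1)) / 4.0  # nominal; design recovered up to scale
            dm2 = float(np.max(d2)) / 4.0
        else:  # pragma: no cover - degenerate file
            dm1 = dm2 = 1.0
        levels = tuple(sorted(set(np.round(d1[treated] / dm1, 12)))) or (1.0,)
        design = CombinationDesign(drug1, drug2, dm1, dm2, tuple(float(k) for k in levels))
        return cls(
            design=design,
            animal_ids=frame["animal_id"].astype(str).tolist(),
            dose1=d1,
            dose2=d2,
            areas=frame["damage_area_mm2"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug1": self.design.drug1_id,
                "drug2": self.design.drug2_id,
                "animal_id": self.animal_ids,
                "dose1_mg_per_kg": self.dose1,
                "dose2_mg_per_kg": self.dose2,
                "damage_area_mm2": self.areas,
            }
        )


@dataclass
class FrequencySweep:
    """Small-amplitude oscillatory shear sweep: (omega, G', G'') triples."""

    sample_id: str
    omega: np.ndarray  # rad/s, strictly increasing
    g_elastic: np.ndarray  # G', Pa
    g_viscous: np.ndarray  # G'', Pa
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        self.omega = _as_float_array(self.omega, "omega")
        self.g_elastic = _as_float_array(self.g_elastic, "g_elastic")
        self.g_viscous = _as_float_array(self.g_viscous, "g_viscous")
        if len(self.omega) < 2:
            raise ValueError("a sweep needs at least two frequencies")
        if not (len(self.omega) == len(self.g_elastic) == len(self.g_viscous)):
            raise ValueError("sweep columns must have equal length")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive")
        if np.any(self.g_elastic < 0) or np.any(self.g_viscous < 0):
            raise ValueError("moduli must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str | None = None) -> "FrequencySweep":
        if sample_id is None:
            ids = frame["sample_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds several samples; pass sample_id")
            sample_id = str(ids[0])
        else:
            frame = frame[frame["sample_id"].astype(str) == str(sample_id)]
        frame = frame.sort_values("omega_rad_s")
        return cls(
            sample_id=str(sample_id),
            omega=frame["omega_rad_s"].to_numpy(dtype=float),
            g_elastic=frame["G_prime_Pa"].to_numpy(dtype=float),
            g_viscous=frame["G_doubleprime_Pa"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "omega_rad_s": self.omega,
                "G_prime_Pa": self.g_elastic,
                "G_doubleprime_Pa": self.g_viscous,
            }
        )
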