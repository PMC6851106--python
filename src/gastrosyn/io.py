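"""CSV readers/writers for the documented schemas.

All files are UTF-8 CSV with a header row and dot decimals.

* dose-response: treatment,animal_id,dose_mg_per_kg,damage_area_mm2
  (dose 0 = ethanol-only control)
* combination:   drug1,drug2,animal_id,dose1_mg_per_kg,dose2_mg_per_kg,
                 damage_area_mm2
* rheology:      sample_id,omega_rad_s,G_prime_Pa,G_doubleprime_Pa
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .study import CombinationStudy, DoseResponseStudy, FrequencySweep

__all__ = [
    "ParseError",
    "read_dose_response",
    "read_combination",
    "read_sweep",
    "write_study",
    "write_combination",
    "write_sweeps",
]

DOSE_RESPONSE_COLUMNS = ("treatment", "animal_id", "dose_mg_per_kg", "damage_area_mm2")
COMBINATION_COLUMNS = (
    "drug1", "drug2", "animal_id", "dose1_mg_per_kg", "dose2_mg_per_kg", "damage_area_mm2",
)
SWEEP_COLUMNS = ("sample_id", "omega_rad_s", "G_prime_Pa", "G_doubleprime_Pa")


class ParseError(ValueError):
    """Structured CSV validation failure (missing column, bad cell, empty file)."""


def _load(path, required: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    for col in numeric:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() & frame[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value(s) in column {col!r} at line(s) "
                + ", ".join(map(str, bad[:5]))
            )
        if values.isna().any():
            lines = frame.index[values.isna()] + 2
            raise ParseError(
                f"{path}: empty cell(s) in column {col!r} at line(s) "
                + ", ".join(map(str, lines[:5]))
            )
        frame[col] = values
    return frame


def read_dose_response(path, treatment_id: str | None = None) -> DoseResponseStudy:
    frame = _load(path, DOSE_RESPONSE_COLUMNS, ("dose_mg_per_kg", "damage_area_mm2"))
    try:
        return DoseResponseStudy.from_frame(frame, treatment_id)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_dose_response_all(path) -> dict[str, DoseResponseStudy]:
    """Read every treatment present in one dose-response CSV."""
    frame = _load(path, DOSE_RESPONSE_COLUMNS, ("dose_mg_per_kg", "damage_area_mm2"))
    return {
        str(t): DoseResponseStudy.from_frame(frame, str(t))
        for t in frame["treatment"].unique()
    }


def read_combination(path) -> CombinationStudy:
    frame = _load(path, COMBINATION_COLUMNS, ("dose1_mg_per_kg", "dose2_mg_per_kg", "damage_area_mm2"))
    try:
        return CombinationStudy.from_frame(frame)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_sweep(path, sample_id: str | None = None) -> FrequencySweep:
    frame = _load(path, SWEEP_COLUMNS, ("omega_rad_s", "G_prime_Pa", "G_doubleprime_Pa"))
    try:
        return FrequencySweep.from_frame(frame, sample_id)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_study(study: DoseResponseStudy, path) -> None:
    study.to_frame().to_csv(path, index=False)


def write_combination(study: CombinationStudy, path) -> None:
    study.to_frame().to_csv(path, index=False)


def write_sweeps(sweeps, path) -> None:
    pd.concat([s.to_frame() for s in np.atleast_1d(sweeps)]).to_csv(path, index=False)
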