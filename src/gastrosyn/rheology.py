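"""Rheological mucoadhesion synergy from oscillatory frequency sweeps.

Mucoadhesion is inferred from small-amplitude oscillatory shear of three
samples measured under identical conditions: the drug suspension, the
mucin dispersion, and their mixture.  The synergy parameters at each
angular frequency are

    dG'  = G'_mix  - (G'_sus  + G'_muc)
    dG'' = G''_mix - (G''_sus + G''_muc)

Positive values of both indicate an interaction between suspension and
mucin, i.e. mucoadhesion.

Instrument frequency grids rarely coincide, so sweeps are first aligned
onto a common grid.  Moduli of weak gels are near power-law in omega, so
interpolation is log-log linear by default (exact for power laws); plain
linear interpolation is available and is used automatically for a
channel containing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import FrequencySweep

__all__ = [
    "DEFAULT_SYNERGY_OMEGAS",
    "AlignedSweeps",
    "SynergyResult",
    "align_sweeps",
    "synergy_parameters",
    "pseudo_solid_check",
]

#: Angular frequencies (rad/s) at which synergy is conventionally reported.
DEFAULT_SYNERGY_OMEGAS: tuple[float, ...] = (2.5, 5.0, 10.0)


def _interp_channel(omega, g, targets, mode: str) -> np.ndarray:
    if mode == "loglog" and np.all(g > 0):
        out = np.exp(np.interp(np.log(targets), np.log(omega), np.log(g)))
    else:
        # linear fallback handles zero moduli, where log is undefined
        out = np.interp(targets, omega, g)
    # a target that was actually measured is returned bit-exactly
    exact = np.searchsorted(omega, targets)
    for i, j in enumerate(exact):
        if j < len(omega) and omega[j] == targets[i]:
            out[i] = g[j]
    return out


@dataclass
class AlignedSweeps:
    """Suspension/mucin/mixture moduli interpolated onto one omega grid."""

    omega: np.ndarray
    g_elastic: pd.DataFrame  # columns: suspension, mucin, mixture
    g_viscous: pd.DataFrame


def align_sweeps(
    suspension: FrequencySweep,
    mucin: FrequencySweep,
    mixture: FrequencySweep,
    omegas=DEFAULT_SYNERGY_OMEGAS,
    interpolation: str = "loglog",
) -> AlignedSweeps:
    """Interpolate all three sweeps at the target angular frequencies.

    Raises if any target frequency falls outside any sweep's measured
    range (no extrapolation).
    """
    if interpolation not in ("loglog", "linear"):
        raise ValueError("interpolation must be 'loglog' or 'linear'")
    targets = np.atleast_1d(np.asarray(omegas, dtype=float))
    if targets.size == 0:
        raise ValueError("no target frequencies given")
    sweeps = {"suspension": suspension, "mucin": mucin, "mixture": mixture}
    for role, sweep in sweeps.items():
        if targets.min() < sweep.omega[0] or targets.max() > sweep.omega[-1]:
            raise ValueError(
                f"omega out of range: targets must lie within "
                f"[{sweep.omega[0]:g}, {sweep.omega[-1]:g}] rad/s of the "
                f"{role} sweep ({sweep.sample_id!r})"
            )
    g_el = pd.DataFrame(
        {r: _interp_channel(s.omega, s.g_elastic, targets, interpolation) for r, s in sweeps.items()},
        index=targets,
    )
    g_vi = pd.DataFrame(
        {r: _interp_channel(s.omega, s.g_viscous, targets, interpolation) for r, s in sweeps.items()},
        index=targets,
    )
    return AlignedSweeps(omega=targets, g_elastic=g_el, g_viscous=g_vi)


@dataclass(frozen=True)
class SynergyResult:
    """Synergy parameters at one angular frequency."""

    omega: float  # rad/s
    dg_elastic: float  # Pa
    dg_viscous: float  # Pa

    @property
    def mucoadhesive(self) -> bool:
        return self.dg_elastic > 0.0 and self.dg_viscous > 0.0


def synergy_parameters(aligned: AlignedSweeps) -> list[SynergyResult]:
    """dG' and dG'' at each aligned frequency, by direct subtraction."""
    out = []
    for i, omega in enumerate(aligned.omega):
        el = aligned.g_elastic.iloc[i]
        vi = aligned.g_viscous.iloc[i]
        out.append(
            SynergyResult(
                omega=float(omega),
                dg_elastic=float(el["mixture"] - (el["suspension"] + el["mucin"])),
                dg_viscous=float(vi["mixture"] - (vi["suspension"] + vi["mucin"])),
            )
        )
    return out


def synergy_frame(results: list[SynergyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "omega_rad_s": [r.omega for r in results],
            "dG_prime_Pa": [r.dg_elastic for r in results],
            "dG_doubleprime_Pa": [r.dg_viscous for r in results],
            "mucoadhesive": [r.mucoadhesive for r in results],
        }
    )


def pseudo_solid_check(sweep: FrequencySweep) -> np.ndarray:
    """Per-frequency flag for viscous dominance, G'' > G' (strict).

    Conventions differ on which dominance marks the structured
    ("pseudo-solid") regime — some authors require the loss modulus to
    dominate with weak frequency dependence, others the storage modulus —
    so this flag is reported alongside the synergy parameters but never
    gates them.  The complementary elastic-dominance vector is simply the
    negation wherever the moduli are unequal.
    """
    return sweep.g_viscous > sweep.g_elastic
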