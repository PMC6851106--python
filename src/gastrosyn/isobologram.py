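"""Normalized isobolograms with a curved additivity envelope.

A normalized isobologram plots a = D1/Dm1 against b = D2/Dm2 for dose
pairs producing the median effect.  The straight isobole b = 1 - a is the
Loewe-additive line.  When the two drugs' shape parameters differ, the
additive region widens into an envelope between a concave and a convex
isobole; in normalized coordinates these are taken as

    b_concave(a) = (1 - a)^(m1/m2)
    b_convex(a)  = 1 - a^(m1/m2)

Both pass through (0, 1) and (1, 0) and collapse onto the straight line
when m1 = m2.  (The raw published forms of these curves mix normalized
and absolute doses and are dimensionally inconsistent in normalized
space; the closed forms above are the normalization that reproduces the
stated endpoints and the equal-slope limit.)

Points below the lower envelope branch indicate synergism, points above
the upper branch antagonism, points within the envelope additivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_point",
    "additivity_envelope",
    "classify_point",
    "Envelope",
    "IsobologramModel",
]


def normalize_point(d1: float, d2: float, dm1: float, dm2: float) -> tuple[float, float]:
    """Normalized isobologram coordinates (D1/Dm1, D2/Dm2)."""
    if dm1 <= 0 or dm2 <= 0:
        raise ValueError("median doses must be positive")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be non-negative")
    return d1 / dm1, d2 / dm2


def _branches(a: np.ndarray, m1: float, m2: float) -> tuple[np.ndarray, np.ndarray]:
    exponent = m1 / m2
    concave = (1.0 - a) ** exponent
    convex = 1.0 - a**exponent
    return concave, convex


@dataclass
class Envelope:
    """Additivity envelope sampled on a grid of normalized abscissae."""

    m1: float
    m2: float
    a: np.ndarray
    b_line: np.ndarray
    b_concave: np.ndarray
    b_convex: np.ndarray

    def lower(self, a: float) -> float:
        c, x = _branches(np.asarray(a, dtype=float), self.m1, self.m2)
        return float(np.minimum(c, x))

    def upper(self, a: float) -> float:
        c, x = _branches(np.asarray(a, dtype=float), self.m1, self.m2)
        return float(np.maximum(c, x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": self.a,
                "b_line": self.b_line,
                "b_concave": self.b_concave,
                "b_convex": self.b_convex,
            }
        )


def additivity_envelope(m1: float, m2: float, a_grid=None) -> Envelope:
    """Concave/convex isoboles plus the straight additive line on [0, 1]."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("shape parameters must be positive")
    if a_grid is None:
        a_grid = np.linspace(0.0, 1.0, 201)
    a = np.asarray(a_grid, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("a grid must lie within [0, 1]")
    concave, convex = _branches(a, m1, m2)
    return Envelope(m1=m1, m2=m2, a=a, b_line=1.0 - a, b_concave=concave, b_convex=convex)


def classify_point(point: tuple[float, float], envelope: Envelope, tol: float = 1e-9) -> str:
    """Place a normalized (a, b) point relative to the additivity envelope.

    Boundary inclusion: points on either branch (within ``tol``, which
    absorbs floating-point jitter of fitted coordinates) count as
    additive.  Points with a > 1 or b > 1 lie beyond both single-drug
    median doses and are antagonism outright.
    """
    a, b = float(point[0]), float(point[1])
    if a > 1.0 + tol or b > 1.0 + tol:
        return "antagonism"
    lower, upper = envelope.lower(a), envelope.upper(a)
    if b < lower - tol:
        return "synergism"
    if b > upper + tol:
        return "antagonism"
    return "additive"


@dataclass
class IsobologramModel:
    """Normalized isobologram for one equipotent combination.

    The experimental point for the equipotent design sits at
    a = b = Dm_exp / (Dm1 + Dm2); the theoretical additive point is
    (0.5, 0.5).  The CI at fa = 0.5 equals a + b for this point.
    """

    dm1: float
    dm2: float
    m1: float
    m2: float
    dm_exp: float

    @property
    def exp_point(self) -> tuple[float, float]:
        coord = self.dm_exp / (self.dm1 + self.dm2)
        return coord, coord

    @property
    def theo_point(self) -> tuple[float, float]:
        return 0.5, 0.5

    def envelope(self, a_grid=None) -> Envelope:
        return additivity_envelope(self.m1, self.m2, a_grid)

    def classify(self) -> str:
        return classify_point(self.exp_point, self.envelope())

    def to_frame(self, a_grid=None) -> pd.DataFrame:
        frame = self.envelope(a_grid).to_frame()
        frame.attrs["exp_point"] = self.exp_point
        frame.attrs["theo_point"] = self.theo_point
        return frame
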