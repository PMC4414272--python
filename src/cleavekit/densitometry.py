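"""Gel densitometry: band intensities -> fraction cleaved.

A cleavage gel lane shows the uncut full-length fusion (fl) and the
C-terminal cleavage product (ccp). Per mole, the two bands stain with
different efficiency (roughly in proportion to mass for Coomassie), so the
naive intensity ratio ccp/(ccp + fl) is biased. A cleavage standard —
defined mixtures of fully cleaved and uncleaved sample run on the same
gel — calibrates a single response factor r, the per-mole staining
intensity of the ccp band relative to the full-length band, through the
one-parameter model

    fraction = ccp / (ccp + r * fl).

With the calibrated r, any lane's band pair converts to a fraction
cleaved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import CalibrationError, DataError, DomainError

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "CleavageStandardModel",
    "build_standard_curve",
    "fraction_from_bands",
    "DEFAULT_LADDER",
]

#: default mixing ladder of cleaved fractions for a synthetic standard;
#: brackets the calls a titration gel has to make ("near complete", "~50%").
DEFAULT_LADDER = (0.0, 0.10, 0.25, 0.50, 0.75, 0.90, 1.0)


@dataclass(frozen=True)
class StandardPoint:
    """One lane of a cleavage standard: a known mixed fraction of fully
    cleaved material and its two band intensities (arbitrary units)."""

    known_fraction: float
    intensity_fl: float
    intensity_ccp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.known_fraction <= 1.0):
            raise DomainError(
                f"known_fraction must lie in [0,1], got {self.known_fraction!r}"
            )
        for name in ("intensity_fl", "intensity_ccp"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")


class CleavageStandardModel:
    """Response-factor calibration model for a cleavage standard.

    Fits the scalar r in fraction = ccp/(ccp + r*fl) to the known mixing
    fractions by least squares. Needs at least two lanes with distinct
    known fractions, of which at least one must be informative about r
    (0 < fraction < 1 lanes; pure lanes pin the endpoints but not r).
    """

    def __init__(self, points: Sequence[StandardPoint]):
        pts = list(points)
        if len(pts) < 2:
            raise CalibrationError("need >= 2 standard points")
        fracs = {round(p.known_fraction, 12) for p in pts}
        if len(fracs) < 2:
            raise CalibrationError(
                "standard points must span >= 2 distinct known fractions"
            )
        self.points = pts
        self.f_known = np.array([p.known_fraction for p in pts])
        self.fl = np.array([p.intensity_fl for p in pts])
        self.ccp = np.array([p.intensity_ccp for p in pts])

    def fit(self, r0: float = 1.0) -> "StandardCurve":
        def predicted(log_r):
            r = np.exp(log_r)
            denom = self.ccp + r * self.fl
            # a truly empty lane cannot constrain r; treat as its known value
            with np.errstate(invalid="ignore", divide="ignore"):
                pred = np.where(denom > 0, self.ccp / denom, self.f_known)
            return pred

        sol = least_squares(
            lambda x: predicted(x[0]) - self.f_known, x0=[math.log(r0)]
        )
        r_hat = float(np.exp(sol.x[0]))
        resid = predicted(sol.x[0]) - self.f_known
        return StandardCurve(points=tuple(self.points), response_factor=r_hat,
                             residuals=resid)


@dataclass(frozen=True)
class StandardCurve:
    """A fitted cleavage-standard calibration.

    ``response_factor`` r relates the per-mole staining intensities of the
    ccp and full-length bands; ``residuals`` are fitted-minus-known
    fractions at the standard lanes.
    """

    points: tuple[StandardPoint, ...]
    response_factor: float
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not math.isfinite(self.response_factor) or self.response_factor <= 0:
            raise CalibrationError(
                f"response factor must be finite and > 0, got {self.response_factor!r}"
            )

    @classmethod
    def from_mass_ratio(cls, mass_ccp: float, mass_fl: float) -> "StandardCurve":
        """Mass-proportional default when no standards were run: Coomassie
        staining scales roughly with chain mass, so r ~= mass_ccp/mass_fl."""
        if mass_ccp <= 0 or mass_fl <= 0:
            raise DomainError("masses must be > 0")
        return cls(points=(), response_factor=mass_ccp / mass_fl)

    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.residuals.size else 0.0

    def summary(self) -> str:
        lines = [
            "Cleavage-standard calibration",
            "=" * 45,
            "model:             fraction = ccp/(ccp + r*fl)",
            f"n standard lanes:  {len(self.points)}",
            f"response factor r: {self.response_factor:.6g}",
            f"RMS residual:      {self.rms_residual():.3g}",
        ]
        return "\n".join(lines)

    def __call__(self, fl: float, ccp: float) -> float:
        return fraction_from_bands(fl, ccp, self)


def build_standard_curve(points: Sequence[StandardPoint]) -> StandardCurve:
    """Fit the response factor to a list of standard lanes."""
    return CleavageStandardModel(points).fit()


def fraction_from_bands(fl: float, ccp: float, curve: StandardCurve) -> float:
    """Convert one lane's band intensities to fraction cleaved.

    Returns ccp/(ccp + r*fl), clamped to [0,1]. An empty lane (both bands
    zero) is a data error, not a fraction.
    """
    for name, v in (("intensity_fl", fl), ("intensity_ccp", ccp)):
        if not math.isfinite(v) or v < 0:
            raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
    if fl == 0.0 and ccp == 0.0:
        raise DataError("empty lane: both band intensities are zero")
    f = ccp / (ccp + curve.response_factor * fl)
    return float(min(max(f, 0.0), 1.0))
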