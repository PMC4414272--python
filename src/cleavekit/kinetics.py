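"""Rate laws for product-inhibited protease cleavage.

A cleavage reaction S -> P + P' releases two fragments; only the
UBL-containing fragment P rebinds the protease and competes with intact
substrate. Extending the Michaelis-Menten rate law with competitive
product inhibition gives

    v = -dS/dt = kcat * E0 * S / ( K_M * (1 + P/K_P + S/K_M) )

with E0 the total enzyme concentration, K_M the Michaelis constant of the
substrate and K_P the inhibition constant of the product. Because substrate
and product present the protease with an essentially identical interaction
surface, K_P ~= K_M is a natural simplification; substituting P = S0 - S
then collapses the rate law to first order,

    v = k_app * S,      k_app = kcat * E0 / (K_M + S0),

so the progress curve is a single exponential and the cleaved fraction is
1 - exp(-k_app * t).

Units are fixed package-wide: concentrations in micromolar (uM), time in
minutes, rates in 1/min. Convert at the I/O boundary, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "KineticParameters",
    "ReactionState",
    "ApparentRate",
    "RateLowerBound",
    "rate_full",
    "rate_equal_affinity",
    "kapp_from_params",
    "fraction_cleaved",
]


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if value < 0:
        raise DomainError(f"{name} must be >= 0, got {value!r}")
    return value


def _check_pos(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if value <= 0:
        raise DomainError(f"{name} must be > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticParameters:
    """Rate-law constants and initial concentrations of one cleavage reaction.

    Parameters
    ----------
    kcat : float
        Catalytic turnover rate, 1/min.
    K_M : float
        Michaelis constant of the intact substrate, uM.
    K_P : float
        Competitive inhibition constant of the cleaved-off UBL product, uM.
    E0 : float
        Total enzyme concentration, uM.
    S0 : float
        Initial substrate concentration, uM.
    """

    kcat: float
    K_M: float
    K_P: float
    E0: float
    S0: float

    def __post_init__(self) -> None:
        _check_nonneg("kcat", self.kcat)
        _check_pos("K_M", self.K_M)
        _check_pos("K_P", self.K_P)
        _check_nonneg("E0", self.E0)
        _check_nonneg("S0", self.S0)

    def with_(self, **changes) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class ReactionState:
    """Instantaneous composition of a cleavage reaction.

    The second, non-inhibitory fragment P' is produced 1:1 with P and is
    not tracked; mass conservation reads S + P = S0.
    """

    S: float
    P: float
    t: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg("S", self.S)
        _check_nonneg("P", self.P)
        _check_nonneg("t", self.t)


@dataclass(frozen=True)
class ApparentRate:
    """An apparent first-order cleavage rate k_app (1/min).

    ``provenance`` records how the value was obtained: ``"from-parameters"``
    (computed from kcat, E0, K_M, S0), ``"single-point"`` (inverted from one
    fraction/time pair) or ``"fitted"`` (nonlinear least squares on a time
    course, in which case ``stderr`` carries the asymptotic standard error).
    """

    k_app: float
    provenance: str
    stderr: float | None = None

    def __post_init__(self) -> None:
        _check_nonneg("k_app", self.k_app)
        if self.provenance not in ("from-parameters", "single-point", "fitted"):
            raise DomainError(
                f"provenance must be one of from-parameters/single-point/fitted, "
                f"got {self.provenance!r}"
            )

    def halflife(self) -> float:
        """Cleavage half-time ln(2)/k_app in minutes."""
        if self.k_app == 0:
            return math.inf
        return math.log(2.0) / self.k_app


@dataclass(frozen=True)
class RateLowerBound:
    """Marker returned when a rate is only bounded from below.

    A lane cleaved to completion within gel resolution carries no rate
    information beyond "at least this fast": with detection resolution
    ``resolution`` (default 1%), full cleavage at time t implies
    k_app >= -ln(resolution)/t.
    """

    min_k_app: float
    t: float
    resolution: float = 0.01

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"k_app >= {self.min_k_app:.4g} 1/min (saturated at t={self.t:g} min)"


def rate_full(state: ReactionState, params: KineticParameters) -> float:
    """Cleavage velocity (uM/min) under full competitive product inhibition.

    v = kcat*E0*S / ( K_M * (1 + P/K_P + S/K_M) ). Returns 0 when S = 0 or
    E0 = 0.
    """
    S, P = state.S, state.P
    if S == 0.0 or params.E0 == 0.0:
        return 0.0
    denom = params.K_M * (1.0 + P / params.K_P + S / params.K_M)
    return params.kcat * params.E0 * S / denom


def rate_equal_affinity(state: ReactionState, params: KineticParameters) -> float:
    """Cleavage velocity (uM/min) under the equal-affinity assumption K_P = K_M.

    v = kcat*E0*S / (K_M + P + S); the ``K_P`` field of ``params`` is ignored.
    Identical to :func:`rate_full` whenever K_P = K_M.
    """
    S, P = state.S, state.P
    if S == 0.0 or params.E0 == 0.0:
        return 0.0
    return params.kcat * params.E0 * S / (params.K_M + P + S)


def kapp_from_params(params: KineticParameters) -> ApparentRate:
    """Apparent first-order rate k_app = kcat*E0/(K_M + S0)."""
    k = params.kcat * params.E0 / (params.K_M + params.S0)
    return ApparentRate(k_app=k, provenance="from-parameters")


def fraction_cleaved(rate: ApparentRate | float, t) -> float:
    """Cleaved fraction 1 - exp(-k_app * t) of the single-exponential model.

    Accepts an :class:`ApparentRate` or a bare rate in 1/min; ``t`` may be a
    scalar or array of minutes. Monotone non-decreasing in both t and k_app.
    """
    import numpy as np

    k = rate.k_app if isinstance(rate, ApparentRate) else float(rate)
    _check_nonneg("k_app", k)
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise DomainError(f"t must be finite and >= 0 minutes, got {t!r}")
    out = -np.expm1(-k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
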