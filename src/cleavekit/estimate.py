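"""Apparent-rate estimation and assay activity summaries.

The workhorse quantity is the apparent first-order cleavage rate k_app.
Under the single-exponential progress model the cleaved fraction obeys
f(t) = 1 - exp(-k_app*t), so a single unsaturated time point suffices to
invert for the rate (:func:`kapp_single_point`), and a multi-point course
can be fitted by nonlinear least squares (:class:`ProgressCurveModel`).
Around the rate sit the activity summaries a tag-removal assay reports:
the molar fold excess of substrate over protease, the minimal protease
concentration achieving near-complete cleavage in a titration, fold
comparisons of activities measured under matched conditions, and the
over-digestion factor relative to that minimal concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    ComparisonError,
    DataError,
    DomainError,
    UnidentifiableError,
)
from .kinetics import ApparentRate, RateLowerBound, fraction_cleaved

__all__ = [
    "TimeCourse",
    "TitrationSeries",
    "TitrationEndpoint",
    "ActivityComparison",
    "OverdigestionFold",
    "ProgressCurveModel",
    "ProgressCurveResults",
    "kapp_single_point",
    "kapp_fit",
    "fold_excess",
    "min_complete_conc",
    "compare_activity",
    "overdigestion_fold",
]

#: detection resolution of a Coomassie gel band: fractions within this of
#: 1.0 are treated as saturated ("complete" lanes) for rate fitting.
SATURATION_EPS = 0.01

#: metadata axes that must agree before two activities may be compared
#: (the axes the assays actually vary).
_MATCH_KEYS = ("substrate", "temp_C", "s0_uM", "nacl_mM")


@dataclass(frozen=True)
class TimeCourse:
    """Sampled progress of one cleavage reaction.

    ``times`` (minutes) strictly increasing; ``fractions`` in [0, 1].
    ``metadata`` carries assay conditions (substrate, protease, temp_C,
    nacl_mM, s0_uM, ...) used for condition-matched comparisons.
    """

    times: np.ndarray
    fractions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if t.ndim != 1 or t.size == 0:
            raise DataError("time course needs at least one point")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(t < 0):
            raise DomainError("times must be >= 0 minutes")
        if np.any((f < 0) | (f > 1)):
            bad = f[(f < 0) | (f > 1)][0]
            raise DomainError(f"fraction_cleaved must lie in [0,1], got {bad!r}")
        if f.shape != t.shape:
            raise DataError("times and fractions must have equal length")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times, "fraction_cleaved": self.fractions})
        for k, v in self.metadata.items():
            df[k] = v
        return df


@dataclass(frozen=True)
class TitrationSeries:
    """Fraction cleaved versus enzyme concentration at fixed substrate,
    time and temperature."""

    enzyme_concs: np.ndarray  # uM, strictly increasing
    fractions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.enzyme_concs, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "enzyme_concs", e)
        object.__setattr__(self, "fractions", f)
        if e.size == 0:
            raise DataError("titration series is empty")
        if np.any(np.diff(e) <= 0):
            raise DomainError("enzyme_concs must be strictly increasing")
        if np.any(e < 0):
            raise DomainError("enzyme_concs must be >= 0 uM")
        if e.shape != f.shape:
            raise DataError("enzyme_concs and fractions must have equal length")
        if np.any((f < 0) | (f > 1)):
            raise DomainError("fraction_cleaved must lie in [0,1]")

    def __len__(self) -> int:
        return self.enzyme_concs.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"enzyme_uM": self.enzyme_concs, "fraction_cleaved": self.fractions}
        )
        for k, v in self.metadata.items():
            df[k] = v
        return df


@dataclass(frozen=True)
class TitrationEndpoint:
    """Minimal enzyme concentration reaching a cleavage threshold.

    ``conc`` is the smallest tested concentration whose fraction met the
    threshold, or None when ``censored`` ("greater than max tested").
    ``upper_bound_only`` flags that even the lowest tested concentration
    passed, so the true minimum may be lower. ``non_monotone`` warns that a
    concentration above ``conc`` failed the threshold (noisy series).
    """

    conc: float | None
    threshold: float
    censored: bool = False
    max_tested: float | None = None
    upper_bound_only: bool = False
    non_monotone: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.censored:
            return f"> {self.max_tested:g} uM (threshold {self.threshold:g} not reached)"
        prefix = "<= " if self.upper_bound_only else ""
        return f"{prefix}{self.conc:g} uM"


@dataclass(frozen=True)
class ActivityComparison:
    """Fold difference between two activities, with direction.

    ``fold`` >= 1; ``faster`` is "a", "b" or "tie". ``is_bound`` marks a
    qualitative ">=" comparison involving a censored input.
    """

    fold: float
    faster: str
    is_bound: bool = False


@dataclass(frozen=True)
class OverdigestionFold:
    """Factor by which applied protease exceeds the minimal sufficient
    concentration; ``is_lower_bound`` when the minimum is only an upper
    bound."""

    fold: float
    is_lower_bound: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (">" if self.is_lower_bound else "") + f"{self.fold:g}-fold"


# ---------------------------------------------------------------------------
# single-point inversion


def kapp_single_point(f: float, t: float) -> ApparentRate | RateLowerBound:
    """Invert one (fraction, time) observation to an apparent rate.

    k_app = -ln(1 - f)/t; round-trips exactly with the forward model
    f = 1 - exp(-k_app*t). A saturated point (f = 1) identifies no rate,
    only a lower bound: the lane is complete within gel resolution, so
    :class:`~cleavekit.kinetics.RateLowerBound` is returned instead.
    """
    if not math.isfinite(f) or f < 0 or f > 1:
        raise DomainError(f"fraction must lie in [0,1], got {f!r}")
    if not math.isfinite(t) or t <= 0:
        raise DomainError(f"t must be > 0 minutes, got {t!r}")
    if f == 1.0:
        return RateLowerBound(
            min_k_app=-math.log(SATURATION_EPS) / t, t=t, resolution=SATURATION_EPS
        )
    return ApparentRate(k_app=-math.log1p(-f) / t, provenance="single-point")


# ---------------------------------------------------------------------------
# multi-point fit, statsmodels-style


class ProgressCurveModel:
    """Single-exponential progress model fitted to a cleavage time course.

    The model is f(t) = 1 - exp(-k*t) with the single parameter k: no
    intercept (nothing is cleaved at t = 0) and no free amplitude (the
    reaction runs to completion). Saturated points (f >= 1 - 0.01) carry
    no rate information and are excluded whenever at least two unsaturated
    points with t > 0 remain; otherwise they are right-censored at
    f = 1 - 0.01 and kept so a lower-bound-ish fit is still possible.

    Examples
    --------
    >>> import numpy as np
    >>> from cleavekit.estimate import ProgressCurveModel, TimeCourse
    >>> tc = TimeCourse([15.0, 30.0], [0.5, 0.75])
    >>> res = ProgressCurveModel(tc).fit()
    >>> round(res.k_app, 4)
    0.0462
    """

    def __init__(self, course: TimeCourse, saturation_eps: float = SATURATION_EPS):
        self.course = course
        self.saturation_eps = float(saturation_eps)
        t, f = course.times, course.fractions
        sat = f >= 1.0 - self.saturation_eps
        usable = (~sat) & (t > 0)
        if usable.sum() < 2:
            # too few unsaturated points: censor saturated ones at 1 - eps
            f = np.where(sat, 1.0 - self.saturation_eps, f)
            usable = t > 0
            self._censored_used = bool(sat.any())
        else:
            self._censored_used = False
        self.t_fit = t[usable]
        self.f_fit = f[usable]
        self.n_saturated = int(sat.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ProgressCurveModel":
        """Build from a DataFrame with ``time_min`` and ``fraction_cleaved``
        columns; remaining columns become metadata (first row)."""
        meta_cols = [c for c in df.columns if c not in ("time_min", "fraction_cleaved")]
        meta = {c: df[c].iloc[0] for c in meta_cols} if len(df) else {}
        course = TimeCourse(
            df["time_min"].to_numpy(), df["fraction_cleaved"].to_numpy(), meta
        )
        return cls(course, **kwargs)

    def fit(self) -> "ProgressCurveResults":
        t, f = self.t_fit, self.f_fit
        if t.size < 2:
            raise DataError(
                f"need >= 2 usable points with t > 0 to fit a rate, have {t.size}"
            )
        if np.all(f >= 1.0 - self.saturation_eps) and self._censored_used:
            raise UnidentifiableError(
                "all points are saturated (cleavage complete); the rate is "
                "unidentifiable, only a lower bound exists"
            )
        # start from the single-point inversion at the most informative point
        mid = int(np.argmin(np.abs(f - 0.5)))
        f0 = min(max(f[mid], 1e-6), 1.0 - 1e-6)
        k0 = max(-math.log1p(-f0) / t[mid], 1e-12)

        def model(tt, k):
            return -np.expm1(-k * tt)

        popt, pcov = curve_fit(
            model, t, f, p0=(k0,), bounds=(0.0, np.inf), maxfev=10000
        )
        k_hat = float(popt[0])
        dof = t.size - 1
        if dof > 0 and np.isfinite(pcov[0, 0]):
            stderr = float(np.sqrt(pcov[0, 0]))
        else:
            stderr = math.nan
        resid = f - model(t, k_hat)
        return ProgressCurveResults(self, k_hat, stderr, resid)


class ProgressCurveResults:
    """Results of a :class:`ProgressCurveModel` fit.

    Attributes
    ----------
    k_app : float
        Fitted apparent rate, 1/min.
    bse : float
        Asymptotic standard error of k_app (NaN when dof = 0).
    resid : ndarray
        Residuals f_obs - f_model at the fitted points.
    """

    def __init__(self, model: ProgressCurveModel, k_app: float, bse: float, resid):
        self.model = model
        self.k_app = k_app
        self.bse = bse
        self.resid = np.asarray(resid)

    @property
    def rate(self) -> ApparentRate:
        return ApparentRate(k_app=self.k_app, provenance="fitted", stderr=self.bse)

    def predict(self, t) -> np.ndarray | float:
        """Predicted fraction cleaved at time(s) t (minutes)."""
        return fraction_cleaved(self.rate, t)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for k_app, floored at 0."""
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        return (max(self.k_app - z * self.bse, 0.0), self.k_app + z * self.bse)

    def summary(self) -> str:
        lines = [
            "Single-exponential progress-curve fit",
            "=" * 45,
            f"model:            f(t) = 1 - exp(-k*t)",
            f"n points used:    {self.model.t_fit.size}"
            + (f"  ({self.model.n_saturated} saturated excluded/censored)"
               if self.model.n_saturated else ""),
            f"k_app (1/min):    {self.k_app:.6g}",
            f"std err:          {self.bse:.3g}",
            f"half-time (min):  {math.log(2)/self.k_app:.5g}" if self.k_app > 0
            else "half-time (min):  inf",
            f"RMS residual:     {float(np.sqrt(np.mean(self.resid**2))):.3g}",
        ]
        meta = self.model.course.metadata
        if meta:
            lines.append("conditions:       " + ", ".join(f"{k}={v}" for k, v in meta.items()))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.model.course
        ax.plot(tc.times, tc.fractions, "o", label="observed")
        tt = np.linspace(0, tc.times.max() * 1.05, 200)
        ax.plot(tt, self.predict(tt), "-",
                label=f"fit k_app={self.k_app:.3g} 1/min")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("fraction cleaved")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax


def kapp_fit(course: TimeCourse) -> ApparentRate:
    """Fit the single-exponential rate to a multi-point time course.

    Convenience wrapper: returns the :class:`ApparentRate` (provenance
    "fitted", with standard error) of ``ProgressCurveModel(course).fit()``.
    """
    return ProgressCurveModel(course).fit().rate


# ---------------------------------------------------------------------------
# activity summaries


def fold_excess(S0: float, E0: float) -> float:
    """Molar fold excess of substrate over protease, S0/E0.

    With 100 uM substrate and 1 nM (0.001 uM) enzyme this is 100000: each
    protease molecule processed on average 1e5 substrate molecules.
    """
    if not math.isfinite(S0) or S0 < 0:
        raise DomainError(f"S0 must be >= 0 uM, got {S0!r}")
    if not math.isfinite(E0) or E0 <= 0:
        raise DomainError(f"E0 must be > 0 uM, got {E0!r}")
    return S0 / E0


def min_complete_conc(
    series: TitrationSeries, threshold: float = 0.95
) -> TitrationEndpoint:
    """Lowest tested enzyme concentration achieving fraction >= threshold.

    Mirrors the visual "lowest fully cut lane" readout of a titration gel.
    If no concentration passes, the result is censored ("greater than max
    tested"); if the lowest tested concentration already passes, the result
    is flagged as an upper bound only. A noisy, non-monotone series still
    returns the smallest passing concentration but carries a warning flag
    when any higher concentration fails.
    """
    if not (0.0 < threshold <= 1.0):
        raise DomainError(f"threshold must lie in (0,1], got {threshold!r}")
    e, f = series.enzyme_concs, series.fractions
    passing = np.flatnonzero(f >= threshold)
    if passing.size == 0:
        return TitrationEndpoint(
            conc=None, threshold=threshold, censored=True, max_tested=float(e[-1])
        )
    i = int(passing[0])
    return TitrationEndpoint(
        conc=float(e[i]),
        threshold=threshold,
        max_tested=float(e[-1]),
        upper_bound_only=(i == 0),
        non_monotone=bool(np.any(f[i:] < threshold)),
    )


def _check_conditions(meta_a: dict | None, meta_b: dict | None) -> None:
    if not meta_a or not meta_b:
        return
    diff = [
        k
        for k in _MATCH_KEYS
        if k in meta_a and k in meta_b and meta_a[k] != meta_b[k]
    ]
    if diff:
        raise ComparisonError(
            "activities measured under different conditions; differing fields: "
            + ", ".join(f"{k} ({meta_a[k]!r} vs {meta_b[k]!r})" for k in diff)
        )


def compare_activity(
    a: ApparentRate | RateLowerBound | TitrationEndpoint,
    b: ApparentRate | RateLowerBound | TitrationEndpoint,
    conditions_a: dict | None = None,
    conditions_b: dict | None = None,
) -> ActivityComparison:
    """Fold difference in activity between two matched measurements.

    Both inputs must be the same kind: apparent rates (higher = faster) or
    titration endpoints (lower minimal concentration = more active; the
    ratio is inverted accordingly). Conditions, when supplied, must agree
    on substrate, temperature, S0 and NaCl. Censored inputs (a rate lower
    bound, or a censored/upper-bound-only endpoint) yield a qualitative
    ">="-style comparison flagged with ``is_bound``.
    """
    _check_conditions(conditions_a, conditions_b)

    rate_like = (ApparentRate, RateLowerBound)
    if isinstance(a, rate_like) and isinstance(b, rate_like):
        bound = isinstance(a, RateLowerBound) or isinstance(b, RateLowerBound)
        ka = a.min_k_app if isinstance(a, RateLowerBound) else a.k_app
        kb = b.min_k_app if isinstance(b, RateLowerBound) else b.k_app
        if ka == kb:
            return ActivityComparison(1.0, "tie", bound)
        if ka == 0 or kb == 0:
            return ActivityComparison(math.inf, "a" if ka > kb else "b", bound)
        fold = ka / kb if ka > kb else kb / ka
        return ActivityComparison(fold, "a" if ka > kb else "b", bound)

    if isinstance(a, TitrationEndpoint) and isinstance(b, TitrationEndpoint):
        bound = a.censored or b.censored or a.upper_bound_only or b.upper_bound_only
        ca = a.max_tested if a.censored else a.conc
        cb = b.max_tested if b.censored else b.conc
        if ca == cb:
            return ActivityComparison(1.0, "tie", bound)
        # lower concentration = more active
        if ca == 0 or cb == 0:
            return ActivityComparison(math.inf, "a" if ca < cb else "b", bound)
        fold = cb / ca if ca < cb else ca / cb
        return ActivityComparison(fold, "a" if ca < cb else "b", bound)

    raise ComparisonError(
        f"cannot compare a {type(a).__name__} with a {type(b).__name__}; "
        "both inputs must be rates or both titration endpoints"
    )


def overdigestion_fold(
    E_used: float, E_min: float | TitrationEndpoint
) -> OverdigestionFold:
    """Factor by which the applied protease exceeds the minimal sufficient
    concentration under matched conditions, E_used/E_min.

    When E_min is known only as an upper bound ("< c", from a titration
    whose lowest lane already cleaved completely), the fold is reported as
    a lower bound E_used/c.
    """
    if not math.isfinite(E_used) or E_used <= 0:
        raise DomainError(f"E_used must be > 0 uM, got {E_used!r}")
    if isinstance(E_min, TitrationEndpoint):
        if E_min.censored:
            raise DataError(
                "minimal concentration exceeds the tested range; the "
                "over-digestion fold is undefined (E_used may not digest at all)"
            )
        return OverdigestionFold(
            fold=E_used / E_min.conc, is_lower_bound=E_min.upper_bound_only
        )
    if not math.isfinite(E_min) or E_min <= 0:
        raise DomainError(f"E_min must be > 0 uM, got {E_min!r}")
    return OverdigestionFold(fold=E_used / E_min)
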