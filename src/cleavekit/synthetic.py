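"""Seeded generators emulating the four wet-lab assay outputs.

Every generator is a pure function of its parameters and a seed, so the
whole analysis pipeline is testable end-to-end without experimental data:
noiseless generation followed by the matching estimator recovers the
planted truth, and noisy generation exercises the estimators at realistic
densitometry variability.

The noise model mimics Coomassie gel quantification: band intensities get
multiplicative log-normal noise (default CV 0.10, a typical densitometry
repeatability) plus an optional additive baseline; noisy *fractions* are
then read back from the perturbed bands exactly the way a calibrated gel
is read, which keeps them in [0, 1] by construction. A direct additive
Gaussian on fractions (``fraction_sigma``) is available for controlled
estimator benchmarks.

Seeding: one global seed governs independent per-generator streams via
``numpy.random.SeedSequence(seed, spawn_key=(stream_id,))`` with a fixed
stream id per generator, so adding new generators never reshuffles the
streams of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .densitometry import StandardPoint
from .errors import DomainError
from .estimate import TimeCourse, TitrationSeries
from .crossreact import CrossReactivityGrid
from .kinetics import KineticParameters, fraction_cleaved, kapp_from_params
from .simulate import simulate_ode

__all__ = [
    "NoiseModel",
    "gen_timecourse",
    "gen_titration",
    "gen_crossreact",
    "gen_standards",
]

# fixed stream ids: appending new generators must not reshuffle these
_STREAM_TIMECOURSE = 0
_STREAM_TITRATION = 1
_STREAM_CROSSREACT = 2
_STREAM_STANDARDS = 3


@dataclass(frozen=True)
class NoiseModel:
    """Densitometry noise description.

    intensity_cv : coefficient of variation of the multiplicative
        log-normal band noise (0 disables it).
    baseline : additive intensity offset applied to each band.
    fraction_sigma : optional additive Gaussian noise applied directly to
        fractions (clipped to [0,1]); when set it takes precedence over the
        band-noise path for fraction outputs.
    """

    intensity_cv: float = 0.10
    baseline: float = 0.0
    fraction_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.baseline < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.fraction_sigma is not None and self.fraction_sigma < 0:
            raise DomainError("fraction_sigma must be >= 0")

    @property
    def sigma_ln(self) -> float:
        """Log-scale sigma giving the requested CV for log-normal noise."""
        return math.sqrt(math.log1p(self.intensity_cv**2))


NOISELESS = NoiseModel(intensity_cv=0.0, baseline=0.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _bands_from_fraction(
    f: np.ndarray, response_factor: float, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal band intensities of lanes at cleaved fractions ``f``.

    The uncut band carries (1-f) of the molar amount; the ccp band carries
    f, weighted by its relative per-mole staining (response factor)."""
    fl = scale * (1.0 - f)
    ccp = scale * response_factor * f
    return fl, ccp


def _noise_bands(
    fl: np.ndarray, ccp: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if noise.intensity_cv > 0:
        fl = fl * np.exp(rng.normal(0.0, noise.sigma_ln, fl.shape))
        ccp = ccp * np.exp(rng.normal(0.0, noise.sigma_ln, ccp.shape))
    return fl + noise.baseline, ccp + noise.baseline


def _noisy_fractions(
    f_true: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    response_factor: float = 1.0,
    scale: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perturb fractions through the chosen noise path.

    Returns (fractions, fl, ccp); the bands are the (possibly noised)
    intensities the fractions were read from.
    """
    fl, ccp = _bands_from_fraction(f_true, response_factor, scale)
    fl_n, ccp_n = _noise_bands(fl, ccp, noise, rng)
    if noise.fraction_sigma is not None and noise.fraction_sigma > 0:
        f = np.clip(f_true + rng.normal(0.0, noise.fraction_sigma, f_true.shape), 0, 1)
    elif noise.intensity_cv > 0 or noise.baseline > 0:
        # read the gel back with the true response factor (calibrated read)
        denom = ccp_n + response_factor * fl_n
        f = np.where(denom > 0, ccp_n / denom, f_true)
        f = np.clip(f, 0.0, 1.0)
    else:
        f = f_true.copy()
    return f, fl_n, ccp_n


def gen_timecourse(
    params: KineticParameters,
    times,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    with_intensities: bool = False,
    response_factor: float = 1.0,
    metadata: dict | None = None,
) -> TimeCourse:
    """Synthetic cleavage time course from the full product-inhibited model.

    Noiseless output equals :func:`~cleavekit.simulate.simulate_ode`
    exactly (and hence the single exponential when K_P = K_M). With
    ``with_intensities=True`` the metadata carries the raw band intensity
    arrays under keys ``intensity_fl`` / ``intensity_ccp``.
    """
    t = np.asarray(times, dtype=float)
    course = simulate_ode(params, t)
    f_true = course.fraction_cleaved
    rng = _rng(seed, _STREAM_TIMECOURSE)
    f, fl, ccp = _noisy_fractions(f_true, noise, rng, response_factor)
    meta = dict(metadata or {})
    meta.setdefault("s0_uM", params.S0)
    if with_intensities:
        meta["intensity_fl"] = fl
        meta["intensity_ccp"] = ccp
    return TimeCourse(t, f, meta)


def gen_titration(
    kcat: float,
    K_M: float,
    S0: float,
    enzyme_concs,
    time: float,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    metadata: dict | None = None,
) -> TitrationSeries:
    """Synthetic endpoint titration: fraction cleaved vs enzyme concentration.

    Each concentration's fraction follows the single-exponential model with
    k_app = kcat*E0/(K_M + S0) at the fixed incubation time; noiseless
    fractions are strictly increasing in E0 (and 0 at E0 = 0).
    """
    e = np.asarray(enzyme_concs, dtype=float)
    f_true = np.array(
        [
            fraction_cleaved(
                kapp_from_params(
                    KineticParameters(kcat=kcat, K_M=K_M, K_P=K_M, E0=e0, S0=S0)
                ),
                time,
            )
            for e0 in e
        ]
    )
    rng = _rng(seed, _STREAM_TITRATION)
    f, _, _ = _noisy_fractions(f_true, noise, rng)
    meta = dict(metadata or {})
    meta.setdefault("s0_uM", S0)
    meta.setdefault("time_min", time)
    return TitrationSeries(e, f, meta)


def gen_crossreact(
    specificity: pd.DataFrame,
    kapp_cognate: float,
    time: float,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    cognate: dict | None = None,
    conditions: dict | None = None,
) -> CrossReactivityGrid:
    """Synthetic cross-reactivity grid from a planted specificity matrix.

    ``specificity`` is a proteases x substrates DataFrame of relative
    activities (1 = cognate-level, 0 = no cleavage); each cell's fraction is
    1 - exp(-kapp_cognate * activity * time). Zero activity gives fraction 0
    before noise, so sub-threshold noise cannot invent cleavage of a truly
    untouched substrate when the baseline is 0. ``cognate`` maps substrate ->
    protease; by default substrate j is cognate to protease j (by position).
    """
    act = specificity.to_numpy(dtype=float)
    if np.any(act < 0):
        raise DomainError("specificity activities must be >= 0")
    if kapp_cognate < 0 or time < 0:
        raise DomainError("kapp_cognate and time must be >= 0")
    f_true = -np.expm1(-kapp_cognate * act * time)
    rng = _rng(seed, _STREAM_CROSSREACT)
    f, _, _ = _noisy_fractions(f_true, noise, rng)
    proteases = tuple(str(p) for p in specificity.index)
    substrates = tuple(str(s) for s in specificity.columns)
    if cognate is None:
        cognate = {s: p for p, s in zip(proteases, substrates)}
    return CrossReactivityGrid(
        proteases, substrates, f, cognate, dict(conditions or {"time_min": time})
    )


def gen_standards(
    ladder=None,
    response_factor: float = 1.0,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    scale: float = 1000.0,
) -> list[StandardPoint]:
    """Synthetic cleavage-standard lanes at the given mixing ladder.

    Intensities are proportional to the molar amounts of uncut and cleaved
    material times the planted per-mole response factor, then perturbed by
    the noise model. Default ladder: {0, 0.10, 0.25, 0.50, 0.75, 0.90, 1.0}.
    """
    from .densitometry import DEFAULT_LADDER

    f = np.asarray(DEFAULT_LADDER if ladder is None else ladder, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise DomainError("ladder fractions must lie in [0,1]")
    if response_factor <= 0:
        raise DomainError("response_factor must be > 0")
    fl, ccp = _bands_from_fraction(f, response_factor, scale)
    rng = _rng(seed, _STREAM_STANDARDS)
    fl_n, ccp_n = _noise_bands(fl, ccp, noise, rng)
    return [
        StandardPoint(known_fraction=float(fi), intensity_fl=float(a),
                      intensity_ccp=float(b))
        for fi, a, b in zip(f, fl_n, ccp_n)
    ]
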