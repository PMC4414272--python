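# cleavekit

Quantitative analysis of protease tag-removal assays built around
ubiquitin-like-protein (UBL) recognition modules — Atg8-family fusions
(LC3B, GATE16, Atg8) cleaved by Atg4-family proteases, alongside SUMO-,
NEDD8- and TEV-based systems. `cleavekit` is for protein biochemists who
quantify cleavage gels and need defensible numbers out of them: apparent
cleavage rates from time courses, minimal sufficient protease
concentrations from titrations, calibrated fraction-cleaved values from
band densitometry, and orthogonality calls from protease × substrate
cross-digestion grids.

## The model

A cleavage reaction S → P + P′ releases the UBL module P, which rebinds
the protease and competes with intact substrate. Extending the
Michaelis–Menten rate law with competitive product inhibition:

    v = −d[S]/dt = kcat·[E0]·[S] / ( K_M·(1 + [P]/K_P + [S]/K_M) )

where [E0] is total enzyme, K_M the Michaelis constant and K_P the
product-inhibition constant. Substrate and product present the protease
with an essentially identical interaction surface, so K_P ≈ K_M is a
natural assumption; with [P] = [S0] − [S] the rate law then collapses to
first order,

    v = k_app·[S],      k_app = kcat·[E0] / (K_M + [S0])

and the cleaved fraction follows a single exponential,

    f(t) = 1 − exp(−k_app·t).

A single unsaturated gel lane (fraction f at time t) therefore fixes the
apparent rate, k_app = −ln(1−f)/t, and multi-point courses can be fitted
by nonlinear least squares. The package also integrates the full ODE
numerically and quantifies how far the single exponential drifts when
K_P ≠ K_M: weaker product binding (K_P > K_M) makes cleavage run ahead of
the exponential, tighter binding makes it lag.

Units everywhere: concentrations in µM, time in minutes, rates in min⁻¹.

## What's in the box

- `kinetics` — the rate laws and closed-form progress model as pure functions
- `simulate` — tight-tolerance ODE integration and the K_P/K_M
  approximation-error sweep
- `estimate` — `kapp_single_point`, the `ProgressCurveModel`/`ProgressCurveResults`
  fit pair, fold-excess, minimal-complete-concentration, matched-condition
  activity comparisons, over-digestion folds
- `densitometry` — cleavage-standard calibration (`CleavageStandardModel` →
  `StandardCurve`) and band-pair → fraction conversion
- `crossreact` — the ++/+/−/−− four-level cleavage key and maximal
  mutually-orthogonal protease/substrate sets
- `synthetic` — seeded generators emulating all four assay outputs
- `io` / `cli` — CSV dialects with provenance headers and a `cleavekit`
  executable (`simulate | fit | titrate | calibrate | crossreact | synth`)

## Worked example

An on-column cleavage where 50% of the target is released after 15 min:

```python
>>> from cleavekit import kapp_single_point, fraction_cleaved
>>> rate = kapp_single_point(0.50, 15.0)
>>> rate.k_app
0.046209812037329684
>>> fraction_cleaved(rate, 30.0)
0.75
```

The rate 0.0462 min⁻¹ is a 15-minute half-time; the same exponential
predicts exactly 75% release at 30 min (two half-lives). A faster fusion
released to 80% at 15 min predicts 96% at 30 min.

Fitting a noisy multi-point course, statsmodels-style:

```python
>>> import numpy as np
>>> from cleavekit import TimeCourse, ProgressCurveModel
>>> tc = TimeCourse([15.0, 30.0], [0.5, 0.75], {"substrate": "xLC3B"})
>>> print(ProgressCurveModel(tc).fit().summary())
Single-exponential progress-curve fit
=============================================
model:            f(t) = 1 - exp(-k*t)
n points used:    2
k_app (1/min):    0.0462098
std err:          0
half-time (min):  15
RMS residual:     0
conditions:       substrate=xLC3B
```

And assay arithmetic: 100 µM substrate fully processed by 1 nM protease
means each enzyme molecule turned over `fold_excess(100, 0.001)` =
100000 substrate molecules.

From the shell, a full synthetic round trip:

    cleavekit --seed 7 synth --outdir assays
    cleavekit fit assays/timecourse.csv
    cleavekit titrate assays/titration.csv
    cleavekit calibrate assays/standards.csv
    cleavekit crossreact assays/grid.csv

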