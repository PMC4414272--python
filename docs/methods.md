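# Methods

## Model

One cleavage reaction S → P + P′ is described by a Michaelis–Menten rate
law extended with competitive product inhibition by the released UBL
module P:

    v = −dS/dt = kcat·E0·S / ( K_M·(1 + P/K_P + S/K_M) )

Assumptions, and what they buy:

- **Only P inhibits.** The second fragment P′ (the freed target protein)
  is produced 1:1 with P but does not rebind the protease; it is not
  tracked as state. Mass conservation is S + P = S0.
- **Total enzyme in the rate law.** E0 is the total enzyme concentration;
  depletion of free enzyme by tight product binding is not modelled. This
  keeps the ODE one-dimensional and matches how such assays are analysed
  in practice.
- **Equal affinities, K_P = K_M.** Substrate and product share a large,
  essentially identical protease-interaction surface, so their affinities
  are taken as equal. Substituting P = S0 − S then collapses the rate law
  to first order with

      k_app = kcat·E0 / (K_M + S0),

  and the cleaved fraction is the single exponential f(t) = 1 − e^(−k_app·t).
  The remaining-substrate fraction is e^(−k_app·t); the package reports the
  *cleaved* fraction throughout because that is what gel quantification
  measures ("completeness of cleavage").

None of kcat, K_M, K_P has a literature value for these proteases; all
three are free simulation parameters. Estimation therefore targets k_app
only — kcat, K_M and K_P are not separately identifiable from
fraction-only progress data at a single S0, and no estimator here
pretends otherwise.

## When the exponential holds

With K_P = K_M the exponential is exact (the equivalence is verified
numerically against the ODE to < 1e−6 absolute fraction over a wide
parameter lattice). For K_P ≠ K_M the deviation is one-signed: weaker
product binding (K_P > K_M) accelerates cleavage relative to the
exponential, tighter binding retards it, so sign(f_ode − f_closed) =
sign(K_P − K_M) at all interior times. `simulate.sweep_kp_ratio`
characterises the magnitude; there is no printed reference value for this
regime, so the sweep is descriptive, not a reproduction.

## Numerical choices

- Integrator: LSODA via `scipy.integrate.solve_ivp`, rel_tol 1e−8,
  abs_tol 1e−10 µM. The problem is a cheap scalar ODE; tight tolerances
  make the closed-form equivalence test meaningful rather than
  tautological. The state is clamped to [0, S0] inside the RHS and the
  output is forced non-increasing to remove tolerance-level jitter.
- Output grid: t = 0 plus 60 log-spaced points over the horizon
  (early-time resolution where the curvature lives).
- Progress-curve fit: `scipy.optimize.curve_fit` on f(t) = 1 − e^(−k·t)
  with k ≥ 0, started from the single-point inversion at the point
  nearest f = 0.5. No intercept and no free amplitude: nothing is cleaved
  at t = 0 and the reaction runs to completion. The reported standard
  error is the asymptotic (Jacobian-based) one.
- Saturated points: a lane within 1% of complete (f ≥ 0.99) carries no
  rate information. Such points are excluded from fits when ≥ 2
  unsaturated points remain, otherwise right-censored at f = 0.99; a
  course that is entirely saturated raises an unidentifiability error,
  and a single saturated observation inverts to a rate *lower bound*
  k_app ≥ −ln(0.01)/t rather than a number.
- Standard-curve fit: the response factor r is fitted on a log scale
  (positivity by construction) by least squares of
  predicted = ccp/(ccp + r·fl) against the known mixing fractions. Pure
  lanes (f = 0 or 1) pin the endpoints but are uninformative about r.

## Defaults and thresholds

| quantity | default | rationale |
|---|---|---|
| near-complete cleavage threshold | 0.95 | cleavage-standard gels resolve ~5% increments; "near complete" is never defined numerically in assay reports |
| category key ++ / + / − / −− | ≥ 0.90 / ≥ 0.10 / ≥ 0.01 / < 0.01 | matches the four-level gel key; ~1% is the band detection limit |
| orthogonality strictness | −− at maximum tested concentration | a pair is called orthogonal only when heavy over-digestion (hundreds- to tens-of-thousands-fold) shows *no* detectable cleavage; "−" tolerance is available but not default |
| densitometry response factor | fitted; mass ratio ccp/fl when no standards exist | Coomassie staining scales roughly with chain mass |
| standard mixing ladder | {0, 0.10, 0.25, 0.50, 0.75, 0.90, 1.0} | brackets the calls a titration gel must make ("near complete", "≈50%") plus the pure endpoints |
| noise model | log-normal band noise, CV 0.10, baseline 0 | typical Coomassie densitometry repeatability; assay reports carry no error bars to fit |

Units are fixed package-wide (µM, minutes, min⁻¹); converters belong at
the I/O boundary. Non-monotone titrations return the smallest passing
concentration but carry a warning flag when any higher concentration
fails — preserving the "lowest fully cut lane" reading while surfacing
the inconsistency.

## Synthetic data: what it emulates, what it does not

The generators emulate the four assay outputs the pipeline consumes:
progress time courses (full ODE, so product-inhibition curvature is
present when K_P ≠ K_M), endpoint titrations (single-exponential fraction
at fixed time per enzyme concentration), cleavage-standard lanes
(intensities proportional to molar amounts × per-mole response factor)
and cross-reactivity grids (k_app scaled by a planted relative-activity
matrix). Noisy fractions are produced by perturbing the *bands* and
reading the gel back with the true response factor, which keeps fractions
in [0, 1] by construction; a direct additive Gaussian on fractions
(`fraction_sigma`) exists for controlled estimator benchmarks.

Deliberately not emulated: gel images and lane-finding (intensities are
assumed extracted), loading/transfer artefacts correlated across lanes,
partial or mis-site cleavage products, enzyme inactivation over long
incubations, and temperature/salt dependence of the constants (assays at
different temperatures are represented only through different k_app
values and metadata). Passing tests therefore demonstrate correctness of
the estimators *given* the single-exponential/product-inhibition model
and uncorrelated densitometry noise — not robustness to every failure
mode of real gels.

Seeding: a single global seed drives independent per-generator streams
via `SeedSequence(seed, spawn_key=(stream_id,))` with fixed stream ids,
so adding generators never reshuffles existing streams; every generator
is a pure function of (parameters, seed).

## Problem sizes

The verification suite uses sizes chosen to make the statistical checks
sharp while keeping the whole suite fast: a 5×5×5 (kcat, K_M, S0) lattice
× 61 time points for the ODE/closed-form equivalence; 200 seeded 8-point
courses at σ = 0.02 for rate-recovery calibration (median relative error,
bias, ±3 SE coverage); 500 noisy lanes across the default ladder for the
densitometry round trip; 100 seeds for the titration-endpoint round trip;
10 randomized planted grids for orthogonality recovery.

## Design choices that were genuinely open

- **Cleaved vs remaining fraction as the public quantity.** The two
  closed forms are complements; the cleaved fraction was chosen because
  every quantification step (gels, standards, titrations) is phrased as
  completeness of cleavage.
- **One-parameter densitometry model.** A single scalar response factor
  relating the two bands' per-mole staining captures what a mixed
  standard can calibrate; lane-specific loading cancels in the ratio.
  N-terminal fragment bands are not modelled.
- **Comparisons require matched conditions.** `compare_activity` refuses
  to compare measurements differing in substrate, temperature, S0 or
  NaCl — the axes these assays actually vary — and propagates censoring
  as qualitative "≥" bounds instead of fabricating folds.
- **Model/Results surface.** The two data fits (progress curve, standard
  curve) follow the statsmodels Model → fit() → Results convention with
  `summary()`, `predict()` and plotting on the results; everything else
  is pure functions over small frozen dataclasses.

## Known limitations

- k_app conflates kcat, E0, K_M and S0; comparisons across different S0
  or E0 are only meaningful through the explicit fold operations.
- The asymptotic standard error of a 1-parameter exponential fit is
  anti-conservative for very few points; with exactly two points it is 0.
- Orthogonality calls are threshold classifications of endpoint
  fractions; graded specificity (a near-cognate pair cleaved only at
  ~100-fold higher enzyme) is representable in the grid but collapses to
  its category at the tested concentration.
- The over-digestion fold for a titration that never reached completion
  is undefined and raised as an error rather than guessed.
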