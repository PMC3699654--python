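# Methods

## Physical model

A particle of mass m and volume V immersed in a fluid of density ρ_f has
buoyant mass m_b = m − V·ρ_f.  We decompose a cell into dry material
(mass m_dry, density ρ_dry) and exchangeable water (volume V_w, density
ρ_w):

    m_b = m_dry·(1 − ρ_f/ρ_dry) + V_w·(ρ_w,eff − ρ_f).

ρ_w,eff interpolates linearly between the water's native density and the
density it assumes once equilibrated with the immersion fluid, controlled
by a *residual H₂O fraction* in [0, 1] (1 = no exchange; impermeable
fluids force 1).  All quantities are carried in fg, fL and g·cm⁻³, a
mutually consistent unit system (1 fg/fL = 1 g·cm⁻³).

Three inversion modes, all closed-form:

- **Dry** (two permeable fluids, water assumed fully exchanged and
  neutrally buoyant): m_dry = (m_b1·ρ₂ − m_b2·ρ₁)/(ρ₂ − ρ₁),
  V_dry = (m_b1 − m_b2)/(ρ₂ − ρ₁), ρ_dry = m_dry/V_dry.  Dry density
  depends only on the ratio m_b1/m_b2 — equivalently the angle of the
  measurement point in the (m_b1, m_b2) plane — so it is invariant under
  common rescaling of both buoyant masses.
- **Water** (impermeable fluid density-matched to a D₂O-based fluid,
  default tolerance 0.001 g·cm⁻³): the dry term cancels in the
  difference, leaving m_b1 − m_b2 = V_w·(ρ_w − ρ_f).
- **Total** (two impermeable fluids): the same two-fluid algebra applied
  to the whole cell.

Cells whose inferred dry volume is ≤ 0 (possible for small cells under
noise) are reported with `valid=False` rather than dropped: silent
filtering would bias population medians, and explicit flags keep the
exclusion auditable.

### Constants

ρ(H₂O) = 0.9975 and ρ(D₂O) = 1.1040 g·cm⁻³ at the 22–23 °C operating
temperature; the 9:1 v/v D₂O:H₂O measurement fluid is assigned
0.9·1.1040 + 0.1·0.9975 = 1.09335 g·cm⁻³ by ideal volume mixing.  The
isotonic measurement fluids (1× PBS bases) have densities 1.005 and
1.101 g·cm⁻³.  All of these are overridable — `FluidSpec` is a plain
value object and fluid tables are ordinary CSV.

## Error model and propagation

Single-measurement error is estimated from ~100 cells each weighed twice
in the same fluid: the paired differences are differences of two
independent errors, so dividing them by √2 gives an empirical sample of
the single-measurement error distribution (its SD is the error scale).
Resampling is bootstrap-with-replacement from these samples by default; a
parametric N(0, scale) mode is provided since the choice between the two
is a protocol detail, not a modelling commitment.

Dry mass is linear in the two buoyant masses, so its standard error is
analytic: √(ρ₁² + ρ₂²)/|ρ₂ − ρ₁| times the single-measurement error —
15.5 for the (1.005, 1.101) pair.  The factor is large because the
inversion differences two nearly equal fluid densities; it is verified in
the tests and the acceptance script by Monte-Carlo propagation of
unit-variance errors, which must agree within 2%.

Dry *density* is a ratio of two correlated noisy quantities, so its
noise-only distribution is simulated (≥10 000 draws): every particle gets
the median observed dry density, a mass bootstrapped from the observed
dry-mass list (optional KDE smoothing behind a flag), forward-modelled
buoyant masses, independent error draws per fluid, and re-inversion.  The
empirical 0.5%/99.5% quantiles of the simulated densities are the 99%
bounds; comparison to observed distributions is reported as an exceedance
fraction and a Q–Q table, deliberately without a hypothesis-test verdict
— the comparison is diagnostic, not decisional.  The RNG call order
inside the simulator is frozen (mass indices, optional jitter, errors for
fluid 1, errors for fluid 2) so seeded runs are exactly reproducible.

## Systematic biases

**Isotonic fluids.**  Osmotically safe measurement fluids are denser than
the pure fluids their bases imply, while intracellular water equilibrates
to the pure-fluid densities, so the water term is not exactly zero.  The
bias module forward-models this violation and inverts with the
neutral-water assumption.  For equal density departures δ in both fluids
the volume bias cancels exactly and the density bias is exactly
−δ·(V_w/V_dry); for the actual PBS departures (+0.0075, +0.00765) and a
cell 80% water by volume the bias is −0.032 g·cm⁻³, under the 0.04
bound expected for such cells.  `bias_map` evaluates the bias over a
water-fraction × departure grid.

**Incomplete exchange.**  Residual intracellular H₂O in the D₂O fluid
depresses early-exposure density estimates.  The diagnostic is an OLS
regression of per-cell dry density on exposure time with a one-sided
t-test.  The alternative is slope > 0: retained H₂O is lighter than the
D₂O fluid, so the water term is negative early and decays away — density
estimates rise toward truth with exposure.  Batches of analyses use
Bonferroni correction, α = 0.05/n_tests (n_tests = 9 reproduces the
α = 0.006 convention of a nine-analysis batch); the denominator is always
recorded in the result.  A Huber-weighted robust variant was considered
and left out: OLS is the reported analysis and the robust fit adds a
tuning constant without changing any decision on the synthetic suites.

## Population statistics

- KDEs use a Gaussian kernel with Scott's rule by default (the rule is
  recorded in the output); curves are rescaled to unit maximum for
  cross-population shape comparison.  The grid pads the data range by
  four bandwidths so the un-rescaled curve integrates to ~1.
- Median uncertainties are seeded bootstrap standard errors (1000
  resamples by default) — the package's uniform interpretation of the
  "median ± x" convention.
- Mann–Whitney U is two-sided; exact null enumeration when both groups
  have n ≤ 8 without cross-group ties, tie-corrected normal approximation
  otherwise.
- Between-instrument comparisons use the closed-form Deming estimator;
  `variance_ratio` is var(y-error)/var(x-error), 1.0 (orthogonal
  regression) by default since the error split between instruments is
  rarely known.
- Growth curves are fit to K/(1 + exp(−r(t − t₀))) by nonlinear least
  squares with data-driven starts (K from max OD, t₀ from half-max, r
  from the steepest slope via r = 4·max-slope/K).  Non-convergence raises
  with the starting values in the message; a converged negative rate is
  returned for the caller to flag.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
lognormal dry masses (positive, right-skewed) specified by median and CV;
normal dry density and water fraction with mean/CV (CV 0 = homogeneous),
redrawn into their valid ranges; exposure times uniform on [1, 30] s
(measurements a few seconds apart); independent Gaussian buoyant-mass
noise per record; and optional incomplete exchange with residual fraction
exp(−t/τ).  Truth tables carry the exact noiseless forward-model buoyant
masses, so conservation (total = dry + water mass) and forward-model
consistency are testable per cell.  Identical seeds give byte-identical
tables.

Preset scenarios (n = 1000 cells each, a realistic single-session yield
that keeps the full suite fast):

| preset | median dry mass | dry density | water fraction | noise |
|---|---|---|---|---|
| `ecoli_stationary_fixed` | 203 fg | 1.40 | 0.78 | 0.5 fg |
| `ecoli_exponential` | 725 fg | 1.41 | 0.78 | 0.5 fg |
| `erythrocyte` | 30 000 fg | 1.39 | 0.65 | 10 fg |

The stationary-phase water fraction 0.78 makes the median water mass
~516 fg given 203 fg dry mass at 1.40 g·cm⁻³; the exponential preset's
slightly higher density reflects the raised RNA/protein ratio of fast
growth; the erythrocyte noise scale reproduces a noise-only dry-density
SD of ~0.002 g·cm⁻³, the narrow-distribution, high-signal regime.  Dry
mass CVs (0.35 bacterial, 0.12 erythrocyte) are chosen as typical
right-skewed single-cell spreads; true dry-density CVs are genuinely
unknown (for bacteria the observed spread is mostly noise), so presets
default to 0 and expose the CV as a free parameter rather than asserting
a biological value.

Preset fluids carry the PBS densities but set the intracellular-water
density equal to the fluid density — the neutral-water idealization the
inversion assumes.  This keeps the generator's parameter-recovery
contract exact (pipeline median dry density inside the noise-only 99%
bounds of the configured truth) and separates concerns: the known,
deterministic isotonic-fluid bias is the `bias` module's subject, where
it is modelled with the physically accurate fluid specs from
`standard_fluids()`.  Consequently, passing recovery tests demonstrate
correctness of the inversion and noise machinery, not absence of the
isotonic bias — on real PBS data the dry-density medians carry the
−0.01 to −0.03 g·cm⁻³ offset quantified by `bias_map`.  Other features of
real data the generator does not emulate: flow-path-dependent sensitivity
(a hardware concern), fluid-switch transients, osmotic volume changes
between fluids, deuterium incorporation into dry matter, and cell-cycle
structure.

## Numerical choices

- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `MatchedDensityError`, `SchemaError`); equal buoyant masses in a
  distinct-density pair yield zero volume, NaN density and
  `valid=False` instead of raising, since they are a data outcome, not a
  configuration error.
- Water-content mode requires the two fluid densities to match within a
  configurable 0.001 g·cm⁻³ (fluids are matched by hand in practice;
  the tolerance makes the requirement explicit and testable).
- Every stochastic operation takes an explicit integer seed; CLI runs
  record seeds, config snapshots and file digests in a JSON manifest.
- The null simulator's 99% bounds use empirical quantiles; with a
  zero-scale error model they collapse and are widened by 1e-12 so the
  open-interval invariant (lo < median < hi) survives the degenerate
  case.

## Limitations

- The water-content and total-mass modes are exposed per cell, but the
  "percent dry by volume" of a population combines medians from separate
  cell cohorts; the package provides the arithmetic
  (`percent_dry`) and leaves cohort pairing to the analyst.
- The exposure-time diagnostic has power only when exposure times vary;
  single-exposure protocols cannot distinguish incomplete exchange from
  a density offset.
- Calibration is a linear response model by design; curvature in the
  frequency response is out of scope.
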