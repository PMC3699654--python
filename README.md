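# smrdry

Dual-fluid buoyant-mass analysis of single cells: dry mass, dry density and
water content from suspended-microchannel-resonator (SMR) measurements.

## The problem

An SMR weighs a single cell as it transits a vibrating microchannel,
returning its *buoyant mass*

```
m_b = m − V·ρ_f
```

— the cell's mass minus the mass of fluid it displaces.  One such
measurement cannot separate mass from volume, but a cell weighed
sequentially in two fluids of different density can be solved for both.
The trick exploited here is the high water permeability of cell membranes:
when the second fluid is D₂O-based, intracellular H₂O exchanges for D₂O
within seconds, making the cell's water content neutrally buoyant in both
weighings.  Decomposing the buoyant mass into dry and aqueous terms,

```
m_b = m_dry·(1 − ρ_f/ρ_dry) + V_w·(ρ_w − ρ_f),
```

the water term vanishes in both fluids and the pair (m_b1, m_b2) at fluid
densities (ρ₁, ρ₂) yields closed-form single-cell estimates

```
m_dry = (m_b1·ρ₂ − m_b2·ρ₁)/(ρ₂ − ρ₁),    V_dry = (m_b1 − m_b2)/(ρ₂ − ρ₁),
ρ_dry = m_dry / V_dry.
```

Dry density — the abundance-weighted mean density of the cell's
biomolecules — is a label-free index of chemical composition (RNA is
denser than protein, which is denser than lipid), independent of the
cell's water content and size.  Pairing a dense *impermeable* fluid with a
density-matched D₂O fluid instead isolates the water mass, and two
impermeable fluids recover total mass, volume and density.

The package is for experimentalists and analysts working with SMR (or
similar single-cell weighing) data.  It provides:

- the forward model and all three closed-form inversions, with explicit
  validity flags instead of silent filtering (`smrdry.inversion`);
- bead/NaCl linear instrument calibration (`smrdry.calibration`);
- measurement-error estimation from repeat weighings (the √2-rescaled
  paired-difference trick), the analytic ~15× dry-mass error
  amplification, and the Monte-Carlo noise-only dry-density null
  distribution with 99% bounds (`smrdry.noise`);
- systematic-bias analysis: isotonic-fluid departures from pure H₂O/D₂O
  and the exposure-time regression test for incomplete water exchange
  (`smrdry.bias`);
- population statistics: maximum-rescaled KDEs, bootstrap median SEs,
  Mann–Whitney U, Deming (total least squares) regression, logistic
  growth fits (`smrdry.popstats`);
- a synthetic-data generator with scenario presets so the whole pipeline
  is testable without instrument data (`smrdry.simulate`);
- CSV readers/writers with validated schemas, a `smrdry` CLI, and a
  statsmodels-style `DryCompositionModel` → `DryCompositionResults`
  surface tying everything together.

## Worked example

Simulate a fixed stationary-phase *E. coli*-like population (median dry
mass 203 fg, dry density 1.40 g·cm⁻³, 78% water by volume, 0.5 fg
measurement noise), estimate the error model from 100 repeat pairs, and
fit:

```python
from smrdry import (DryCompositionModel, estimate_error_model,
                    generate_noise_calibration_pairs, generate_population,
                    scenario_presets, simulate_measurements)

cfg = scenario_presets()["ecoli_stationary_fixed"]
truth = generate_population(cfg)
records = simulate_measurements(truth, cfg)
repeats = generate_noise_calibration_pairs(truth, cfg.noise_scale, seed=cfg.seed + 2)
error = estimate_error_model(repeats[["mb_a_fg", "mb_b_fg"]].to_numpy())

model = DryCompositionModel.from_records(
    records, {f.label: f for f in (cfg.fluid1, cfg.fluid2)},
    "pbs_h2o", "pbs_d2o", error_model=error)
print(model.fit(seed=0).summary())
```

```
Dry composition from paired buoyant-mass measurements
========================================================
fluids: pbs_h2o (rho=1.0050) / pbs_d2o (rho=1.1010) g/cm^3
cells: 1000 measured, 1000 valid
median dry mass:        197.07 +/- 2.47 fg
median dry volume:      141.13 +/- 1.69 fL
median dry density:     1.4008 +/- 0.0007 g/cm^3
dry-mass error amplification: 15.5x single-measurement error
noise-only 99% density bounds: [1.3476, 1.4782] g/cm^3 (n_sim=10000)
observed fraction outside bounds: 0.009
exposure-time slope: -3.394e-06 g/cm^3/s (one-sided p=0.517, not significant at alpha=0.05)
```

Reading this: the per-cell medians recover the configured truth (the
median dry mass of a 1000-cell lognormal draw sits a couple of percent
from the distribution median); the 15.5× factor says a 0.5 fg
single-measurement error becomes a ~7.8 fg dry-mass error; the wide
noise-only 99% bounds on dry density show that, at bacterial signal
levels, most of the apparent cell-to-cell density spread is measurement
noise (0.9% of observed cells fall outside, consistent with the nominal
1%); and the exposure-time regression finds no residual-exchange trend,
as expected for instantaneous exchange.

The same stages are available from the shell:

```
smrdry simulate --preset ecoli_stationary_fixed --seed 5 --out-dir run/
smrdry noise --pairs run/repeat_pairs.csv --out run/error.json
smrdry dry --measurements run/measurements.csv --fluids run/fluids.csv \
       --fluid1 pbs_h2o --fluid2 pbs_d2o --out run/dry.csv
smrdry null --dry-results run/dry.csv --error-model run/error.json \
       --fluids run/fluids.csv --fluid1 pbs_h2o --fluid2 pbs_d2o \
       --out-dir run/null/
smrdry report --results run/dry.csv --out run/summary.csv
```

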