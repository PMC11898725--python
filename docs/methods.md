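# Methods

`napacool` models the cooling of Chinese cabbage (*Brassica rapa* ssp.
*pekinensis*) in cold storage: how heads of different sizes are classified,
how much metabolic heat they release, how a single head cools through its
porous leaf matrix, how the surface heat-transfer coefficient is calibrated
from cooling curves, and how room-loading strategies rank against each
other. This note records the models, the defaults and why, and what the
synthetic data do and do not establish.

## Morphological classification

Heads are described by three traits: length circumference (cm), width
circumference (cm) and fresh weight (g). K-means (k-means++ initialization,
best of 10 restarts) clusters the z-standardized traits; standardization is
required because the traits mix centimetres and grams and unscaled
Euclidean distance would be dominated by weight. The cluster count is
chosen by the mean silhouette coefficient `(b − a)/max(a, b)` over K in
{2..5}; the SSE elbow (largest second difference of the SSE-vs-K curve) is
reported as a diagnostic only. Fitted clusters are relabelled into size
classes 1..k by ascending mean weight, so "class 1" is always the smallest
heads. Singleton clusters contribute a silhouette of 0. The silhouette is
evaluated in the same standardized space the clustering uses.

Basket allocation balances metabolic load: with equal class counts, each
basket receives one head per class, pairing the lightest class-1 heads with
the heaviest class-3 heads (classes sorted by weight, class 3 reversed).

## Respiration rate and heat

In a sealed basket the CO2 mole fraction rises linearly while respiration
is constant. The molar rate is recovered from the least-squares slope of
the CO2 trace via the ideal gas law,

    R_CO2 = P · V_chamber · (dx/dt) / (M · R_gas · T̄)   [mol CO2 / kg·h]

with `x` the mole fraction (ppm × 1e-6), `T̄` the trace-mean absolute
temperature and P the total pressure (101 325 Pa default). The printed
form of this relation in the postharvest literature often omits P and the
ppm conversion; both are required for the units to close and are included.

Heat release follows the ASHRAE empirical power law

    Q(T) = 10.7 f / 3600 · (9T/5 + 32)^g    [W/kg],  T in °C,

with cabbage coefficients f = 6.0803e-4, g = 2.6183. The `(9T/5 + 32)`
term is the Celsius-to-Fahrenheit conversion of the original correlation; a
`literal_9t` switch evaluates `(9T + 32)` instead for comparison with
sources that print the uncommon literal form. Heat and molar rate are
interconvertible through the aerobic-respiration stoichiometry of glucose,
10.7 kJ per gram of CO2 (470.9 kJ/mol CO2) — the same constant the "10.7"
prefactor encodes.

The volumetric source for a loaded basket is `q̇ = Q(T) · m / V_basket`
(bulk density times per-mass heat). Inside a single head, the source is
`Q(T) · (1 − φ) ρ_s` — the solid-fraction mass per unit volume — so that
the source term is consistent with the solid-fraction heat capacity of the
porous energy balance.

## Porous-sphere cooling model

A head is an equivalent sphere: semi-axes `a = L/2π`, `b = W/2π` from the
two circumferences, radius `R = (a b²)^{1/3}` preserving spheroid volume
(class 2: R ≈ 0.0965 m). The interior is a porous medium (measured
porosity φ = 0.31, vacuum impregnation) in local thermal equilibrium — the
energy equation lists solid and pore-vapour phases but no interphase
exchange coefficient, so a single temperature with combined capacity

    (ρc)_eff = (1 − φ) ρ_s Cp_s(T) + φ ρ_f Cp_f

is the only closed formulation. Effective conductivity uses arithmetic
(parallel) volume weighting of solid and fluid conductivities by default;
harmonic and geometric rules are available, and no dispersion term is
included. Solid k(T) (linear) and Cp(T) (quadratic) polynomials and the
class densities (601.64 / 675.70 / 754.34 kg/m³) are the measured values.
Pore fluid is water vapour with standard-table values at 4 °C (ρ = 0.0068
kg/m³, μ = 9.2e-6 Pa·s, Cp = 1884 J/kg·K, k = 0.0184 W/m·K). Boundary and
initial conditions are spherically symmetric, so the angular terms drop
and the problem is radial.

Vapour seepage obeys the Darcy–Forchheimer law
`|∇P| = (μ/K) u + (ρ C_F/√K) u²`; the permeability (1e-7 m²) and
Forchheimer coefficient (0.55) defaults are order-of-magnitude placeholders
for a leafy matrix, not measured values, and are config-overridable.

### Numerics

Finite volumes on a uniform radial grid (default 100 cells), flux
conservative in `r²`; backward Euler in time (default dt = 5 s),
unconditionally stable, with properties and the source lagged one step so
each step is one tridiagonal solve. The Robin surface condition enters as
a half-cell conduction resistance in series with `1/h`; the centre face
carries zero flux. Divergence (NaN/Inf) aborts with a diagnostic.

Verification oracles: the textbook eigenfunction series for convective
sphere cooling (eigenvalues of `1 − λ cot λ = Bi` by Brent bracketing per
π-interval, ≥ 50 terms) and the closed-form steady generation profile
`T(r) = T∞ + q̇R/3h + q̇(R² − r²)/6k`. Observed accuracy at n = 200,
dt = 5 s: < 0.005 °C against the series; convergence is second order in
cell size and first order in dt; the discrete energy balance closes to
round-off for constant properties.

## Surface-coefficient calibration

The surface coefficient h is estimated exactly as the original procedure:
simulate the head's volume-average cooling curve for each h on a grid
(default 150…400 step 10 W/m²·K), interpolate onto the observation times,
score by RMSE averaged over measurement positions (top/middle/bottom — the
pooling choice, since per-position boundary data are unavailable), and take
the grid argmin (ties toward smaller h). Noiseless synthetic experiments
are recovered exactly.

A caveat the package makes explicit: with the measured conductivity
(~0.022 W/m·K) and R ≈ 0.0965 m, the Biot number at h = 270 W/m²·K is
≈ 1200, so cooling is conduction-limited and the volume-average curve is
nearly insensitive to h (≈ 3e-4 °C per W/m²·K). Under 0.2 °C sensor noise
the grid argmin therefore scatters widely across the grid even though it
is unbiased; single-experiment recovery of h to one grid step is not
statistically achievable in this regime, and the calibration tests document
this. Point estimates of h in this regime should be treated as averages
over many experiments.

## Zonal storage model

The commercial room (thousands of boxes, room airflow) is represented at
desk scale by a compartment network: eight lumped blocks of bulk produce
(14 kg each, the midpoint of the 13–15 kg box range; class-2 properties;
basket volume 0.0468 m³, area 0.804 m²) exchanging heat with zone air held
at the cooler supply temperature. Each block's surface coefficient scales
with its share of circulated air, `h_eff = h_ref · g^0.8` (turbulent
forced-convection exponent), `h_ref = 270 W/m²·K` from calibration, where
`g = effective_flow · f_i / Σ_active f` — the base fraction map
renormalized over the blocks present, so air serving absent blocks
redistributes during staged loading. `effective_flow = 0.075` is the share
of circulated air effective at block surfaces (most bypasses the stacks);
it sets cooling times to the order of magnitude of commercial rooms
(10–17 h) rather than to any measured value.

The supply setpoint is 4.0 °C so that blocks equilibrate near the 4.1 °C
storage target once the respiration offset `Q(T)·m/(h_eff A)` is added;
this is the only configuration in which a "within ±0.05 °C of 4.1 °C"
equilibrium band is reachable for every block. The standard airflow map
(first-loaded positions hold both the starved corner, fraction 0.06, and
the well-blown front, 0.16–0.17; second-loaded positions hold mid
fractions 0.10–0.12) has a spread echoing the measured in-room velocity
heterogeneity (0.23–0.53 m/s); the repositioned-cooler map is nearly
uniform (0.11–0.14). The three scenarios are: fully packed (all blocks at
t = 0), 50:50 batch fill (second set enters after a 5 h staging delay),
and batch fill with repositioned coolers (uniform map). Comparison metrics
follow the study's definitions: "temperature gradient time" is the time for
the slowest first-set block to reach 4.25 °C, "equilibrium time" the time
after which every block stays within 0.05 °C of 4.1 °C (including re-entry
after undershoot).

Integration is explicit Euler with sub-steps bounded by a tenth of the
fastest block time constant; energy bookkeeping closes to round-off. Under
the default maps the ranking reproduces the study's ordering — repositioned
batch ≤ batch fill ≤ fully packed — with roughly 12.5 / 13.9 / 16.6 h
equilibrium times. Clock-time agreement with a real room is out of scope:
the zone air has infinite cooling capacity, airflow maps are configuration
rather than CFD output, and block-internal gradients are lumped away.

## Synthetic data

The generators stand in for the study's sensor logs:

- **Morphology** — independent truncated Gaussians per class with the
  published per-class means, SDs and min/max (correlations are unreported,
  so traits are independent; class sizes are equal at 54 per class,
  matching the 162 = 54 × 3 design). Because truncation is asymmetric for
  some traits, sample moments converge to the truncated-distribution
  moments, which differ from the nominal location by a few grams at most.
- **Sealed-chamber traces** — constant temperature, constant rate over the
  short trace, additive Gaussian ppm noise; the forward rate is the heat
  law inverted through the CO2 stoichiometry, so rate estimation on a
  noiseless trace is an exact inverse.
- **Cooling experiments** — the forward radial solver (respiration on)
  sampled every 10 min, independent Gaussian noise per position.
- **Environment logs** — stationary Gaussians with the published
  means/SDs (921 ± 8 ppm mid-height CO2, 59–68 % RH, 0.45/0.23/0.53 m/s
  velocities).

What passing tests show: the estimators invert their own forward models,
the solver matches closed forms, and the pipeline's qualitative findings
(three size classes, early-period respiration warming, the loading-strategy
ranking) are reproduced. What they do not show: agreement with the real
room's fields or clock times, trait correlations, transpiration and RH
dynamics, or airflow physics — none of which the generators emulate.

A further honest observation: with the published per-class spreads, the
mean silhouette of the k=3 fit on synthetic morphology is ≈ 0.72
(standardized space; ≈ 0.78 unstandardized), noticeably below the 0.87
reported for the real measurements. The real data were evidently separated
more cleanly than independent truncated Gaussians with the published
summary statistics can be; the generator follows the published summaries
and does not force the higher score.

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| porosity φ | 0.31 | – | vacuum-impregnation measurement |
| f, g | 6.0803e-4, 2.6183 | – | cabbage respiration coefficients |
| pressure | 101 325 | Pa | standard atmosphere |
| basket | 0.52 × 0.30 × 0.30 | m | storage basket dimensions |
| h grid | 150…400 step 10 | W/m²·K | scan bounds/resolution of the calibration |
| solver dt / cells | 5 s / 100 | – | < 0.01 °C vs series oracle |
| block mass | 14 | kg | midpoint of 13–15 kg boxes |
| staging delay | 5 | h | batch-fill delay of the study design |
| supply setpoint | 4.0 | °C | blocks settle at the 4.1 °C target with respiration |
| effective_flow | 0.075 | – | sets desk-scale cooling to commercial order of magnitude |

Problem sizes used by the test suite and the acceptance script (162-record
tables, 20-seed replications, 20 h cooling runs at dt = 30 s with 60 cells
for calibration scans) are the package's reference configurations; finer
discretizations only tighten the already-verified numerics.
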