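# Methods

## Dissipation kinetics

Residue decay in each site × matrix is modelled as single first-order
kinetics, C(t) = C0·e^(−kt), with half-life t½ = ln2/k. The estimator
is nonlinear least squares on the concentration scale with residuals
weighted by the observed concentration (`sigma=c` in
`scipy.optimize.curve_fit`): residue measurement error is
multiplicative, so unweighted natural-scale least squares would let the
first one or two samples dominate and roughly triple the estimator
variance on a 2 h–30 d schedule. The fit is initialized at the
log-linear OLS solution and converges to it exactly on noiseless data.
R² is reported on the concentration scale over the points actually
fitted. Biphasic kinetics, robust variants and censored-likelihood
(Tobit) estimation are deliberately out of scope.

Left-censored (<LOQ) handling: the default policy for *fitting* is
`exclude` — a censored tail point carries no quantitative information
about k. `substitute_loq` and `substitute_half_loq` are provided
because risk assessment conventions are the opposite: when every
terminal residue is censored, the STMR and HR are maximized to the LOQ
(see below). The 2-hour sample is encoded as t = 0.083 d and treated as
the initial deposit for dissipation ratios; replicate values at a time
point are averaged (arithmetic mean) before fitting unless
`average_replicates=False`.

The dissipation ratio 1 − C(t)/C(initial) interpolates log-linearly
between bracketing observations, consistent with locally exponential
decay; it refuses a censored initial deposit and does not extrapolate
beyond the observed range.

## Compartmental uptake model

The wheat–environment system is eight physical compartments (air, soil,
leaf surface, grain surface, leaf, grain, stem, root) plus an explicit
ninth *degraded* state. All processes — deposition, surface
penetration, wash-off, root uptake, xylem/phloem transfer, degradation
and growth dilution — are first order, giving dm/dt = K·m with a 9×9
rate matrix whose off-diagonals are non-negative and whose columns sum
to zero. Making degradation an explicit sink (rather than implicit
loss) lets mass conservation be asserted numerically: every simulation
must keep Σm = 1 within 1e-9 (and errors out beyond 1e-6).

The solution m(t) = exp(Kt)·m(0) is evaluated with `scipy.linalg.expm`
stepwise along the grid; the test-suite cross-checks it against an
independent adaptive ODE integration (`solve_ivp`, DOP853 at rtol 1e-12)
on seeded random rate matrices to ≤1e-8 relative error. Source
contributions place unit mass in each source compartment separately and
scale by the application split; by linearity they sum to the full
solution exactly, which is asserted to 1e-9.

Default time grid: geometric from 0.01 to 300 days (400 points) with
t = 0 prepended — it resolves both the sub-day deposition/penetration
transient and the multi-month tail. Numerical choices: harvest-time and
arbitrary-time masses interpolate log-linearly in mass (linear fallback
when a bracket holds zero mass); residence time is the negative inverse
terminal slope of ln m(t) over the final 30 % of the grid (the slowest
mode drives the tail there) and refuses non-decaying windows; the
translocation factor divides biomass-normalized concentrations and is
undefined at zero root concentration; roundoff-level negative masses
(>−1e-9) are clamped to zero, anything larger is a hard numerical error.

Two grain-fraction denominators are implemented (`applied_mass` and
`total_crop_residue`, the latter summing the four crop interiors plus
both surface compartments) because both conventions are in use; the
choice is an explicit argument.

Biomass per crop compartment is constant within a simulation; growth
dilution enters only as a first-order pseudo-loss on crop compartments.
This is the simplest structure consistent with dilution-by-growth and is
a known limitation: real crops change biomass and interception area
over the season, and weather-driven, time-varying rates are not
modelled. Single application only.

## Fixture parameterizations

Full rate tables for diflufenican and flufenacet in wheat are not
publicly available, so the shipped `diflufenican_like` and
`flufenacet_like` configs are synthetic. Their degradation rates come
from the reported dissipation ranges (straw t½ 16 d vs 3.3 d, soil 43 d
vs 38 d); the transfer rates were tuned once, by hand, so the simulated
system reproduces the qualitative landmarks expected of these
compounds: a leaf peak of ≈0.57 kg/kg applied at ≈0.2 d, an early root
peak (day ~0.6–5) of order 1e-3, a grain peak of ≈5.5e-2 kg/kg applied
between days 10 and 30 (hence iF ≈ 1.8e-2 with the 0.33 grain→bread
processing factor), grain as the slowest-decaying crop compartment
(residence ≈ 15–19 d), a soil-route translocation-factor plateau of
≈4.5 for the diflufenican-like compound, and stronger translocation
plus faster in-crop loss for the flufenacet-like one (log Kow 3.2 vs
4.2). They are illustrative fixtures for exercising the machinery —
not a validated parameterization of either compound, and model outputs
derived from them (residence times, grain fractions, model–field R²)
are checked structurally, not against published values.

## Dietary risk

Chronic: NEDI = Σᵢ(STMRᵢ × Fᵢ)/bw over registered commodities, RQc =
NEDI/ADI × 100 %. Acute: NESTI is piecewise in the commodity unit
weight Ue — no Ue: HR×LP/bw; Ue < LP: (Ue×HR×ν + (LP−Ue)×HR)/bw;
Ue ≥ LP: HR×LP×ν/bw — and RQa = NESTI/ARfD × 100 %. The Ue = LP
boundary is assigned to the third branch; the two branches coincide
there, so NESTI is continuous, and with ν = 1 all branches collapse to
HR×LP/bw. Cereals carry no unit weight, so wheat assessments use the
first branch. Quotients below 100 % are acceptable.

Conventions: a compound without an established ARfD yields "not
applicable" acute results (represented as `None`), never 0. Fully
censored residue sets are summarized conservatively as STMR = HR = LOQ.
Mixed-source assessments (field STMR with modeled HR) are permitted but
the source is carried on the result. Raw quotients keep full precision;
rounding to 2 decimals happens only in the reporting layer. Population
defaults ship only for the two groups whose diet parameters are public
(adult: 63 kg, 138.5 g/day, LP 732.96 g; child under six: 16.1 kg, LP
25.8 g); the child's mean daily intake is not tabulated, so its chronic
quotient is reported as not computed rather than invented. Cumulative
multi-pesticide and probabilistic exposure are out of scope.

## Synthetic trials

The generator emulates a supervised wheat residue trial: three sites
with first-order truth per matrix (site half-lives span the reported
ranges — straw 7.4/11.5/16 d, soil 11/27/43 d; straw initial deposits
4.2–10 mg/kg, about four-fold the soil deposit), three replicate plots,
sampling at 2 h and 1, 3, 5, 7, 14, 21, 30 days plus a terminal day-63
harvest, and multiplicative lognormal noise with unit mean. The default
CV of 10 % keeps fitted R² in the realistic 0.84–0.99 band. Values
falling below the 0.01 mg/kg LOQ are emitted censored at the LOQ, and
terminal grain records are censored by construction, matching the
emulated trials. A fixed seed gives byte-identical output; true
parameters go to a sidecar JSON for recovery studies.

What the generator does *not* emulate: weather and soil covariates,
spatial autocorrelation between plots, matrix effects or recovery
variation of the analytical method, and between-replicate systematic
bias. Passing recovery tests therefore demonstrate estimator
correctness under the assumed error model, not robustness to every
feature of real field data.

## Problem sizes

The test-suite and the acceptance script run the full pipeline at the
study's own scale: 400-point simulation grids to day 300, 200-series
parameter-recovery studies, 20 random 9-state systems for the
ODE-oracle cross-check. The whole suite completes in a few seconds on
one CPU.
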