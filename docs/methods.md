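# Methods

## Transport model and its assumptions

The groundwater stage uses the closed-form solution for an
instantaneous vertical line source in a homogeneous, saturated aquifer
with uniform one-dimensional flow: a 2-D Gaussian plume in (x, y),
uniform in z (the source spans the saturated thickness, so there is no
vertical dispersion), with no degradation or dissolution of the
particles.  Particle–medium interaction is collapsed into a constant
retardation factor F sampled on [1, 1.1]: at the low aqueous
concentrations produced here (peak concentrations well below the
1–40 mg/L range of laboratory column studies), attachment behaves
pseudo-linearly, and mechanistic clean-bed/blocking/ripening models are
deliberately out of scope.

The unit convention is fixed package-wide: mass in µg, lengths in m,
time in days.  Concentration then comes out in µg/m³, which is
numerically identical to ng/L; reports convert to mg/L by dividing by
10⁶.  River flows are configured in m³/s (the natural gauge unit,
spelled out in the config field name `flow_QR_m3_s`) and converted to
m³/day internally.

Two conventions in the transport chain deserve note:

- the dispersivity correlation `αx = 0.83·(log x)^2.414` uses the
  base-10 logarithm, the standard convention for this family of
  scale-dependent correlations; only base-10 reproduces the case-study
  peak-concentration medians from the configured inputs.  The
  correlation is undefined at distances ≤ 1 m and the code raises
  there.
- the "peak" concentration is defined as the field evaluated at the
  plume-centre passage time `t_max = L·F/V_fx`.  Because of the `1/t`
  prefactor the true temporal maximum at fixed x occurs slightly
  earlier and is a few percent higher; the package follows the
  passage-time definition (a test documents the size of the gap).

`m` is the total spilled mass.  The 4π prefactor of the line-source
solution makes `C_max = m/(4π·b·n·F·L·√(αx·αy))` dimensionally a bulk
concentration per unit plan area spread over the source length; with
the shipped scenarios this reading reproduces the expected
concentration scale, and it is the one the package adopts.

## Receptor mixing

River: the lateral profile at the discharge point is averaged over the
plume width `W = 4√(2·αy·L)` (two lateral standard deviations each
side, 95% of the Gaussian mass), giving `C_D = 0.5981·C_max`; the
coefficient is `√(π/8)·erf(√2)` exactly and is cross-checked in the
tests by numeric quadrature.  The aquifer discharge is the steady-state
flow through the plume cross-section, `Q_D = k·g·W·b`, and the
in-stream balance `C₀ = (C_R'·Q_R' + C_D·Q_D)/Q_R` defaults to a clean
upstream river (`C_R' = 0`, `Q_R' = Q_R`).  A warning is emitted if a
draw produces `Q_D > Q_R`, where the dilution picture is meaningless.

Wetland: the wetland volume is constant (pumped supply balances
evapotranspiration, e.g. 30 m³/ha·day × 6.8 ha = 204 m³/day), the
pumped concentration holds at `C_max` for the whole contaminated
pumping time `t_m`, and mixing is instantaneous, so
`C₀ = C_max·q_w·t_m/V = C_max·DF` with `DF ≤ 1` enforced.  The shipped
wetland scenario samples DF directly as Uniform(4.2×10⁻⁴, 2.7×10⁻²);
sampling `t_m` uniformly on [1 h, 65 h] at fixed `q_w` and `V` is an
equivalent parameterization (uniform `t_m` maps linearly to uniform
DF) and is supported as an alternative config style.

## Monte Carlo engine

Plain independent Monte Carlo, N = 10,000 draws by default.  Each
variable gets its own stream: the per-variable seed is derived from the
scenario master seed and a fixed variable index through a seed
sequence, so runs are bit-for-bit reproducible and streams are
statistically independent (no correlated sampling, Latin hypercube or
quasi-random sequences — the output statistics of interest are medians
and tail fractions at N = 10⁴, where plain MC error is already ~1–3%).
Lognormal parameters are always the mean and standard deviation of
ln X.  Normal porosity draws are defensively clipped to (0, 1); at the
shipped parameters (mean 0.15 or 0.25, sd 0.02) clipping is a
≈7σ event and never observed.  Percentiles use linear interpolation
between order statistics; compliance fractions count draws strictly
below the threshold.

Dispersivities depend only on the constant receptor distance L, so they
are computed once per scenario rather than per draw.

## Fuzzy toxicity and risk model

Mamdani inference throughout: trapezoidal/triangular membership
functions, min conjunction, max aggregation, centroid defuzzification
on a 0.05-unit output grid.  Centroid was chosen as the defuzzifier
because it is the de-facto default of the toolbox workflow this model
family comes from; the engine itself accepts any model-definition file,
so alternative set shapes or rule bases are configuration, not code.

The toxicity system maps (size [nm], shape, coating) to a toxicity
score on [0, 100].  Size sets are small/medium/large with the "small"
set flat at membership 1 below 20 nm, which is why the toxicity of a
citrate sphere is constant over the whole 5–15 nm range (a property the
sensitivity analysis depends on).  Shape and coating are crisp
categorical terms (vocabulary: sphere/rod, citrate/PVP); unknown terms
raise a configuration error listing the known values.

The risk system combines concentration (ng/L) and toxicity.  For the
high-toxicity particle class the shipped concentration breakpoints are
calibrated so the defuzzified risk-vs-C₀ curve:

- rises through very-low/low scores below 22 ng/L (the proposed
  maximum allowable concentration for silver in surface water), with a
  steep jump in the last ng/L before 22 — the elasticity (SR) spikes
  there and collapses to zero at 22;
- is exactly flat at the medium-category centroid (62.5) on
  [22, 300] ng/L;
- rises monotonically on [300, 490] ng/L, crossing into the high
  category around ~420 ng/L;
- saturates at the high-set centroid (86.5) from 490 ng/L on — the
  rule base imposes no further variation, and inputs above 550 ng/L
  are clamped.

Risk scores are banded very_low [0,25), low [25,50), medium [50,75),
high [75,100]; the bands are part of the model file.  The exact
membership values of the source model are not public, so the
reconstruction is constrained by the curve anchors above; the category
frequencies it produces are therefore calibration-sensitive at the
level of a few percentage points.

## Sensitivity analysis

Concentration sensitivity is one-dimensional Monte Carlo analysis:
Spearman rank correlation (average-rank ties) between each sampled
input and C₀, ranked by |r_s|.  Constant inputs are skipped; a
correlation against a constant vector is treated as an error rather
than silently returned as NaN.

Risk sensitivity uses the sensitivity ratio SR = (ΔR/ΔC)·(C₀/R₀), the
local elasticity of the risk curve, estimated by a central finite
difference with half-width 1% of C₀ (configurable; the report states
the width used).  On a power law R = a·C^b the estimator returns b
everywhere, which the tests assert.  When SR is evaluated on a
tabulated curve, evaluation points are kept one grid-spacing plus one
half-width away from interval edges so the finite difference never
straddles an interpolation kink; this is why plateau intervals report
exactly 0.

## Synthetic scenario generator

`generate_synthetic_scenario(seed)` emits random but physically
plausible scenarios for property-based testing of the whole chain:
receptor distances 50–1000 m, porosity means 0.10–0.35, gradients
10⁻⁴–5×10⁻³, conductivities lognormal with ln-means 4–7 (≈55–1100
m/day medians), retardation up to 1.3.  River scenarios set the
river-flow median to 100× an upper bound (+4σ) of the aquifer
discharge, so the dilution assumption holds essentially surely.  The
generator emulates parameter uncertainty only — it does not emulate
spatial heterogeneity, transient flow, particle aging or measured field
data, so passing property tests demonstrate internal consistency of the
chain, not predictive skill on a real site.

## Problem sizes and numerical choices

Default ensembles are N = 10,000 draws (seconds of runtime); tests that
check analytic moments use N = 10⁵ with 4-standard-error bands, and
seed-stability tests allow the documented <3% shift of p50/p95 between
master seeds.  Fuzzy defuzzification uses a 0.05 output-grid step;
batch and scalar inference agree to ~10⁻¹² (float summation order).
Degenerate inputs are rejected loudly: draw counts < 1, distances
≤ 1 m, non-positive flows, DF outside [0, 1], porosity outside (0, 1),
retardation < 1, and empty vectors all raise with the offending field
named.

## Known limitations

- No z-dispersion, decay, dissolution or aggregation chemistry; the
  retardation interval [1, 1.1] encodes weak, pseudo-linear attachment
  only.
- No transient river transport downstream of the mixing point and no
  wetland ecology beyond the constant-volume balance.
- The fuzzy membership reconstruction is anchored to the published
  behavior of the risk curve, not to raw toxicity data; absolute
  category frequencies inherit a few percentage points of calibration
  uncertainty, and the magnitude of the SR spike just below 22 ng/L is
  reported rather than asserted.
- Inputs are sampled independently; real aquifer parameters (e.g. k
  and n) can be correlated, which would change tail fractions.
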