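# Methods

This note records the model as implemented: its assumptions, the
parameters that matter, the numerical choices, what the synthetic data
emulate, and the limits of what the tests demonstrate.

## Canopy architecture

The stand is 16 plants on a 4 × 4 grid at 1 m spacing over a rectangular
ground extending 0.5 m beyond the outer plants (16 m²). A plant is an
ordered list of phytomers; phytomer r carries an internode and a leaf at
azimuth φ_r = φ_{r−1} + 144° + U(−j, +j), with jitter j = 10° by default
and a random base azimuth per plant. New phytomers appear when the
plant's cumulative thermal time (base 10 °C, daily mean from a 12 h/12 h
day/night split) crosses multiples of the phyllochron (25 °C·d). With
the LT regime (22/18 °C) this gives ≈ 10 °C·d per day, one leaf every
2.5 days, and 30–32 leaves by day 80 — within the calibration band used
by the tests (25–35).

Organ elongation uses a beta-shaped rate over a fixed thermal-time
expansion window (leaf: 250 °C·d toward a 40 cm potential length;
internode: 150 °C·d toward 6 cm), times three multiplicative responses:

* g_T — an optimum curve (Yan–Hunt form) with T_min = 5, T_opt = 25,
  T_max = 40 °C. The optimum near 25 °C mirrors the crop's reported
  photosynthetic optimum; at 22 °C g_T ≈ 0.97, at 32 °C ≈ 0.80.
* g_V — 1 up to 1 kPa VPD, then decreasing at 0.2 kPa⁻¹, floored at 0.5.
* g_S = max(0, 1 + c_El,max · x · VPD), leaves only. The reference
  sensitivity c_El,max = −0.0006 mM⁻¹ kPa⁻¹ is *inferred*: the published
  sensitivity scan lists −0.0003 … −0.0009 as 50–150 % of the reference,
  which pins the midpoint. At 80 mM and 2.0 kPa, g_S = 0.904.

These response forms are declared stand-ins: the original calibrated
response equations are unpublished, so the implementation preserves the
causal structure (temperature, VPD and salinity jointly suppress leaf
elongation; internodes ignore salinity) with simple, fully configurable
shapes. Consequences that depend only on this structure (monotonicity,
invariances, directional responses) are meaningful; absolute organ
trajectories are not calibrated to any measured dataset.

Leaf blade area is s·L² with s = 0.4375 (a 40 cm leaf ≈ 700 cm²), split
exactly over seven flat rhombus leaflets (three opposite pairs at 30, 55
and 80 % of the rachis plus a terminal leaflet; relative lengths
normalised so the rhombus areas sum to s·L², aspect 0.6). The rachis
inserts at 35° above horizontal and droops by 70° base-to-tip; each
leaflet is a flat rhombus oriented along the local rachis frame, so mesh
area equals bookkept area to machine precision. The leaf-angle trait
factor scales the whole elevation profile (insertion and droop
together): factors > 1 steepen the leaf everywhere. Insertion/droop
defaults were chosen so the 70–130 % angle scan spans a clearly resolved
range of canopy transmittance while internode scaling moves interception
only weakly — the qualitative ordering reported for this crop. There is
no senescence; organ lengths and leaf area are non-decreasing.

## Light transport

The sky is a weighted set of downward directions: a ring-banded diffuse
dome (default 46 patches in 6 elevation bands; band weights are the
closed-form integrals of the uniform- or standard-overcast radiance
times sin e cos e, default standard overcast) plus the direct solar path
sampled at half-hour steps with weights proportional to sin(elevation),
for a configurable site/date (default Hannover, 52.38° N). The
diffuse:direct split defaults to 0.5.

Rays are emitted from a horizontal plane just above the canopy,
stratified over directions (largest-remainder allocation), with uniform
random origins over the ground rectangle expanded by a constant 1 m
margin. The margin admits oblique light from outside the plot footprint;
it is constant (not height-dependent) so absorbed fractions are
comparable across canopies of different heights. Lateral boundaries are
open — rays leaving the scene escape; a periodic boundary is not
implemented. The residual edge bias of the finite margin is visible as
the empty-plot transmittance deviating from 1 by ≲ 1 % at 5·10⁴ rays.

Each ray carries unit energy. At a leaf hit the event
{reflect, transmit, absorb} is sampled from the side-specific
coefficients (adaxial 7.3 %/2.4 %, abaxial 12.7 %/2.5 %); scattering is
bi-Lambertian (cosine-weighted about the normal on the appropriate
side). The ground reflects 80 % diffusely and transmits nothing. A ray
terminates on absorption, escape, or after 10 scatter events (counted as
residual), so incident = leaf + ground + escaped + residual *exactly* —
energy conservation is bookkeeping, and the tests assert closure at
1e-12. Per-ray randomness is a counter-based xorshift64* stream seeded
by (seed, ray index): results are bit-reproducible and independent of
execution order. Nearest-hit queries run in a numba kernel with
two-level axis-aligned-box pruning (plant → leaf → 14 triangles), which
is exact. Transmittance Q_T/Q_0 is the energy density arriving at the
ground from above, divided by the incident flux density; intercepted
light is the leaf-absorbed fraction of emitted flux.

Default ray counts: 10⁵ for single-scene analyses, 1 500–5 000 per day
inside multi-day simulations (80 daily traces integrate the noise down
to ≈ 0.2–0.4 % on final mass). Oracle tests use vertical beams and flat
rectangle scenes where interception is analytic; the two-layer test
compares against the closed-form multiple-reflection geometric series
with a 5 mm layer gap (edge losses < 1 % of the bounced flux).

## Dry-mass production

ΔW per leaflet = I_abs · ε(I_abs) · k · A. The reference efficiency is a
rectangular hyperbola ε(I) = ε_max · I_half/(I_half + I) with
ε_max = 6·10⁻⁶ g J⁻¹ and I_half = 5·10⁶ J m⁻² d⁻¹ — the published
empirical function is unavailable, so ε is a configurable stand-in with
the right qualitative shape (positive, decreasing, saturating), and all
quantitative claims are made on ratios (k, R_a, R_n, relative scans)
that are insensitive to ε's absolute scale. Shoot mass is μ·W_p with
μ = 0.87 (the reported average shoot fraction), initial plant mass
0.25 g. k is looked up per DAFLA interval (defaults: the harvest
intervals 29–35 … 71–77; uncovered days use k = 1).

k multiplies mass increments but never feeds back on architecture, so a
run under any k schedule equals the k = 1 reference run with daily
increments rescaled. `apply_k_schedule` implements this identity and is
used by the harvest generator, the dissection protocol and the closure
check; a property test verifies it against a genuine re-simulation to
1e-12.

## Synthetic study

`generate_climate` draws day temperature N(target, 1 °C), VPD
= −1.64 + 0.12·T_day + N(0, 0.0775 kPa) — giving the observed T–VPD
R² ≈ 0.71 and means ≈ 1.0 kPa (LT) / 2.2 kPa (HT) — and PAR as an
8 MJ m⁻² d⁻¹ seasonal sinusoid (± 40 %) with noise. The VPD and PAR
magnitudes are realistic spring-greenhouse defaults, not reported
measurements.

`generate_harvests` scales the reference trajectory by the ground-truth
k schedule, evaluates it at the harvest days (28, 35, 43, 50, 56, 63,
70, 77 DAFLA), and draws four replicates of mean-preserving log-normal
noise (default CV 0.08) for mass; leaf area is the ground-truth
allometry (default ln A = 0.75 ln W + 5.0 under LT) applied to the true
mass, times its own noise. Replicates are noise draws around one
trajectory; plant-to-plant architectural variation enters through the
phyllotaxis jitter in the simulator instead. What this emulates — and
what it does not: the generator reproduces the study *design* and the
statistical structure the estimators assume (log-linear allometry,
multiplicative errors, k acting linearly on increments). It does not
emulate model misspecification (a real canopy's area–mass relation is
not exactly the generator's line), so recovery tests certify the
estimation machinery, not the field accuracy of the model.

## Estimation, dissection, sensitivity

The allometry is OLS of ln A on ln W_sh, as the relationship is written
(not reduced major axis), with a two-sided t-test on the slope; groups
are {LT, HT} × {non-stress, salinity-pooled}. Three constructions of the
measured mass series W_sh,m feed the k estimator: the default passes the
replicate-mean measured *area* through the fitted allometry (exact on
the synthetic study at zero noise), alternatives use the simulated area
through the fit (smooths noise through the regression, but biased when
the simulated area–mass relation deviates from the measured line) or
the replicate-mean mass directly. k per interval is the plain increment
ratio; a non-positive reference increment raises, naming the interval.
Dissected factors are ratios (k_ht = k_HT,0/k_LT,0, k_x = k_T,x/k_T,0),
so recomposition is exact; reported tables round half-up to 2 decimals.

A caveat the tests quantify: increment ratios amplify harvest noise by
sqrt(W_t² + W_{t+1}²)/ΔW. With 8 % measurement CV and 4 replicates the
median per-interval recovery error is ≈ 14 % under the default growth
pattern (late intervals grow < 50 % per week); at zero noise recovery is
exact. Interval-wise k estimates from realistically noisy harvests
should therefore be read as noisy measurements — their factorisation
and time trends are informative, individual cells are not.

The dissection runs control-architecture and salt-architecture
references with the same seed and applies k_T,0/k_T,x as rescalings;
R_a + R_n equals the total reduction identically (asserted at 1e-10).
Interval rows use inter-harvest increments; the whole-period row uses
cumulative mass at the final harvest. Trait scans perturb exactly one
trait (leaf number via phyllochron/f; c_El,max, potential internode
length and the angle profile multiplicatively; per-10-mM literature
rates convert to overall factors as 1 − rate·x/10) and normalise to the
unscaled same-seed run under the same stressed efficiency.

## Evaluation statistics

RMSD and bias are standard; accuracy = 100·(1 − RMSD/mean(obs)), floored
at 0 — the source convention does not print its formula, so this
normalised-RMSD definition is declared here as the package's choice.

## Problem sizes used in tests and the acceptance script

Reference simulations: 77 days, 16 plants, 2 000 rays/day. Seed-spread
check: five phyllotaxis seeds at 4 000 rays/day with a fixed ray seed.
Energy-conservation check: the day-77 canopy (≈ 7 000 triangles) at 10⁵
rays. Analytic oracles: 2–4·10⁵ rays. Trait scans: 55-day canopies at
3 000–4 000 rays/day. Recovery experiments: 20 random k schedules in
[0.3, 1.8] over the 7 harvest intervals. These sizes keep the full suite
around half a minute after JIT compilation while leaving Monte Carlo
errors well below the tolerances being asserted.

## Known limitations

* All growth-response shapes and ε are stand-ins (above); absolute
  masses and areas are plausible in magnitude but uncalibrated.
* Salinity affects geometry only through leaf elongation by default;
  salinity-induced leaf-angle and leaf-number changes are reachable only
  through the trait-scan interface.
* No senescence, fruit sinks, carbon allocation or Na⁺ physiology; the
  latter is subsumed in k.
* Open lateral boundaries make the 16-plant plot edge-lit compared with
  a large field; the constant emission margin controls but does not
  eliminate this.
* Within-day solar movement is integrated into a single daily dome; no
  spectral resolution.
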