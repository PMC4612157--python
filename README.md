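# saltcanopy

A functional-structural plant model (FSPM) of a greenhouse tomato stand
for dissecting how salinity and high temperature reduce dry mass
production — through the plant's *architecture* (smaller leaves, altered
angles, less light interception) versus through its *physiology*
(reduced canopy light-use efficiency).

The package is aimed at crop modellers and stress physiologists who want
to separate effects that are experimentally inseparable: in a real
canopy, salinity changes geometry and photosynthesis at the same time;
in a virtual canopy they can be switched independently.

## The model

**Architecture.** Sixteen plants on a 4 × 4 grid at 1 m spacing. Each
plant is a stack of phytomers (internode + leaf); each leaf carries
seven flat rhombus leaflets on a drooping rachis, with a phyllotaxis
angle of 144° (± 10° random jitter). Organ elongation follows thermal
time with multiplicative environmental responses,

    rate = potential(age) · g_T(T) · g_V(VPD) · g_S(x, VPD),
    g_S  = max(0, 1 + c_El,max · x · VPD)   (leaves only; internodes
                                             are salinity-insensitive)

with x the NaCl concentration (mM) applied from 21 DAFLA (days after
first leaf appearance).

**Light.** A discretised sky dome (ring-banded diffuse patches plus the
solar path for the site and date) is Monte Carlo path-traced over the
leaflet mesh: adaxial/abaxial reflectance 7.3 %/12.7 %, transmittance
2.4 %/2.5 %, a ground reflecting 80 %, recursion depth 10. The result
is the absorbed flux I_abs per leaflet and the canopy transmittance
Q_T/Q_0.

**Dry mass.** Each leaf produces

    ΔW_l(t) = I_abs(t) · ε(I_abs(t)) · k_T,x · A_l(t)

where ε is a reference canopy light-use efficiency (a decreasing,
saturating function of absorbed light) and k_T,x a dimensionless
interval-wise multiplier capturing temperature (T ∈ {LT = 22/18 °C,
HT = 32/28 °C}) and salinity effects. Shoot mass is W_sh = μ·W_p with
μ = 0.87.

**Estimation and dissection.** From harvests (total leaf area A and
W_sh, linked by the allometry ln A = p ln W_sh + q fitted per regime),
the relative light-use efficiency per inter-harvest interval is

    k_T,x = ΔW_sh,measured / ΔW_sh,reference-simulated,

factorised as k_T,x = k_LT,0 · k_HT · k_x. Three same-seed simulations
then split the shoot-mass reduction under x mM NaCl into an
architectural effect R_a = 100(W_sh,0 − W_sh,a)/W_sh,0 and a
non-architectural effect R_n = 100(W_sh,a − W_sh,x)/W_sh,0, which sum
to the total reduction exactly. A trait-sensitivity module rescans leaf
number, leaf elongation sensitivity, internode length and leaf angle
one at a time.

Because the original experiment's raw data are not available, the
package ships a synthetic-data module that emulates the study design
(two regimes × salinity 0/40/60/80 mM, harvests at 28–77 DAFLA, four
replicates, log-normal measurement noise) with a *known* ground-truth k
schedule and allometry, so every estimator can be validated by
parameter recovery.

## Worked example

`examples/04_relative_lue_estimation.py` builds a synthetic experiment
with a known k schedule and recovers it end to end:

```
allometric fit: p=0.750 q=5.000 r2=1.0000 (n=32)

interval      k_true   k_hat
 29-35       0.428    0.428
 36-43       0.655    0.655
 44-50       1.502    1.502
 ...

worked example 29-35: k_HT = 0.96, k_40(LT) = 1.17
```

The fit recovers the generator's allometry exactly (noise was zero), the
interval ratios invert the generator's k schedule, and the dissection
worked example reproduces the published factorisation: 1.33/1.38 = 0.96
(high temperature lowers canopy light-use efficiency) and
1.61/1.38 = 1.17 (40 mM salinity transiently raises it early on).

`examples/06_trait_sensitivity.py` scans the leaf-angle profile at
70–130 % of the reference under 40 mM NaCl:

```
     trait  level  w_sh_rel  a_s_rel  transmittance_pct
leaf_angle    0.7     102.7    100.0               37.2
leaf_angle    1.0     100.0    100.0               39.9
leaf_angle    1.3      96.8    100.0               40.5

d(dry mass %) / d(interception %): slope=0.91, R2=1.00
```

Steeper leaves leave leaf area untouched but transmit more light to the
ground, intercept less, and lose dry mass; the interception change
explains essentially all of the mass change.

The other examples cover canopy growth (01), the light-transport energy
budget (02), the daily growth loop (03) and the architectural /
non-architectural dissection (05).

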