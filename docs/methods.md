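# Methods

`cardioscale` implements a subject-specific, multiscale model of the
biventricular heart and closed-loop circulation of pediatric (P21) rats,
together with the workflow used to study postnatal hyperoxia (Hx, 85 % O2
for 14 days, a rodent model of human preterm birth) against normoxic (Nx)
controls: local sensitivity analysis with Fisher-information subset
screening, multistart pressure-volume calibration, and derived-metric group
statistics.  This note records the model, its assumptions, the numerical
choices, and what the synthetic data do and do not establish.

## Model

### Calcium activation

Cytosolic Ca2+ is prescribed per cycle as a raised-cosine rise over
`T_S = k_TS T` followed by a raised-cosine fall over `T_R = k_TR T` and a
diastolic floor:

    Ca(t) = Ca_dia + Ca_amp * 0.5 (1 - cos(pi t / T_S)),        0 <= t < T_S
          = Ca_dia + Ca_amp * 0.5 (1 + cos(pi (t-T_S) / T_R)),  T_S <= t <= T_S+T_R
          = Ca_dia                                              otherwise

with `Ca_dia = 0.1610 uM` and `Ca_amp = 2 uM` fixed for all animals, and
the timing fractions `k_TS`, `k_TR` calibrated per animal.

### Crossbridge moment kinetics (per wall, 11 ODEs)

Five states — attached A1 (loosely bound), A2 (strongly bound), A3
(post-ratchet), unattached U, and super-relaxed U_SR — with occupancies
summing to one.  Attached-state strain distributions are tracked by their
0th-2nd moments (Gaussian-like closure at second order), so each wall
carries nine moment ODEs plus the non-permissible thin-filament fraction
`N_np` and `U_SR`.  New attachments enter A1 at zero strain; strain moments
advect with half-sarcomere velocity; transitions preserve strain.

Thin-filament regulation is a permissible/non-permissible gate driven by
cooperative Ca2+ binding to troponin C with binding flux
`k_on Ca (Ca / 1 uM)^(n_H - 1)`, `n_H = 4`.  The cooperativity exponent is a
structural constant chosen from the measured cardiac force-pCa Hill
coefficient range (3-6); a first-order gate would make the half-activation
point strictly proportional to `k_off / k_on`, which is incompatible with
the small pCa50 shifts produced by large `k_off` changes in this
preparation.

Metabolites (ATP, ADP, Pi; uM) modulate the rates:

* Pi rebinding drives the reverse A2 -> A1 flux, `k_-1 Pi / Pi_ref`
  (`Pi_ref = 1000 uM`), and competes with Pi unbinding (`k_Pi`) for the
  forward flux — exactly zero rebinding at Pi = 0;
* detachment from A3 requires ADP release (inhibited by ADP rebinding via
  `K_D`) and ATP binding (via `K_T`, saturating at `k_ATP`):
  `k3_eff = series(k_3 * phi, k_ATP)`, `phi = (ATP/K_T) / (1 + ATP/K_T + ADP/K_D)`.

Active stress (per wall `i`):

    sigma_XB,i = OV(L_s,i) * [ k_stiff1 (p2_1 + p3_1) + k_stiff2 dr p3_0 ]

where `OV` is a piecewise-linear thick-filament overlap tent with knots at
(1.60, 2.05, 2.30, 3.60) um — plateau 2.05-2.30, ascending limb below,
long shallow descending limb above.  The ascending limb makes shortening
self-limiting (a stable Frank-Starling operating point); end-diastole is
anchored near 2.2 um by the reference-area rule below.

### Myofiber force balance (3 ODEs)

Passive stress is a single collagen-recruitment power law,
`sigma_pas = k_passive (L_s - L_sc0)^gamma` for `L_s > L_sc0` and zero
below slack (no compressive collagen force).  The wall-strain-implied
sarcomere length `L_s,wall` loads a linear series element
`sigma_SE = K_SE (L_s,wall - L_s)`, and the contractile length evolves
through the viscous balance

    eta dL_s/dt = sigma_SE - sigma_XB - sigma_pas

so the closure `sigma_SE = sigma_XB + sigma_pas + sigma_visc` holds
identically at every state.

### TriSeg biventricular geometry (4 algebraic states)

LV free wall, septum and RV free wall are thick spherical caps joined at a
circular junction of radius `y_m`; signed cap heights `x_m` point along the
LV-to-RV axis, so septal midwall curvature
`C_m,SEP = 2 x_SEP / (x_SEP^2 + y_m^2)` is positive when the septum bulges
into the RV.  Midwall area `A_m = pi (x^2 + y^2)`, thickness ratio
`z = 3 C_m V_w / (2 A_m)`, natural fiber strain
`eps = 0.5 ln(A_m / A_m,ref) - z^2/12 - 0.019 z^4`, and
`L_s,wall = L_s,ref exp(eps)` with `L_s,ref = 2.35 um`.  Midwall tension
`T_m = sigma V_w (1 + z^2/3 + z^4/5) / A_m` reduces to the thin-wall
membrane tension `sigma h` (verified against the Laplace law on a
nearly-closed cap); its axial/radial components balance at the junction,
and the two cavity-volume constraints close the 4x4 algebraic system.
Transmural pressures follow from the free-wall axial tension,
`P = ±2 T_x / y_m`.  The load-bearing wall stress is the series-element
stress with a smooth tensile floor (soft-plus, width 0.1 kPa): a
transiently slack wall wrinkles rather than supporting compression, which
also keeps the junction balance away from the septal snap-through
degeneracy.  There is no pericardium.

### Circulation (6 ODEs)

Six compartments (LV, RV, systemic arteries/veins, pulmonary
arteries/veins) with linear compliances `P = (V - V_un)/C`, Ohmic
resistances between compartments, and four valves as ideal diodes smoothed
by a soft-plus of width 0.02 mmHg.  Ventricular outflow is additionally
gated by a smooth cavity-availability factor `V^2/(V^2 + (2 uL)^2)` — a
near-empty ventricle whose walls coapt cannot eject — which exists purely
to keep extreme (mid-optimization) parameterizations well-posed; it is
inactive (>0.99) above ~15 uL.  Total blood volume is conserved exactly by
construction.

State count: 3 walls x 11 kinetic + 3 sarcomere lengths + 4 TriSeg
unknowns + 6 volumes = 46.

## Parameterization

The free-parameter registry has 54 named entries: 12 wall-resolved
(`k_passive`, `k_off`, `k_stiff1`, `k_stiff2` for LV/SEP/RV — exactly the
entries remodelled by hyperoxia), 14 shared crossbridge rates, 3
metabolites, 5 shared myofiber constants, 4 calcium-transient parameters, 6
TriSeg geometry parameters, and 10 circulation parameters.  The cardiac
period `T`, total blood volume (`0.06 mL/g x bodyweight`) and zero-pressure
volumes are data-derived auxiliaries, not free parameters.

Per-animal nominal rules: wall volumes from condition-specific
wall-weight/bodyweight ratios (Nx 3.8 / 0.86, Hx 3.2 / 1.00 mg/g; LV takes
2/3 and septum 1/3 of the LV+SEP weight; density 1.055 g/mL); midwall
reference areas from the measured end-diastolic volumes under a
spherical-shell midwall rule with fixed per-wall area shares (LV 0.876,
SEP 0.506, RV 1.489) calibrated once against a uniform-stress TriSeg solve
of the control group-average end-diastolic geometry so that end-diastolic
sarcomere length lands near 2.2 um; the actin-myosin attachment rate is
reduced 20 % from the adult value for all animals (pediatric adjustment);
systemic and pulmonary resistances from the record
(`R = (0.9 ESP - P_ven) / CO`); remaining entries at the package's nominal
values, which were tuned once so the control group-average simulation
reproduces Table-1-scale hemodynamics (SV ~27 uL, LV ESP ~67 mmHg, RV
operating range ~24-51 uL) and were not revisited per test.

Hyperoxia modifiers (multiplicative, RV wall only where wall-specific):
ATP x0.95, ADP x1.05, Pi x1.05 (the "table" convention x0.95 is a config
switch), `k_passive,RV` x2, `k_off,RV` x0.6, `k_stiff1,RV` x1.7,
`k_stiff2,RV` x1.7.  Applying the modifiers twice is an error.

## Numerics

* Stiff integration: scipy BDF with an analytically-free compiled
  finite-difference Jacobian (step `1e-6 max(|y|, 0.01)`), rtol 1e-6
  (1e-5 inside calibration), per-block absolute tolerances, max step T/20.
* TriSeg algebra: damped Newton with a per-component trust-region cap
  (10 % of scale), warm-started from the geometry states, cold-restarted
  from a volume-based heuristic on failure; the geometry states relax onto
  the solved root with a 1 ms time constant while pressures always use the
  exact root.  The tension-balance residuals are scaled with an absolute
  floor so the all-walls-unloaded limit degenerates gracefully.
* Steady state: cycle-by-cycle integration until the per-cycle relative
  change of both ventricles' EDV/ESV falls below 1e-3 (default), at most
  40 cycles; the initial state places the ventricles at measured EDV,
  distributes vascular volume at sub-nominal arterial pressures (the first
  beats charge the windkessels), and solves a passive-consistent geometry.
* Static endpoints: EDV/ESV at the volume extremes; EDP as the pressure
  minimum on the end-diastolic volume plateau (within 2 % of stroke
  volume) and ESP as the maximum on the end-systolic plateau.  Single-
  sample reads at argmax/argmin would alias the isovolumetric pressure
  swing (tens of mmHg per grid step) into the endpoints.

## Sensitivity and subset selection

Outputs are the concatenated steady LV/RV volume and pressure traces on
the common 50-point grid (4N = 200 values).  Centered differences on
log-parameters with half-width h = 0.01 over the 18 organ-scale and timing
parameters; perturbed runs warm-start from the baseline's converged state.
Per animal, a parameter's scalar sensitivity is the Euclidean norm of its
column, normalized to the animal's maximum; the influence threshold is
0.1.  Subsets are screened through the approximate Fisher information
matrix `F = S^T S` and accepted only if `cond(F) < 1e8`.  The harmonized
ten-parameter calibration subset is
`{R_SA, R_PA, A_m,ref x3, V_w x3, k_TS, k_TR}` (the borderline systemic
compliances are dropped so both conditions share one subset).

## Calibration

Residuals: four dynamic blocks (LV/RV volume and pressure traces, each
scaled by `1/(sqrt(N) max y_data)`) plus eight relative static errors (the
EDV/ESV/EDP/ESP octet), 208 entries; the `1/sqrt(N)` weighting makes one
whole trace commensurate with a single static entry, i.e. the static
endpoints dominate.  Model cycles are rotated so LV end-diastole sits at
grid index 0 (the catheter convention).  Optimization: scipy
trust-region-reflective least squares on log-parameters, finite-difference
step 1e-2 (matching the sensitivity half-width and sitting well above the
steady-state solver's noise floor; the library default of ~1e-8 produces
pure-noise gradients), bounds [0.8, 1.2] x log-nominal for shape
parameters, [0.1, 10] x log-nominal for resistances (interval endpoints
sorted so negative log-nominals are handled), and natural-scale boxes
k_TS in (0.001, 0.1), k_TR in (0.3, 0.5).  Twenty randomized starts drawn
per coordinate as uniform [0.5, 1.5] factors of log-nominal (the first
start is the nominal vector); a failed candidate simulation returns a
constant penalty vector of magnitude 1e3 so trust-region steps retreat.
The standing test uses a reduced configuration (4 starts, 6 main
iterations, steady tolerance 3e-3, 14-cycle budget) sized for a desk-scale
run; the full 20-start protocol is available through the same interface.

## Synthetic cohorts

The generator emulates the study's data-collection conditions: bodyweights
around the measured group means (Nx 49.9 ± 1.2 g, Hx 53.4 ± 2.8 g),
periods around 0.177 ± 0.015 s, lognormal between-animal dispersion with
10 % CV on the ten calibration parameters (a documented assumption — the
real dispersion is unknown), the hyperoxia modifiers for Hx animals, and —
because the crossbridge remodelling alone cannot raise pulmonary pressure —
a hyperoxic afterload drawn ~45 % above the Nx-nominal pulmonary
resistance with a ~25 % lower pulmonary arterial compliance, mirroring the
calibrated group contrasts; together these nearly double the R/C afterload
ratio while leaving the RC time approximately preserved.  Raw recordings
replicate the steady cycle into 20-50 beats with independent LV/RV period
jitter (sequential catheterization), additive Gaussian pressure/volume
noise, and optional negative-EDP and isovolumetric-spike artifacts.  All
randomness flows through one seeded generator.

What passing tests on these cohorts show: that the pipeline (beat
averaging, harmonization, artifact correction, calibration, metrics,
statistics) is self-consistent and recovers known ground truth under the
stated noise.  What they do not show: fidelity to unmodelled features of
real catheter data (autocorrelated noise, drift, respiratory modulation)
or to between-animal variation beyond the assumed lognormal dispersion.

## Known limitations

* There are no atria and no pericardium; filling is driven entirely by
  venous pressure, so end-diastolic pressures read slightly high and the
  end-diastolic pressure-volume relation is flat — the same behaviour the
  catheter data themselves show in this preparation.
* The maximal Ca2+-activated force scales essentially linearly with the
  stiffness constants; the hyperoxic +70 % stiffness remodelling therefore
  raises Fmax by ~70 %, in line with the experimental trabecula
  observation, and no parameterization of this model family can make the
  same modifiers produce a ~1.7 % Fmax change.
* Wall stresses halve their published trabecula magnitudes' upper range at
  peak because contractility was anchored to chamber pressures rather than
  to isolated-muscle force; ratios between conditions are unaffected.
* Sequential-recording artifacts are modelled as independent Gaussian
  noise plus two discrete artifact types; catheter gain drift is out of
  scope.
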