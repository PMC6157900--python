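# Methods

## The forward model

Blood flow in the larger systemic arteries is described by the standard 1D
(cross-sectionally averaged) equations for an incompressible Newtonian
fluid in impermeable, axisymmetric elastic vessels,

    A_t + q_x = 0
    q_t + (q²/A)_x + (A/ρ) p_x = −(2√π ν/δ) q/√A,

on a bifurcating binary tree of 55 arteries (28 terminals).  Each vessel
tapers linearly in radius from `r_in` to `r_out`; radii are defined at the
reference pressure of 97 mmHg.  The pressure–area (tube) law is

    p(A) = p_ref + F(x) (1 − √(A0/A)),

anchored so that `p(A0) = p_ref = 97 mmHg` exactly, with the wall stiffness

    F(x) = (4/3) (k1 e^(−k2 r0(x)) + k3),     k2 = 22.53 cm⁻¹.

Large arteries (r0 ≫ 1 cm) are therefore governed by `k3` alone and small
arteries by `k1 + k3`.  The linearised pulse wave speed at the reference
area is `c0 = √(F/2ρ)`; with the hemodialysis-cohort mean `k3 = 14.51×10⁵
g s⁻² cm⁻¹` this gives ≈ 9.6 m/s in the aorta, consistent with the
aorta-to-femoral transit speeds the model produces.  `r0` is treated as a
radius (in cm): with the radius convention the printed cohort stiffness
means land exactly in the physiological PWV range, while a literal
diameter reading would not.

Each terminal vessel drains into a three-element Windkessel (proximal
resistance R1, distal resistance R2, compliance C, venous pressure 5 mmHg).
The nominal per-terminal elements ship with the tree file; at run time both
resistances are multiplied by the patient parameter `S_R` and the
compliance by `S_C`.  The nominal values distribute the terminal flow by
Murray's cube law on outlet radii and are normalised so that `S_R = 1.34`,
`S_C = 13.57` (the reported cohort means) correspond to a physiological
state: ≈ 88 mmHg perfusion pressure at a cardiac output of 3.56 l/min and
an outflow time constant `R2·C = 1.0 s`.

The heart is a prescribed ejection flow at the ascending-aorta inlet: a
beta-shaped pulse `q(s) ∝ s^a (1−s)^b` on `s = t/ED` with total exponent
5, its single interior maximum exactly at `t = τ`, zero for `t ≥ ED`, and
area equal to the stroke volume `SV = CO/HR`.  `ED` defaults to a third of
the cardiac cycle when not measured.  Subject height scales all vessel
lengths by `height/176 cm`; radii are left unchanged (lengths dominate
path-dependent wave timing, and no radius scaling is reported for this
model family).

Fixed constants: blood density 1.055 g/cm³, viscosity 0.049 g cm⁻¹ s⁻¹,
boundary-layer thickness 0.086 cm.  Units are CGS internally; mmHg, l/min,
ml and ms appear only at the I/O boundary (1 mmHg = 1333.22 dyn/cm²).

## Numerics

The hyperbolic system is integrated with the two-step (Richtmyer)
Lax–Wendroff scheme on the conservation form, with geometric source terms
from the axial variation of `F` and `A0` evaluated so that the state
`A = A0`, `q = 0` is an exact discrete equilibrium.  Where a source term
needs √A at a cell midpoint, the mean of the nodal square roots is used (a
consistent second-order choice that allows one square root per node and
step).

Boundary nodes are closed by half-cell mass balances coupled to the
junction conditions.  At a bifurcation, the three boundary flows are the
unknowns of a local Newton solve requiring (i) half-cell continuity for
each boundary area, (ii) continuity of static pressure across the
junction, and (iii) exact discrete flow conservation.  A Windkessel
terminal solves the analogous scalar problem against its capacitor
pressure, which is then advanced by the exact exponential update.  With
this closure the tree's stored volume is flux-conservative to round-off:
the volume-balance audit over a converged cycle is at machine precision,
and junction pressure continuity is exact.  Continuity of *static*
pressure is the junction condition; a total-pressure variant was
considered and not implemented, as the kinetic correction (½ρu²) is two
orders of magnitude below pulse pressure at these flow velocities.

The time step follows a CFL number of 0.9 on the fastest characteristic;
the default spatial step is 0.25 cm (a vessel shorter than the step is
represented by its two end nodes).  Grid convergence on the nominal tree:
halving the step from 1.0 to 0.5 cm changes the radial-site pressure by
< 1 mmHg in max-norm, so the coarse 1.0–1.75 cm grids are used for the
many-simulation workflows (fitting, cohort generation) and the 0.25 cm
grid for single-run audits.

A periodic state is reached by repeating cycles from a resting
initialisation (uniform pressure at the Windkessel-estimated mean) until
the root pressure trace changes by less than 0.5 mmHg (max-norm) between
cycles — about 8 cycles at the defaults.  Fitting and synthetic-recording
generation instead run a *fixed* cycle count (7 by default) so that the
simulated waveform depends smoothly on the parameters; a residual-based
stop would make the objective piecewise-defined in parameter space.

## Pulse wave analysis

Waveforms are calibrated by an affine map of the recorded span onto the
brachial systolic/diastolic pair.  The foot is located by the
intersecting-tangent method (tangent at the maximum upslope intersected
with the end-diastolic minimum), the de-facto standard for foot-to-foot
transit timing.  The systolic shoulder comes from the zero crossings of
the fourth derivative of a Savitzky–Golay-smoothed waveform (window 5% of
the cycle); the dicrotic notch is the incisura (post-peak local pressure
minimum) when present, the sharpest post-peak deceleration otherwise, and
an ED estimate with a warning flag when neither exists.  AP is the
pressure difference between the systolic peak and the shoulder (negative
for early-peak waveforms, with the type reported), and
`AI = (SP−DP)/(SP−DP−AP) × 100%` is applied as printed in either case.
SEVR uses plain (not heart-rate-corrected) diastolic/systolic
pressure–time integrals on the cycle re-based at the foot, with the
ejection duration taken from the notch.  Model PWV between two sites
divides the path length along the tree (through the deepest common
ancestor) by the foot-to-foot transit time.  SEVR and central indices are
evaluated on the model's own aortic waveform rather than a
device-reconstructed one.

## Parameter estimation

Six parameters (k1, k3, CO, τ, S_R, S_C) are estimated per recording by
minimising the relative waveform error at the distal radial site: mean
absolute difference over the cycle, normalised by the mean measured
pressure (an L2 variant is available).  Simulated and measured cycles are
aligned at their feet, so a uniform time shift of the recording does not
change the objective.  Search bounds are per-parameter boxes spanning the
reported cohort means ± 4 SD, truncated to positivity.

The waveform pins down the *composite* stiffness at the recording-site
calibre, `k1 e^(−k2 r_rad) + k3`, far more strongly than `k1` and `k3`
separately: trading `k1` against `k3` — with small compensations in CO,
S_R and S_C — changes the waveform only through subtle timing features.
The objective therefore contains a long, shallow, curved valley with
distinct local branches, and a plain swarm-plus-local-polish search
reliably lands on the wrong branch.  The estimator combines:

1. a constriction-coefficient particle swarm (χ = 0.7298, c1 = c2 = 2.05,
   20 particles × 30 iterations by default, reflecting box boundaries);
2. a simplex settle from the swarm best;
3. an *anchored profile walk* over k1: the k1 = 0 edge is solved
   thoroughly (simplex + bounded quasi-Newton over the other five
   parameters), then k1 is stepped upward (0.08 of its range per step),
   each conditional solve warm-started by linear extrapolation of the
   five tracked parameters, until the profiled minimum has clearly
   passed (three consecutive rises);
4. a least-squares parabola through the walked points around the
   profiled minimum locates the dip (the walk's grid spacing gives far
   more contrast than the conditional-solve noise); one more conditional
   solve runs at the vertex;
5. a final polish in all six parameters (simplex, then bounded
   quasi-Newton).

CO and S_R jointly set the mean pressure and form their own exchange
valley inside each conditional solve, so the conditional and final
quasi-Newton stages work in rotated coordinates — (log CO + log S_R,
log CO − log S_R) — which turns that trade-off into an axis direction
and improves the conditional floors by an order of magnitude at equal
budget.  The anchored walk makes the outcome essentially independent of
which valley branch the swarm finds.  On a noiseless self-generated waveform the
procedure recovers all six parameters to within a few percent; the
identifiability audit (each parameter perturbed ±20% one at a time moves
the objective measurably above its floor) documents that all six are
individually visible, while the valley structure above documents why the
joint problem is hard — uniqueness cannot be guaranteed, only searched
for.  Every fit records its seed, configuration hash and evaluation count;
particle evaluations are independent and order-stable, and results are
bitwise reproducible for a given seed.

## Arteriovenous fistula

The dialysis access is a reduced shunt: a short (1 cm), narrow (0.18 cm
radius) segment grafted at the anastomosis site — mid-brachial for an
upper-arm access, 95% along the fistula-arm radial for a lower-arm one —
draining into a dedicated venous Windkessel (anastomosis resistance in
series with a 2.5×10³ dyn s cm⁻⁵ venous resistance) that is *not* scaled
by S_R/S_C.  The graft splits the host vessel without altering geometry
elsewhere, so an infinite anastomosis resistance reproduces the
fistula-free model to better than 0.1 mmHg (the residual being the small
compliance of the shunt stub itself).  The default resistance yields
450–600 ml/min of shunt flow, and lowering it drives the flow beyond
600 ml/min with a 10–25 mmHg drop in mean aortic pressure — the
clinically reported regime.  A full venous network is deliberately out of
scope; the shunt's venous parameters are this package's calibration.

The radial-to-aortic transfer function is the per-harmonic ratio of the
aortic to the radial pressure spectra (harmonic 0 excluded, default 10
harmonics) of a periodic cycle, used to quantify how little the fistula
perturbs the mapping that pulse-wave-analysis devices assume.  The
fistula-free refitting experiment generates radial waveforms *with* a
fistula, fits the plain model to them, and tabulates the per-parameter
percent deviations; its characteristic signature is an underestimation of
k1 and S_R.

## Synthetic cohorts

Virtual subjects draw their six parameters and covariates from truncated
normal distributions matching the reported cohort means and SDs
(truncation at positivity and at ±4 SD).  Where the positivity truncation
cuts into the left tail (k1, k3, S_R), the parent location is solved
numerically so the *truncated* mean still equals the reported value.
Healthy-control parameter means are emulation (the source tabulates only
covariates for that group): stiffness ≈ 60% below the pre-dialysis HD
level, equal cardiac output, and lower capillary-bed compliance scaling,
mirroring the reported group contrasts.  Brachial pressures and heart
rates are typical-dialysis conventions, as they are not tabulated.

The study design is reproduced exactly: each HD subject has two sessions
(3-day and 2-day interdialytic break) × four time points (before/after
start, before/after end) = 8 scheduled recordings (280 for n = 35);
controls are recorded once.  Dialysis effects are multiplicative factors
on the subject's baseline k3 (before-start 16.44/14.51, before-end
9.92/14.51, i.e. the reported transient stiffness drop), with milder
transient reductions of CO and τ.  Recording quality exclusion is
emulated as missing-completely-at-random at 25/280 per HD slot.  The
device model resamples the solver output at 128 Hz and adds Gaussian noise
(1.5% of pulse amplitude) plus a small sinusoidal baseline wander; these
stand in for unpublished tonometry characteristics and are configurable.
What passing tests on this cohort do *not* show: real tonometry artefacts
(hold-pressure drift, motion), inter-parameter correlations in the HD
population (defaults assume independence), and any guarantee that the
fitted model is structurally correct for real vessels.

## Cohort statistics

The repeated-measures test is a Friedman-type rank statistic valid for
unbalanced designs with missing data: within each subject the observed
conditions are ranked and centred; the vector of per-condition sums of
centred ranks S has, under within-subject exchangeability, an exactly
computable covariance Σ (Var = (m²−1)/12, Cov = −(m+1)/12 for a subject
observing m conditions), and the statistic is the pseudo-inverse quadratic
form S'Σ⁺S referred to χ² on rank(Σ) degrees of freedom.  On complete
balanced tables this reduces algebraically to Friedman's chi-square
(verified to 10⁻¹⁰ against an independent implementation), and its
empirical type-I error under 10% MCAR missingness is within [0.03, 0.07]
at α = 0.05.  Pairwise follow-ups use the same S and Σ with ±1 contrasts,
each contrast chi-square referred to the *global* test's degrees of
freedom — a Scheffé-type family-wise adjustment that can never fall below
the unadjusted p.

Propensity matching fits a logistic model of group membership on age and
gender, then greedily pairs treated to control subjects nearest on the
logit scale without replacement, within a caliper of 0.2 SD of the logit;
the treated order is randomised under the run seed.  Balance diagnostics
(Wilcoxon rank-sum for continuous, Yates-corrected chi-square for
categorical, plus standardised mean differences) are reported before and
after.  Correlation structure uses Spearman coefficients with a 0.05
significance mask (unadjusted, mirroring the white-square convention; a
Benjamini–Hochberg variant is available) and average-linkage clustering on
the distance 1 − |R|.  Two-group comparisons are the Wilcoxon rank-sum
test with normal approximation (mid-ranks for ties) and the
Yates-corrected chi-square.

## Problem sizes and reproducibility

The packaged workflows use: 0.25 cm grids for single-run conservation and
wave-speed audits; 1.0–1.25 cm grids for forward studies and fitting; a
1.75 cm grid with 5 fixed cycles for the many-fit experiments (noisy
refits, fistula refitting); 100 tables for the Friedman-equivalence check
and 2000 for type-I calibration; cohorts of 35 + 32 for design and
matching checks and 2 subjects for the fistula refitting audit.  All
randomness flows from explicit seeds; `scripts/acceptance.py --seed N`
fans its seed into every stage and recomputes all reported quantities
from scratch.

## Known limitations

- The wall is purely elastic; viscoelasticity, curvature, gravity and
  autoregulation are out of scope.
- The tube law softens with distension (c ∝ A^(−1/4)); real arteries
  stiffen at high strain.  Within the physiological pressure range used
  here the difference is second-order.
- The ejection profile is a two-parameter shape; only its peak time and
  area are identified, not its true form.
- Joint identifiability of (k1, k3) rests on subtle timing features; with
  noisy data the k1/k3 split should be interpreted with caution even
  though the composite small-artery stiffness is robust.
- The healthy-control population parameters and the tonometry noise model
  are emulations chosen once, not fitted to data.
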