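# Methods

This note documents the models, numerical choices and known limitations of
`heartgsa`. The package couples three layers: a synthetic kinematics
generator, a lumped-parameter (0D) circulation model per heart side, and a
surrogate-based global sensitivity analysis (Gaussian-process emulators +
Sobol' indices on Saltelli designs).

## 1. Patient record and derived scalars

All baselines hang off a small set of clinical scalars: left-ventricular
end-diastolic and end-systolic volume (mL), heart rate (bpm), systolic and
diastolic cuff pressure (mmHg), and optionally cardiac output (L/min) and
right-ventricular volumes. Derivations are exact arithmetic: SV = EDV −
ESV, CO = SV·HR/1000, LVEF = 100·SV/EDV. Reports show errors both
unrounded and rounded half-away-from-zero to integer percent; machine
output always retains the unrounded value.

The validation report computes, for every feature present in both tables,
100·|sim − clin|/clin — the **clinical value is the denominator**. A zero
clinical value flags the row "undefined" instead of raising. The shipped
reference table (`clinical.REFERENCE_IN_SILICO` / `REFERENCE_CLINICAL`)
contains published cluster-CFD feature values and clinical measurements; it
exercises the report format and is *not* a reproduction target for the 0D
model, which is different physics. The tricuspid rows in that table
disagree strongly (clinically suspected regurgitation that the simulations
never attempted to capture); the report simply prints them.

## 2. Synthetic volume transients

The simulator is driven by prescribed periodic chamber-volume curves. The
real study derives them from image registration; that data is not publicly
available, so the generator builds them from C² smootherstep
(6x⁵−15x⁴+10x³) segments with the canonical morphology:

- ventricle: isovolumic hold (3% of T), ejection EDV→ESV over the systolic
  fraction (default 0.35), isovolumic relaxation (5%), E-wave filling
  (70% of SV), diastasis plateau, atrial-kick filling (30% of SV), end
  hold;
- atrium: reservoir filling during ventricular systole, conduit emptying
  into the E-wave, slight diastasis refill, booster emptying at the kick.

Ventricular extrema match the prescribed EDV/ESV exactly (well within the
0.1% tolerance the downstream stages assume). Atrial extrema are synthetic
defaults (LA 50–110 mL, RA 45–100 mL). Right-side volumes fall back to the
left-side values when the record carries none; a `right_sv_fraction`
setting can introduce the left/right stroke-volume mismatch seen in
image-derived data (default balanced). 1024 samples per cycle. The `seed`
argument only matters when the optional phase-boundary jitter is enabled
(default off); generation is deterministic either way.

Fluxes are the exact spectral (FFT) derivative of the periodic volume
series. Valve events are sign changes of the ventricular net flux after a
fixed 5-point moving average: the ejection run opens the outflow valve,
the merged filling runs (E-wave + diastasis + kick; diastasis is a zero
plateau, not a sign change) open the inflow valve. Because the smoothing
window smears each edge by ~2–3 samples, detected events are accurate to a
few grid steps — immaterial downstream because fluxes vanish at the
events. More than one ejection or filling interval after smoothing is
rejected as ambiguous rather than guessed at.

## 3. Windkessel estimation and integration

Three-element Windkessel per arterial outlet: R = MAP/CO (unit-converted
to kPa·ms/mL with 1 mmHg = 0.133322 kPa), Z = 0.05·R, C = T_cycle/R. Two
MAP conventions are exposed (`third_pulse`, default, and
`two_fifths_pulse`), plus a variant that splits the total resistance
R = 0.95·R_total with Z absorbing 5%. The compliance formula is the
dimensionally consistent period-over-resistance reading; it makes the
Windkessel relaxation time R·C exactly one cardiac cycle. The pulmonary
side uses an assumed mean PA pressure (default 14 mmHg) with the
right-ventricular output as a configuration input, since it is not
recoverable from cuff data.

The distal state advances by implicit Euler (unconditionally stable at any
step), and the proximal pressure is p = p_c + Z·q_in. With the default
dt = RC/100 in the free-decay check the discrete half-life is within 1% of
ln2·RC.

## 4. The 0D heart-side model

Unknowns per step are the atrial and ventricular node pressures; the
venous inflow, inflow-valve and outflow-valve flows follow from Ohm
relations. With prescribed dV/dt the two chamber mass balances close the
2×2 linear system; the Windkessel distal pressure then advances one
implicit-Euler step. dt defaults to 0.5 ms (snapped so a beat holds an
integer number of steps); 4 beats are simulated and features are extracted
from the last. The Windkessel state is warm-started on its periodic orbit
(10 beats of the Windkessel alone against the prescribed ejection flux),
after which adding a 5th beat moves no feature by more than 0.5%.

**Chamber compliance.** A small wall compliance (0.05 mL/kPa at each
chamber node; 0 recovers the purely algebraic limit) regularizes the
system while valves switch. Without it, any residual flux during a
closed-valve interval — spectral ripple, or real flux inside the finite
transition window — is forced through the leak resistance, producing
pressure spikes that grow without bound as κ→0. With it, those intervals
are pressure-limited by the stored charge (≈ q·Δt/C ≪ 1 kPa), the model is
well-posed over the whole κ range, and the κ-insensitivity below holds.
At 0.05 mL/kPa the compliance stores < 1 mL at systolic pressures, so
prescribed volumes are honoured to well under 1%.

**Valves.** R(σ,κ) = R_open·(R_leak(κ)/R_open)^(1−σ): a log-linear blend
between an open resistance and a closed Darcy leak R_leak = μ·c_geom/κ.
σ(t) is a smootherstep transition of width `dur` (default 15 ms, study
range 11.25–18.75 ms) centered on each event, exactly 0/1 outside the
windows. R_open comes from a linearized orifice law ρ·Q_peak/(2A²) at the
baseline peak flow; the effective orifice areas (AV 3.0, MV 4.5, PV 3.5,
TV 5.0 cm²) are synthetic configuration values, not measurements. The leak
geometry factor c_geom = 625 mm⁻¹ is calibrated so that the closed valve
is effectively impermeable across the entire κ range [1e-9, 1e-5]:
R_leak(1e-5) = 2.5·10⁵ kPa·ms/mL, more than 10³× the largest afterload,
and leak flow under a 100 mmHg head stays below 0.1% of peak systolic
flow. This is a design target, deliberately mirroring the finding that the
valve penalization is a numerical parameter without physiological
influence: measured across the full κ range, every feature changes by
< 0.05%. κ itself carries no published units; it enters only through μ/κ.

Blood constants: ρ = 1060 kg/m³, μ = 4 mPa·s (standard Newtonian values).
Venous inflow resistance 5 kPa·ms/mL (synthetic default). A failed linear
solve or a pressure beyond a configurable bound (default 1000 mmHg) marks
the trace unconverged — such runs are discarded from emulator training,
never silently patched.

## 5. Output features

All features are computed on the last simulated beat:

- **Valve gradients (mmHg)** — time-mean of the upstream-minus-downstream
  node pressure difference. The window is configurable per valve: full
  cycle (default), systole (outflow-valve open interval) or diastole
  (inflow-valve open interval), with half a transition width trimmed at
  each end so means never straddle valve switching. The full-cycle default
  follows the observation that systolic pressure differences in a
  boundary-driven model are flux-prescribed and parameter-insensitive;
  the parameter response lives in the intervals when the valve is closed
  and the difference is set by the preload/afterload pressure levels.
  Consequently the full-cycle means are dominated by the closed-valve
  intervals and are strongly negative — they are signed pressure
  differences, not stenotic gradient magnitudes.
- **Max valve velocities (m/s)** — max |Q|/A_eff over the beat. An
  effective orifice velocity, not a 3D field maximum.
- **Kinetic energy proxies (mJ)** — time-mean of ½·ρ·V(t)·v(t)², with v
  the effective velocity of the compartment's dominant outflow branch
  (arterial compartments use fixed synthetic volumes/areas). A 0D proxy,
  not a volume-integrated field energy.
- **Residence times (s)** — the well-mixed age equation
  d(a·V)/dt = V + Q_in·a_in − Q_out·a with fresh inflow (a_in = 0),
  integrated cycle by cycle until the cycle-mean age changes < 0.1%
  (tolerance and cycle cap configurable); the converged cycle-mean age is
  reported. In the constant-flow limit this is exactly V/Q. The left
  atrial appendage is a synthetic 10 mL side pocket exchanging 30% of the
  atrial inflow with the atrium; its inflow age is the atrial age series.
  A compartment without inflow cannot wash out and flags the feature
  instead of failing the run.

## 6. Design, emulation, screening

Parameter spaces use the published study ranges (authoritative where they
differ from a literal ±25% of the baseline): afterload resistances
AO [37.46, 62.32] / PA [27.81, 46.21] kPa·ms/mL, preloads LA [7.5, 12.5] /
RA [3.5, 8.5] mmHg, κ log-uniform over [1e-9, 1e-5] (linear sampling would
collapse three decades), dur [11.25, 18.75] ms. Left side: D = 6
{r_wk_ao, p_la, kappa_av, kappa_mv, dur_av, dur_mv}; right side: D = 4
with κ dropped. Training designs are seeded Latin hypercubes of ≈10·D
points; pick-freeze designs use a seeded scrambled Sobol' sequence in 2D
dimensions split into A and B (plain-random fallback available).

Each feature's emulator is a deterministic mean function (linear in the
standardized inputs by default; constant available) plus a zero-mean GP
with Matérn covariance (ν = 2.5 default, 1.5 available) and i.i.d.
Gaussian noise with a positive floor. Inputs map to [0,1]^D (log10 first
for log-scale parameters), outputs are z-scored. Hyperparameters maximize
the log marginal likelihood with 5 seeded multi-starts. Accuracy is the
mean 5-fold cross-validated R² in native units (a fold with constant truth
is recorded as undefined and excluded from the mean, with a warning);
emulators at or below R² = 0.5 are excluded from the index stage, with
their scores reported in the heatmap output.

Posterior sampling is exact (Cholesky of the joint predictive covariance,
jitter escalated 1e-10→1e-6) up to 2000 points, and switches to a pathwise
approximation above: Matérn random Fourier features (frequencies drawn
from the kernel's Student-t(2ν) spectral measure, 1024 features) combined
with the Matheron update against the training data. This scales posterior
draws to the n(D+2) pick-freeze evaluations at a cost linear in the number
of points.

## 7. Sobol' indices

S1 uses the Saltelli-2010 estimator, ST the Jansen estimator (the standard
pairing), normalized by the empirical variance of (f(A), f(B)). Point
estimates come from the predictive-mean path; uncertainty comes from
recomputing the indices per joint posterior draw (default 20), reported as
across-draw means and 2.5/97.5 percentiles. Negative small estimates are
sampling noise: kept raw in the result files, clipped to zero only in the
heatmap display. A parameter is flagged negligible when both S1 and ST
point estimates fall below 0.01.

**Degenerate outputs.** An output whose spread over the whole parameter
space is below 0.1% of its magnitude is treated as constant: its indices
are set to zero with a `degenerate` flag rather than apportioning solver
noise. In the default configuration this affects the kinetic-energy,
velocity and residence-time features, whose values are essentially fixed
by the prescribed kinematics (coefficient of variation ~1e-5–1e-4); the
two valve-gradient features carry all the genuine parameter response.

**What the default run shows.** For the gradients, the afterload
resistance dominates (ST ≈ 0.98), preload is small but clearly
non-negligible (ST ≈ 0.02), and κ and dur sit 2–3 orders below the 0.01
threshold. The κ result is by construction (leak dominance) and mirrors
the original screening conclusion. The preload/afterload ordering is a
property of the 0D analog, not of 3D hemodynamics: with both chamber
volumes prescribed, flows are fixed by the kinematics, so parameters act
through absolute pressure levels, and the Windkessel resistance sets the
largest level scale (its range spans ≈36 mmHg of mean arterial pressure
versus ±2.5 mmHg of preload). A 3D model with resolved intracavity flow
gives preload additional causal routes (filling jets, vortex structures,
mixing) that a 0D circuit cannot represent.

## 8. What passing tests do and do not show

The synthetic generator reproduces the *morphology* of image-derived
volume transients and the exact clinical extrema, but none of the
beat-to-beat variability, regurgitation, or left/right imbalance of real
data; the simulator reproduces circuit-level physics (series-resistance
limits, Windkessel decay, mass conservation, washout), not spatial flow
fields. Passing tests therefore certify the statistical machinery (design,
emulation, screening, index estimation — checked against analytic
oracles: Ishigami decomposition, additive-model identities, a from-scratch
Cholesky GP) and the internal consistency of the 0D model; they do not
certify agreement with 3D CFD feature values, which is explicitly out of
scope.

## 9. Problem sizes and determinism

Default analysis profile: 60 left-side training simulations (≈10·D), 4
beats each at dt = 0.5 ms; 5-fold CV; 2000 pick-freeze samples with 20
posterior draws in the shipped desk profile (the `n_saltelli` default in
`RunConfig` is 10000, matching the study scale; the acceptance script and
tests use 2000, which leaves index estimates for these smooth emulators
well inside the tolerances checked). Every stage takes an explicit seed
(design, fit, GSA), and repeated runs with identical configuration are
byte-identical. The full left-side pipeline takes ~2 minutes on one CPU.
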