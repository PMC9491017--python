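# heartgsa

Variance-based global sensitivity analysis of four-chamber heart
hemodynamics with Gaussian-process surrogate models, on a desk-scale
lumped-parameter simulator.

## The problem

Patient-specific simulations of blood flow through all four heart chambers
depend on boundary-condition parameters that are hard to measure directly:
atrial preload pressures, arterial Windkessel afterloads, and the numerical
parameters of the valve model (a permeability-like penalization κ and a
finite opening/closing duration *dur*). Before tuning such a model to a
patient, one wants to know **which of these parameters actually move the
clinically relevant outputs** — valve pressure gradients, peak valve
velocities, chamber kinetic energies and blood residence times.

Running a global sensitivity analysis directly on 3D CFD is intractable
(thousands of expensive simulations), so the analysis is done through
surrogates: each scalar output feature gets a Gaussian-process emulator
(GPE) trained on a small Latin-hypercube design of simulator runs, and
Sobol' sensitivity indices are estimated by evaluating the emulator on a
Saltelli pick-freeze design, with emulator uncertainty propagated by
posterior sampling.

This package implements that entire analysis as a tested, reusable
pipeline. The expensive 3D solver is replaced by a 0D circuit model per
heart side, driven by prescribed periodic chamber-volume transients, which
exposes the same parameter vector and the same output-feature registry, so
every stage of the methodology — design, emulation, screening, index
estimation — runs end to end on one CPU in minutes.

## The model

**Circuit.** For each side, a constant atrial preload source `p_atrium`
feeds the atrium through a venous resistance; the atrium empties into the
ventricle through the inflow valve; the ventricle ejects through the
outflow valve into a three-element Windkessel (characteristic impedance
*Z*, peripheral resistance *R*, compliance *C*). Chamber volumes V(t) are
prescribed, so each step solves the node pressures from the two mass
balances Q_vein − Q_in = dV_atr/dt and Q_in − Q_out = dV_vent/dt (with a
small chamber compliance regularizing the instants when valves switch),
then advances the Windkessel state by implicit Euler.

**Windkessel estimation from clinical scalars.**

    MAP = p_dia + (p_sys − p_dia)/3        (cuff pressures, mmHg)
    R   = MAP / CO                          (kPa·ms/mL)
    Z   = 0.05·R,   C = T_cycle / R

**Valves.** Each valve is a resistor blending log-linearly between an open
resistance (linearized orifice law at baseline peak flow) and a closed
Darcy leak resistance R_leak = μ·c_geom/κ, with a smootherstep open
fraction σ(t) of transition width *dur* centered on the opening/closing
events detected from the volume transients.

**Sensitivity indices.** With pick-freeze matrices A, B, AB_i,

    S1_i = E[ f(B)·(f(AB_i) − f(A)) ] / V        (Saltelli 2010)
    ST_i = E[ (f(A) − f(AB_i))² ] / (2V)         (Jansen 1999)

estimated from n(D+2) emulator evaluations; emulators are screened by
5-fold cross-validated R² > 0.5, and indices below 0.01 are flagged
negligible.

## Worked example

```python
import heartgsa as hg

rec = hg.load_patient_record("examples/patient_record.csv")
print(hg.stroke_volume(rec), round(hg.cardiac_output(rec), 2),
      round(hg.ejection_fraction(rec), 2))
# 140.0 11.62 33.82      <- stroke volume (mL), CO (L/min), LVEF (%)

wk = hg.estimate_systemic_windkessel(rec.p_sys_cuff, rec.p_dia_cuff, rec.hr, rec.co)
print(f"Z={wk.z:.3f} R={wk.r:.2f} C={wk.c:.2f}")
# Z=2.421 R=48.42 C=14.93   <- kPa·ms/mL, kPa·ms/mL, mL/kPa

vt  = hg.generate_volume_transients(rec, seed=0)
tim = hg.detect_valve_events(hg.derive_fluxes(vt), dur_ms=15.0)

from heartgsa.pipeline import RunConfig, side_context, baseline_params
ctx   = side_context(RunConfig(record=rec), rec, "left")
trace = hg.simulate(baseline_params("left", ctx), vt, tim)
for name, value in hg.extract_features(trace, tim).items():
    print(name, round(value, 3))
# dp_AV -35.48   dp_MV -37.436        (mmHg, full-cycle means)
# Ek_LV 308.27   Ek_AO 48.443  Ek_LA 38.826   (mJ)
# RT_LV 1.758    RT_APP 0.593         (s)
# maxv_AV 3.449  maxv_MV 2.972        (m/s)
```

The stroke volume, cardiac output and ejection fraction are exact
derivations from the record. The simulated feature magnitudes are those of
the 0D proxy (effective orifice velocities, well-mixed residence times) —
they are not meant to match 3D field quantities, but they respond to the
study parameters, which is what the sensitivity analysis needs.

The full analysis from the shell:

```sh
heartgsa run-all --record examples/patient_record.csv --seed 5 \
    --side left --out out/
```

writes the training design, per-run feature table, cross-validation scores,
per-feature Sobol' tables and the S1/ST heatmap matrices (CSV) plus a JSON
manifest. With the default configuration the two valve-gradient emulators
are kept (CV R² > 0.999) and the analysis finds the afterload resistance
dominant (ST ≈ 0.98), the preload non-negligible (ST ≈ 0.02) and the valve
penalization κ negligible (ST ≈ 1e-4) — see `docs/methods.md` for why the
0D analog orders afterload above preload.

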