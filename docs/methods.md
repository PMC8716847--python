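# Methods

`cardioem` simulates a fully coupled heart beat at desk scale: monodomain
electrophysiology drives a myofilament tension model, the tension loads a
hyperelastic finite-element left ventricle inside a pericardial shell, the
ventricle exchanges volume with a closed-loop lumped circulation, and the
deforming voltage sources feed a forward ECG.  This note records the models,
the numerical choices, and what the synthetic setting does and does not
represent.

## Geometry and fibers

The ventricle is a truncated prolate ellipsoid (outer semi-axes
35 × 35 × 55 mm, 10 mm wall, basal truncation at z = +15 mm), the standard
idealization used by cardiac-mechanics benchmarks.  The wall is meshed by a
structured transmural × longitudinal × circumferential grid split into
tetrahedra with the Kuhn pattern (conforming by construction; pole wedges
close the apex).  Two resolutions are built from the same analytic surfaces:
a fine linear-tetrahedron mesh for electrophysiology (default target edge
3 mm, ≈ 25k elements) and a coarse quadratic-tetrahedron mesh for mechanics
(default ≈ 650 elements).  Transmural (e) and apico-basal (a) coordinates are
exact by construction.  Midside nodes sit at edge midpoints, so the
isoparametric map of each quadratic element is affine.

Fibers follow the rule-based transmural helix: helix angle
α(e) = 60° − 120°·e (endocardium +60°, epicardium −60°), fiber **f** in the
circumferential–longitudinal tangent plane, sheet **s** transmural,
**sn** = **f** × **s**.  Note the frame convention: in this package the sheet
axis is the *transmural* direction, so material coefficients and the
unloading stress refer to (f, sn) as the two in-wall directions.

The torso is not meshed; limb electrodes (RA/LA/LL) sit on a
180 × 120 × 300 mm ellipsoidal shell around the heart, while the precordial
electrodes (V1–V6) are pulled radially inward to 40–75 mm from the
epicardium — a real heart sits anterior-left in the chest, so the V leads
are far closer to it than the average torso radius.  An optional
Fibonacci-spiral surface cloud supports body-surface maps.

## Electrophysiology

Tissue propagation uses the monodomain equation with conductivity
σ = σ_l f⊗f + σ_t (s⊗s + sn⊗sn), first-order Godunov splitting (cell
reaction at 0.02 ms substeps, implicit-Euler diffusion at 0.1 ms), lumped
mass, and no-flux boundaries.  The diffusion operator is assembled once in
the reference configuration; deformation does not alter conduction (a stated
model assumption).

Two membrane models stand behind one interface:

* the published human ventricular ionic model (endo/epi variants, ≈ 41
  states) integrated with Rush–Larsen gates + forward Euler at 0.005 ms
  substeps (the step size at which APD90 is converged to < 0.5 ms under
  halving).  Its fast-sodium conductance carries a scale factor
  (default 2.5) because the published formulation fails to propagate at the
  coarse desk resolutions — the same motivation the literature gives for
  sodium-current alterations in whole-heart meshes;
* a fast phenomenological two-variable model with a prescribed calcium
  transient (peak 0.7 µM at 60 ms after activation), used by the coupled
  desk runs so the whole chain runs in minutes.  Its repolarization time
  constant is divided by the same per-node "gKs" multiplier the ionic model
  uses, so the apico-basal heterogeneity machinery is shared.

Conduction velocities are never assumed: a secant calibration on 1D cable /
2D sheet fixtures *at the resolution of the target mesh* tunes σ_l and σ_t
until the measured velocities match 800 / 550 mm/s within 1%.  CV is
measured by regressing activation time (−40 mV upward crossing) on distance
over the central 50% of the fixture.  The apical repolarization gradient is
likewise calibrated: bisection on the apical gKs multiplier until the
limit-cycle APD90 shortens by 17% versus base at 850 ms pacing; the
multiplier is interpolated linearly in the apico-basal coordinate.

Ventricular stimulation mimics Purkinje–muscular junction breakthrough with
three configurable endocardial root sites (default: apical third, three
circumferential positions, zero relative offsets), fired 120 ms after sinus
time (the atrio-ventricular delay); atria are not meshed, so the sinus event
only starts the atrial elastance and the AV timer.

## Active tension

A Rice-type mean-field myofilament model: calcium binds low/high-affinity
regulatory troponin-C, filament-overlap functions of sarcomere length weight
their contribution, a steeply cooperative permissive transition
(Hill exponent 8, half-activation 0.22) gates a three-state crossbridge
cycle, and mean crossbridge distortions carry the force–velocity behaviour.
SL = λ·1.9 µm is prescribed by the mechanics; rates are effective 37 °C
values chosen to give a physiological isometric twitch (time-to-peak
≈ 110 ms, 50% relaxation ≈ 110 ms).  Stiff sub-systems (attached-pair
occupancies, mean distortions) are updated semi-implicitly; distortions are
bounded at ±3 power strokes (detachment makes larger mean distortions
unphysical).  The exact ventricular parameter values used by the reference
study are not public; the shipped set is therefore this package's own
calibration, with `t_ref` (contractility scale, default 220 kPa in the
coupled configuration) chosen so the coupled desk ventricle ejects a
physiological fraction of its end-diastolic volume.

With strong coupling enabled the model returns the net troponin-C binding
flux — length/velocity dependent through the overlap weighting — and the
ionic model drops its internal (length-independent) troponin buffer in
favour of it.

## Mechanics

Total-Lagrangian quadratic tetrahedra, 4-point quadrature, with all strain
algebra in the local fiber frame (the material gradients are rotated once at
setup).  Passive wall: orthotropic Fung-type exponential
W = c0/2 (e^Q − 1) with Q quadratic in the fiber-frame Green–Lagrange
strain, plus a volumetric penalty κ/2 (J − 1)² (κ = 650 kPa).  The exponent
coefficients are the standard cardiac orthotropic family mapped onto this
package's frame (transmural = sheet axis gets the soft radial coefficient).
The stress scaling c0 = 0.5 kPa was set by a self-consistency requirement of
the initialization scheme: re-pressurizing the estimated unloaded state at
the diastatic pressure must recover the diastatic cavity volume (it does, to
≈ 4%).  Active tension enters the fiber-fiber component of the second
Piola–Kirchhoff stress at each quadrature point, interpolated linearly from
the EP nodes through a mapping fixed in the reference configuration.

The pericardium is a rigid analytic ellipsoidal shell offset 0.5 mm outward
from the epicardium; epicardial nodes (reference selection, with a 3 mm
basal margin next to the fixed ring) feel a frictionless normal penalty with
a C¹ quadratically-smoothed hinge (width 0.5 mm, factor ramped 0 → 20 kPa).
Dirichlet conditions fix the basal vessel-analog ring (the epicardial edge
of the truncation plane); the meshed non-cardiac sleeve of the full-scale
study is replaced by the rigid shell, so there are no sleeve DOFs to fix.

Dynamics: Newmark-beta (average acceleration), Rayleigh damping
α_R M + β_R K with α_R = 100 s⁻¹, β_R = 0.04 s and K lagged (refreshed with
the Newton tangent, at most 5 steps old).  Newton uses a direct sparse LU,
reused across iterations/steps in modified-Newton fashion with automatic
refresh and a backtracking line search; the follower-pressure load tangent
is included.  The convergence criterion is a residual norm below 1e-8
*relative to the force scale of the step* — the published threshold is
unit-system dependent, and an absolute 1e-8 in kPa·mm·ms units sits at the
float64 round-off floor.  Stagnation within 100× the tolerance after
repeated refreshes is accepted as the attainable floor.  Mechanics dt is
1 ms with automatic halving (≤ 4) on non-convergence.

## Circulation

A two-sided closed loop: time-varying-elastance atria, the FEM left
ventricle (a 0D elastance double stands in for the right ventricle and for
circuit-only studies), characteristic-resistance + windkessel arterial
compartments and venous compliances, with diode valves
(flow = max(0, Δp)/R).  Explicit 0.1 ms substeps keep total blood volume
conserved to round-off.  The constants reproduce the standard
pressure anchors (aortic 85/125 mmHg, pulmonary 13/20 mmHg) when run with
0D ventricles of full-size stroke volume (`calibrate_circuit` re-derives
them); the coupled desk configuration re-balances systemic resistance and
arterial compliance for the smaller desk ventricle's output, which leaves
desk aortic pressures somewhat below those anchors — a size effect,
not a model change.

FEM–circuit coupling is iterative per 1 ms step: secant on the cavity
pressure until the FEM volume change matches the net valve flow within
0.01 mL.  Two robustness measures damp the oscillations this staggering is
known to produce in the isovolumetric phases: the per-step pressure change
is bounded at 12 mmHg/ms (several times the physiological maximum, so it
never binds in normal operation), and near-tolerance best iterates (< 5×)
are accepted rather than aborting a beat.  The stretch fed back to the
myofilament model is low-pass filtered (τ = 5 ms) and rate-limited to
±0.01/ms (the sarcomere-physiological range) so solver-scale velocity noise
cannot pump the crossbridge distortions.

## Initialization

The constructed geometry is treated as the (pressurized) diastatic state.
The unloaded reference is estimated by adding a stress T_init to the two
in-wall components of S, equilibrating statically (adaptive load
continuation), and iterating T_init by secant until the cavity volume
matches the empirical unloaded-volume estimate
V0 = V_diastatic (0.6 − 0.006 P_diastatic[mmHg]); reported targets are
truncated to whole mL (the rule that reproduces both reference
values).  The deformed configuration is adopted as the new stress-free
reference (fiber-frame rotation neglected at these strains), the diastatic
pressure (7.3 mmHg) is applied with the pericardial factor ramped linearly
0 → 20 kPa over 50 ms, and the wall settles for 250 ms.  The initialization
transient is heavily over-damped (20× α_R) and the pressure is applied over
the first ≈ 180 ms — the procedure seeks a static state, not a physical
trajectory — and velocities are zeroed before the beat starts.

## Forward ECG and the frozen-geometry protocol

Each EP element contributes an equivalent dipole −σ_i ∇Vm · vol with
gradient, volume and centroid evaluated in the deformed configuration
(displacement interpolated from the mechanics mesh with quadratic shape
functions; stretch is measured against the interpolated unloaded
configuration).  Potentials use the infinite homogeneous volume conductor
(σ_b = 0.2 S/m); leads are I/II/III and V1–V6 against Wilson's central
terminal.  Because the heterogeneous torso of the full-scale study is out of
scope, absolute amplitudes are not comparable to body-surface recordings;
morphologies and the relative dynamic-versus-frozen comparisons are the
meaningful outputs.

The comparison protocol freezes the recorded deformation at the
end-diastatic (0 ms), end-diastolic (150 ms) and end-systolic (400 ms)
instants, replays the identical Vm history on each frozen geometry
(material-point identity), recomputes the ECG, and tabulates per-lead T-wave
amplitudes (% of dynamic) and end-of-T times (tangent method: intersection
of the steepest terminal slope with the zero line, measured from the first
ventricular stimulus).  The T-wave window starts 20 ms before the earliest
nodal repolarization (−70 mV downward crossing); amplitude baselines are the
20 ms pre-window mean.  Body-surface amplitude maps exclude points whose
dynamic |T| is below 0.5 mV.  Rotation is reported
counterclockwise-viewed-from-base positive (so the base peaks negative and
the apex positive during ejection); AVPD is positive toward the apex.

## What the synthetic setting does and does not show

The generator stands in for subject-specific imaging: an idealized LV with
rule-based fibers, a rigid pericardium, 0D atria and right heart, and a
homogeneous infinite conductor.  Passing tests therefore demonstrate the
*mechanisms* — calibrated conduction, repolarization gradients, coupled
pressure–volume dynamics with the five-phase cycle, moving-source ECG
effects and their frozen-geometry ordering — not subject-level numbers.
Printed full-scale quantities (per-lead table values, AVPD magnitudes,
measured-ECG correlations) depend on the unavailable anatomy and recordings
and are treated as qualitative anchors only.  P waves are absent (no atrial
myocardium), and desk aortic pressures sit below the standard anchors because
the desk ventricle's stroke volume is smaller than a full-size heart's.

## Problem sizes and determinism

Default desk sizes: EP mesh ≈ 25k linear tets / 5.6k nodes; mechanics mesh
≈ 650 quadratic tets / 4k DOF; one coupled beat of 850 ms (≈ 70 bpm) at
1 ms mechanics steps; 64 body-surface points.  A full build + initialization
+ beat + four-case comparison takes roughly 10 minutes on one CPU.  Nothing
in the pipeline draws random numbers; repeated runs are bit-identical.
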