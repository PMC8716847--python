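# cardioem

Desk-scale, fully coupled cardiac electro-mechanics in Python: monodomain
electrophysiology → myofilament active tension → hyperelastic finite-element
left ventricle with pericardial contact → closed-loop lumped circulation →
forward ECG from moving sources.  The package exists to study a question
that static electrophysiology models cannot address: **how much does the
beating motion of the heart itself change the ECG**, and in particular the
T wave, compared to computing the same membrane voltages on a geometry
frozen at a single instant of the cycle.

It is aimed at computational-cardiology researchers and students who want a
transparent, testable implementation of the whole coupled chain that runs on
a laptop, not a cluster: every ingredient (ionic model, monodomain solver,
Rice-type crossbridge model, total-Lagrangian FEM, windkessel circulation,
dipole-source ECG) is plain `numpy`/`scipy`/`numba` code behind small
interfaces.

## The model in brief

* **Electrophysiology** — monodomain reaction–diffusion
  `χC_m ∂V/∂t = ∇·(σ∇V) − χI_ion` with σ = σ_l f⊗f + σ_t(s⊗s + sn⊗sn)
  built from a rule-based ±60° transmural fiber helix; the human ventricular
  ionic model (endo/epi variants) or a fast phenomenological reduction; the
  conductivities are *calibrated* so measured conduction velocities hit
  800/550 mm/s, and an apical g_Ks scaling is calibrated to shorten APD90 by
  17% toward the apex.
* **Active tension** — a Rice-type mean-field crossbridge model at 37 °C:
  T_k(Ca, λ, dλ/dt) added to the fiber–fiber component of the second
  Piola–Kirchhoff stress, with optional *strong coupling* (the troponin-C
  calcium flux computed by the tension model replaces the ionic model's
  internal buffer).
* **Mechanics** — quasi-incompressible orthotropic Fung-type wall
  (W = c0/2 (e^Q − 1) + κ/2 (J−1)²) on quadratic tetrahedra, Newmark-beta
  dynamics with Rayleigh damping (α_R = 100 s⁻¹, β_R = 0.04 s), frictionless
  penalty contact against a rigid pericardial shell, and the unloaded
  reference state estimated from the Klotz-type relation
  V0 = V·(0.6 − 0.006·P).
* **Circulation** — a closed loop of elastance atria, diode valves,
  windkessel arteries and venous compliances, coupled to the FEM cavity by
  iterative pressure–volume matching and calibrated to the 85/125 mmHg
  aortic and 13/20 mmHg pulmonary anchors.
* **Forward ECG** — per-element equivalent dipoles −σ_i∇V_m·vol evaluated in
  the *deformed* configuration, an infinite homogeneous conductor, and
  standard leads against Wilson's central terminal; the analysis protocol
  replays the dynamic V_m history on geometries frozen at the end-diastatic
  (0 ms), end-diastolic (150 ms) and end-systolic (400 ms) instants and
  tabulates T-wave amplitude and end-of-T-wave differences.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
from cardioem.pipeline import HeartSimulation, RunConfig

sim = HeartSimulation(RunConfig())   # idealized LV, 850 ms cycle (~70 bpm)
sim.build()                          # meshes, CV + gKs calibration, mapping
sim.initialize()                     # unloaded state, Klotz target, ramp
hist = sim.run_beat()                # one fully coupled beat
print(f"EF = {sim.lv_ejection_fraction():.1f} %")
print(" -> ".join(sim.phase_sequence()))

dyn, cases, table = sim.run_comparison(hist)
print(table.to_frame().head(3).to_string(index=False))
```

prints (one CPU, ≈ 10 minutes end to end):

```
EF = 54.6 %
atrial_contraction -> isovolumetric_contraction -> ejection -> isovolumetric_relaxation -> relaxation
lead  dynamic_mV  dynamic_t_end_ms  end_diastatic_pct ...
```

The ejection fraction is the fraction of end-diastolic volume ejected over
the beat; the phase line is the five-phase cardiac cycle recovered from the
valve states; the table rows give, per standard lead, the dynamic-case
T-wave amplitude and, for each frozen geometry, its T-wave amplitude as a
percentage of the dynamic one and its end-of-T-wave shift in ms.  The
geometry frozen at end-systole (where the T wave happens) tracks the
dynamic T wave most closely, while the geometries frozen early in the beat
deviate most during the T wave and least during the QRS complex — the
central moving-source effect the package is built to expose.

The same functionality is available from a shell:

```bash
cardioem klotz 142 7.3            # unloaded-volume target: 78 mL
cardioem calibrate-cv --dx 0.7    # conductivities for 800/550 mm/s
cardioem beat --out out/          # coupled beat, PV traces + Vm history
cardioem compare --out out/       # four-case ECG comparison tables
```

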