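# Methods

## Model

The epithelium is a single well-stirred intracellular compartment of
volume Cv between two identically composed baths, voltage-clamped so
that both membranes sit at the same potential V (intracellular minus
extracellular) and the transepithelial PD is zero. Three Cl⁻ pathways
connect the compartment to the baths: apical channels (whole-tissue
conductance G_A), basolateral channels (G_B), and an electro-neutral
basolateral uptake carrier whose flux is J_C = j·CT_Act.

Each conductive pathway carries the chord-conductance current

    I = G·V·(cl_in − cl_out·e^u) / (cl_out·(1 − e^u)),  u = F·V/(R·T),

normalised so that G is the conductance measured at the reference
condition and I vanishes exactly at the Cl⁻ equilibrium concentration
cl_out·e^u. Internally a secretory (cell-to-lumen) current is negative;
a single conversion (`to_display_current`) flips the sign for all
user-facing traces so that secretion plots positive, matching how I_sc
is conventionally reported. The V→0 removable singularity is served by
a dedicated limit operation, −G·(RT/F)·(cl_in−cl_out)/cl_out.

The transporter is a two-state system: inactive ⇌ active with rate
constants α (activation) and β (inactivation), so the active amount
relaxes mono-exponentially to α·CT_T/(α+β) with τ₂ = 1/(α+β), and
CT_Act + CT_Inact = CT_T is conserved identically. The uptake flux is
taken independent of [Cl⁻]ᵢ and of V — a deliberate simplification:
the carrier's dominant driving force is the transmembrane Na⁺ gradient,
which the protocols here do not perturb. This is also the model's main
known limitation (see below).

Mass balance, Cv·df/dt = J_C − J_A − J_B, is then a linear ODE with

    τ₁ = Cv·F·(e^u − 1)·cl_out / (V·(G_A + G_B))       (> 0 for V ≠ 0)
    f(∞) = cl_out·e^u + J_C(∞)·τ₁/Cv

and closed-form solution

    f(t) = f(∞) + A₁·e^(−t/τ₁) + A₂·e^(−t/τ₂),
    A₂ = (j·ΔCT/Cv)·τ₁τ₂/(τ₂ − τ₁),   ΔCT = CT_Act(0) − CT_Act(∞),
    A₁ = f(0) − f(∞) − A₂,

with f(0) continuous across the stimulus step (concentrations cannot
jump; currents can). When τ₁ = τ₂ to 1e-10 relative the solver switches
to the confluent form (j·ΔCT/Cv)·t·e^(−t/τ) and logs the switch.

Two consequences carry the interpretive weight. At t = 0⁺, with V
fixed, I_A(0⁺)/I_A0 = G_A/G_A0 exactly — the jump sees only the apical
conductance. At steady state I_A(∞) = −F·J_C·G_A/(G_A+G_B) — the
steady current is the uptake flux split across the conductance ratio,
independent of V. Inverting the latter at two steady states yields the
activation estimator

    J_C(∞)/J_C0 = [I_A∞·(G_A∞+G_B∞)/G_A∞] / [I_A0·(G_A0+G_B0)/G_A0].

## Parameters, units, defaults

SI units internally (V, S, m³, mol/m³ ≡ mM, s, whole-tissue A); display
quantities are μA/cm² and μS. Defaults describe the A6 renal monolayer
preparation:

| parameter | default | meaning |
|---|---|---|
| Cv | 5.0e-10 m³ | total secreting cell volume on the support |
| area | 0.33 cm² | tissue area of the permeable support |
| [Cl⁻]ₒ | 127.5 mM | bath Cl⁻ (120 NaCl + 3.5 KCl + 1 CaCl₂ + 1 MgCl₂) |
| T | 297.8 K | in the 24–25 °C amphibian band; makes e^{FV/RT} = 0.2104 at −40 mV and 0.0654 at −70 mV |
| G_A0 | 12.87 μS | measured baseline apical Cl⁻ conductance |
| G_B0/G_A0 | 30 | stylized baseline ratio for canned scenarios (the measured 360.00/12.87 ≈ 28.0 is used where a printed result requires it) |
| V0 | −40 mV | baseline membrane potential |
| I_A0 | 0.08 μA/cm² | measured baseline secretion, sets the absolute scale |

These defaults put τ₁ at ~5.4 min at baseline and [Cl⁻]ᵢ at ~32 mM,
i.e. well above the −40 mV equilibrium concentration of ~26.8 mM, as an
actively secreting cell must be.

Scenario builders express stimuli as relative changes (G_A/G_A0,
G_B/G_B0, J_C(∞)/J_C0, V); the baseline uptake flux is back-computed
from I_A0 through the steady-state identity, so every protocol starts
at an exact steady state. τ₂ is not constrained by any printed value;
scenarios with transporter kinetics default to τ₂ = 10·τ₁ — honouring
the model's τ₂ ≫ τ₁ separation while keeping simulations short — and
expose it as a parameter. Horizons default to 20·max(τ₁, τ₂), long
enough that trace-end levels agree with the closed-form steady ratios
to < 1e-6.

## Numerical choices

* The ODE twin (`simulate`) integrates the same right-hand side with
  LSODA at rtol 1e-11 / atol 1e-12; integration starts exactly at the
  step time from the continuous initial condition, so the conductance
  discontinuity is never smoothed across. Default grids carry samples
  on both sides of t = 0 to make the current jump representable.
  Analytic and numeric [Cl⁻]ᵢ agree to ~1e-11 relative on all canned
  scenarios (tested bound 1e-8).
* Biexponential fitting initializes by log-linear peeling: the
  asymptote is the mean of the final 10% of samples; the slow
  component is fitted on a window from just after the trace's last
  extremum to where the smoothed residual sinks below max(3·tail-noise,
  1e-3·amplitude); the fast component on the pre-extremum residual.
  A Levenberg–Marquardt refinement (log-parameterized time constants,
  enforcing positivity) follows; τ₁ < τ₂ by ordering. Degenerate traces
  collapse explicitly: constant → zero amplitudes, one component →
  single-exponential model with A₂ = 0. Non-convergence is reported in
  the result status, never silently.
* Steady levels are read from a trace as the mean of the final 10% of
  samples, rejected if the tail slope is both statistically significant
  (|t| > 3) and practically meaningful (> 1 ppm of the level across the
  window).
* The estimator accepts currents in either sign convention (using
  magnitudes) and logs the convention it detected. An optional
  first-order delta-method confidence interval propagates stated
  fractional noise on currents and conductances; it is an extension,
  not part of the core estimator.

## Synthetic data

The generators emulate the two raw-data shapes the pipeline consumes:
secretion traces (closed-form solution plus multiplicative Gaussian
noise on the currents; [Cl⁻]ᵢ is left clean since it is not measured)
and PD recordings with +1 μA, 0.5 s pulses every 10 s whose square
deflections ΔPD = I/G ride on additive Gaussian noise. Default noise
levels used in tests — 1% on currents, 5% on conductances, 0.05–0.5 mV
on PD — reflect the relative SEMs of the measured table. All
randomness flows from one explicit integer seed; noise without a seed
is refused. What the synthetic data does **not** emulate: baseline
drift, pulse-edge capacitive transients, pump-current contributions,
permeabilization artifacts, or correlated noise — so passing recovery
tests demonstrate correctness of the inference pipeline under the
model's own assumptions, not robustness to every artifact of live
recordings. Experimentally recorded traces are wet-lab data and are
not reproduced quantitatively; scenario simulations match them in
shape (jump/dip/rise structure), which is the model's claim.

## Design choices

* The chord-conductance current form is adopted as the unique form
  simultaneously consistent with the τ₁ expression, the printed
  steady-state fold-changes, and the worked voltage-step evaluation;
  all of those anchors are pinned in tests.
* Membrane areas are absorbed into whole-tissue conductances;
  per-area quantities divide by the support area.
* V is an exogenous protocol parameter (the short-circuit clamp makes
  it so), never solved from charge balance.
* The `forskolin_full` scenario uses the measured baseline conductance
  ratio (≈28.0) rather than the stylized 30, because its printed
  steady fold (~79) is only consistent with the measured ratio; the
  simulated value is 78.1 and is treated as approximate.
* Trace files are plain TSV with a `#` key=value metadata header — no
  domain standard exists for Ussing traces; this is greppable and
  round-trips floats exactly.

## Limitations

* J_C independent of [Cl⁻]ᵢ: in reality NKCC activity falls as
  intracellular Cl⁻ rises; over large uptake activations the model
  will overestimate the steady [Cl⁻]ᵢ rise.
* Single V for both membranes and no paracellular pathway: valid only
  under short circuit with identical baths.
* No Na⁺/K⁺ bookkeeping, pump currents, or cell-volume dynamics.
* The activation estimator assumes both measurement epochs are true
  steady states at the same V; drifting tails violate its premise (the
  steady-level reader refuses them).
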