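"""Conductance from a constant-current pulse train.

Emulates the standard Ussing-chamber protocol — a +1 uA, 0.5 s pulse
every 10 s — on a synthetic PD recording with additive noise, extracts
the per-pulse PD deflections, and recovers the conductance by Ohm's
law (G = I / dPD).
"""

import clsecretion as cs
from clsecretion.synth import generate_pulse_recording

g_true = 12.87e-6  # S: the baseline apical Cl- conductance
rec, truth = generate_pulse_recording(
    g_true, n_pulses=30, noise_sd=0.5, seed=7
)

deflections = cs.extract_pulse_deflections(rec)
g_hat = cs.conductance_from_pulse(deflections.mean())

print(f"true deflection : {truth['deflection_true_mV']:.2f} mV per 1 uA pulse")
print(f"mean measured   : {deflections.mean():.2f} mV over {len(deflections)} pulses")
print(f"G recovered     : {g_hat * 1e6:.2f} uS (true {g_true * 1e6:.2f} uS)")
print(
    "\nSubtracting the conductance after a Cl--channel blocker from the one\n"
    "before it (nppb_sensitive_conductance) isolates the membrane's Cl-\n"
    "component of this total."
)
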