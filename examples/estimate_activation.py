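"""Estimate electro-neutral transporter (NKCC1) activation from the six
Ussing-chamber measurables.

An electro-neutral carrier moves no net charge, so no conductance
measurement can see it.  But at a steady state the uptake flux equals
the total Cl- efflux, of which the apical current is the measurable
fraction G_A/(G_A + G_B) — so two currents and four blocker-sensitive
conductances pin down the fold-change in uptake.
"""

import clsecretion as cs

# measured values: baseline and forskolin-stimulated currents (uA/cm^2)
# and NPPB-sensitive conductances (uS)
m = cs.UssingMeasurement(
    i_a0=0.08, i_a_inf=6.40,
    g_a0=12.87, g_b0=360.00,
    g_a_inf=689.04, g_b_inf=480.47,
)

ratio = cs.estimate_transporter_activation(m)
lo, hi = cs.activation_confidence_interval(m, sigma_current_frac=0.01,
                                           sigma_conductance_frac=0.05)

print(f"J_C(inf)/J_C0 = {ratio:.3g}")
print(f"95% CI (1% current / 5% conductance noise): [{lo:.2f}, {hi:.2f}]")
print(
    "\nThe stimulated epithelium takes up Cl- about 4.7x faster than at\n"
    "baseline, even though the transporter itself is invisible to the\n"
    "voltage clamp."
)
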