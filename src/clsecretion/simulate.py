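"""Numerical integration of the Cl- mass-balance ODE.

Serves as the independent numerical twin of the closed-form solution in
:mod:`clsecretion.model`: the same right-hand side is handed to a
general-purpose stiff-capable integrator, with integration restarted at
the protocol's step time so the conductance/potential discontinuity is
never smoothed across.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    InvalidInputError,
    NumericalError,
    PathwayState,
    SecretionTrace,
    StepProtocol,
    TissueParams,
    TransporterParams,
    build_trace,
    current_to_molar_flux,
    default_grid,
    membrane_current,
    membrane_current_v0_limit,
    steady_state_cl,
    transporter_timecourse,
    uptake_flux,
)

__all__ = ["SolverOptions", "ode_rhs", "integrate_protocol"]


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and method for the ODE integrator."""

    rel_tol: float = 1e-11
    abs_tol: float = 1e-12
    max_step: float = np.inf
    method: str = "LSODA"

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol"):
            v = getattr(self, name)
            if not (0 < v <= 1e-2):
                raise InvalidInputError(f"{name} must lie in (0, 1e-2], got {v}")


def ode_rhs(
    t: float,
    cl_in: float | np.ndarray,
    tissue: TissueParams,
    state: PathwayState,
    transporter: tuple[TransporterParams, float],
) -> float | np.ndarray:
    """d[Cl-]i/dt = (J_C(t) - J_A - J_B)/Cv in mM/s.

    ``transporter`` is (params, ct_act_0): the kinetics and the active
    amount at t = 0, from which CT_Act(t) and hence J_C(t) follow.
    Linear in cl_in at fixed t.
    """
    cl = np.asarray(cl_in, dtype=float)
    if np.any(cl < 0):
        raise InvalidInputError("cl_in went negative: model breakdown")
    params, ct_act_0 = transporter
    j_c = uptake_flux(params, transporter_timecourse(params, ct_act_0, t))
    if state.v_membrane == 0:
        i_total = membrane_current_v0_limit(
            state.g_total, cl, tissue.cl_out, tissue.temperature
        )
    else:
        i_total = membrane_current(
            state.g_total, state.v_membrane, cl, tissue.cl_out, tissue.temperature
        )
    j_out = current_to_molar_flux(i_total)  # J_A + J_B, mol/s
    return (j_c - j_out) / tissue.cell_volume


def integrate_protocol(
    tissue: TissueParams,
    protocol: StepProtocol,
    grid: np.ndarray | None = None,
    opts: SolverOptions | None = None,
) -> SecretionTrace:
    """Integrate the protocol numerically on ``grid`` (defaults to
    :func:`clsecretion.model.default_grid`).

    Samples at t < 0 sit at the pre-stimulus steady state; the
    integration starts exactly at the step time from the continuous
    initial condition, so the current jump at t = 0 is event-exact.
    """
    if opts is None:
        opts = SolverOptions()
    if grid is None:
        grid = default_grid(protocol.horizon)
    t = np.asarray(grid, dtype=float)
    if t.size and t[-1] > protocol.horizon * (1 + 1e-12):
        raise InvalidInputError("grid extends beyond the protocol horizon")

    f0 = steady_state_cl(tissue, protocol.pre, protocol.jc_pre)
    tp = t[t >= 0]
    if tp.size == 0 or tp[-1] == 0.0:
        cl_post = np.full(tp.shape, f0)
        return build_trace(tissue, protocol, t, cl_post)

    sol = solve_ivp(
        ode_rhs,
        (0.0, tp[-1]),
        [f0],
        t_eval=tp,
        method=opts.method,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
        max_step=opts.max_step,
        args=(tissue, protocol.post, (protocol.transporter, protocol.ct_act_pre)),
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    return build_trace(tissue, protocol, t, sol.y[0])
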