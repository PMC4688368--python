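"""Core kinetic model of transcellular Cl- secretion.

The epithelium is reduced to a single well-stirred intracellular
compartment exchanging Cl- with identical apical and basolateral baths
through three pathways:

* pathway A — apical Cl- channels (conductance ``G_A``), the secretory
  efflux;
* pathway B — basolateral Cl- channels (``G_B``), a recycling back-flux;
* pathway C — an electro-neutral basolateral uptake carrier (NKCC1-like),
  carrying a flux ``J_C = j * CT_Act`` proportional to the amount of
  transporter in its active conformation.

Under short circuit both membranes see the same potential ``V`` and the
same bath concentration ``[Cl-]o``.  Each conductive pathway carries a
chord-conductance current

    I = G * V * (cl_in - cl_out * e^u) / (cl_out * (1 - e^u)),
    u = F * V / (R * T),

which vanishes at the Cl- equilibrium concentration ``cl_out * e^u`` and
is normalised so that ``G`` is the conductance measured at the reference
condition.  In this internal convention a secretory (cell-to-lumen)
current is negative; user-facing traces flip the sign once, in
:func:`to_display_current`, so that secretion plots positive.

The transporter interconverts between inactive and active forms with
first-order rate constants ``alpha`` (activation) and ``beta``
(inactivation), giving a mono-exponential approach of ``CT_Act`` to its
fixed point with time constant ``tau2 = 1/(alpha+beta)``.  Mass balance
on intracellular Cl- is then a linear ODE whose solution is the
biexponential

    f(t) = f(inf) + A1 * exp(-t/tau1) + A2 * exp(-t/tau2),

with the fast time constant ``tau1`` set by cell volume and total
conductance, and the slow one by transporter kinetics.  All of that is
closed-form and implemented here; the numerical twin lives in
:mod:`clsecretion.simulate`.

Units are SI throughout this module (V, S, m^3, mol/m^3 == mM, s, A
whole-tissue); per-area display quantities (uA/cm^2) are produced only
by :func:`to_display_current` and the trace builder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    DEFAULT_AREA_CM2,
    DEFAULT_CELL_VOLUME,
    DEFAULT_CL_OUT,
    DEFAULT_TEMPERATURE,
    FARADAY,
    GAS_CONSTANT,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidInputError",
    "NumericalError",
    "TissueParams",
    "PathwayState",
    "TransporterParams",
    "StepProtocol",
    "SecretionTrace",
    "boltzmann_factor",
    "cl_equilibrium",
    "membrane_current",
    "membrane_current_v0_limit",
    "cl_in_from_current",
    "current_to_molar_flux",
    "to_display_current",
    "transporter_timecourse",
    "uptake_flux",
    "tau_cl",
    "steady_state_cl",
    "steady_state_current_ratio",
    "instantaneous_current",
    "analytic_solution",
    "default_grid",
]


class InvalidInputError(ValueError):
    """Raised when an argument violates a model precondition."""


class NumericalError(RuntimeError):
    """Raised when a numerical routine fails to produce a valid result."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Physical scale of the preparation.

    Parameters
    ----------
    cell_volume : float
        Total volume of the secreting cell mass, m^3 (symbol Cv).
    area : float
        Tissue area over which whole-tissue conductances were measured,
        cm^2.
    cl_out : float
        Bath Cl- concentration, identical on both sides under short
        circuit, mol/m^3 (numerically mM).
    temperature : float
        Absolute temperature, K.
    """

    cell_volume: float = DEFAULT_CELL_VOLUME
    area: float = DEFAULT_AREA_CM2
    cl_out: float = DEFAULT_CL_OUT
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("cell_volume", "area", "cl_out", "temperature"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be finite and > 0, got {v}")
        if not (270.0 <= self.temperature <= 330.0):
            raise InvalidInputError(
                f"temperature {self.temperature} K outside physiological band [270, 330]"
            )


@dataclass(frozen=True)
class PathwayState:
    """Whole-tissue conductances and clamped potential at one epoch.

    ``v_membrane`` is intracellular minus extracellular; both membranes
    share it under short circuit.
    """

    g_apical: float
    g_basolateral: float
    v_membrane: float

    def __post_init__(self) -> None:
        if self.g_apical < 0 or self.g_basolateral < 0:
            raise InvalidInputError("conductances must be non-negative")
        if self.g_apical + self.g_basolateral <= 0:
            raise InvalidInputError("total conductance must be positive")
        if not math.isfinite(self.v_membrane):
            raise InvalidInputError("v_membrane must be finite")

    @property
    def g_total(self) -> float:
        return self.g_apical + self.g_basolateral


@dataclass(frozen=True)
class TransporterParams:
    """Two-state (inactive <-> active) transporter kinetics.

    ``alpha`` activates, ``beta`` inactivates (both s^-1);
    ``flux_per_unit`` (symbol j) is the Cl- flux carried per unit of
    active transporter, mol/s per amount unit.  The uptake flux is
    ``j * CT_Act`` and, by deliberate model simplification, independent
    of intracellular Cl- and of V.
    """

    ct_total: float
    alpha: float
    beta: float
    flux_per_unit: float

    def __post_init__(self) -> None:
        if self.ct_total <= 0:
            raise InvalidInputError("ct_total must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("rate constants must be >= 0")
        if self.flux_per_unit < 0:
            raise InvalidInputError("flux_per_unit must be >= 0")

    @property
    def ct_act_inf(self) -> float:
        """Fixed point alpha*CT_T/(alpha+beta) of the activation kinetics."""
        if self.alpha + self.beta == 0:
            raise InvalidInputError("alpha + beta must be > 0 for a time course")
        return self.alpha * self.ct_total / (self.alpha + self.beta)

    @property
    def tau2(self) -> float:
        """Relaxation time 1/(alpha+beta) of the active amount."""
        if self.alpha + self.beta == 0:
            raise InvalidInputError("alpha + beta must be > 0 for a time course")
        return 1.0 / (self.alpha + self.beta)


@dataclass(frozen=True)
class StepProtocol:
    """A pre-stimulus steady epoch followed by a step at t = 0.

    The pre epoch is fully determined by ``pre`` and the uptake flux
    ``flux_per_unit * ct_act_pre`` (the transporter's pre-stimulus
    active amount).  At t = 0 the conductances/potential switch to
    ``post`` and the transporter relaxes from ``ct_act_pre`` toward the
    fixed point of ``transporter`` with time constant tau2.
    """

    pre: PathwayState
    post: PathwayState
    transporter: TransporterParams
    ct_act_pre: float
    horizon: float
    step_time: float = 0.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise InvalidInputError("horizon must be > 0")
        if self.step_time != 0.0:
            raise InvalidInputError("step_time is fixed at 0")
        if not (0.0 <= self.ct_act_pre <= self.transporter.ct_total):
            raise InvalidInputError("ct_act_pre must lie in [0, ct_total]")

    @property
    def jc_pre(self) -> float:
        """Pre-stimulus uptake flux J_C0 (mol/s)."""
        return self.transporter.flux_per_unit * self.ct_act_pre

    @property
    def jc_inf(self) -> float:
        """Post-stimulus steady uptake flux J_C(inf) (mol/s)."""
        return self.transporter.flux_per_unit * self.transporter.ct_act_inf


@dataclass(frozen=True)
class SecretionTrace:
    """Time series of intracellular Cl- and pathway currents.

    Currents are per tissue area in uA/cm^2 in the display convention
    (secretion positive); ``i_uptake`` is the electro-neutral uptake
    expressed as the equivalent current F*J_C/area.
    """

    t: np.ndarray
    cl_in: np.ndarray
    i_apical: np.ndarray
    i_basolateral: np.ndarray
    i_uptake: np.ndarray

    def __post_init__(self) -> None:
        arrays = (self.t, self.cl_in, self.i_apical, self.i_basolateral, self.i_uptake)
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise InvalidInputError("all trace arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if np.any(self.cl_in <= 0):
            raise InvalidInputError("cl_in must be positive everywhere")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def boltzmann_factor(v_membrane: float, temperature: float) -> float:
    """exp(F*V/(R*T)) — the Boltzmann factor for a monovalent anion's
    equilibrium distribution across a membrane at potential V."""
    if not (math.isfinite(v_membrane) and math.isfinite(temperature)):
        raise InvalidInputError("v_membrane and temperature must be finite")
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0")
    return math.exp(FARADAY * v_membrane / (GAS_CONSTANT * temperature))


def cl_equilibrium(cl_out: float, v_membrane: float, temperature: float) -> float:
    """Intracellular Cl- concentration at which the membrane current is
    exactly zero: cl_out * exp(F*V/(R*T))."""
    if cl_out < 0:
        raise InvalidInputError("cl_out must be >= 0")
    return cl_out * boltzmann_factor(v_membrane, temperature)


def membrane_current(
    g: float,
    v_membrane: float,
    cl_in: float | np.ndarray,
    cl_out: float,
    temperature: float,
) -> float | np.ndarray:
    """Chord-conductance Cl- current through one membrane (A, whole tissue).

    I = G*V*(cl_in - cl_out*e^u)/(cl_out*(1 - e^u)) with u = F*V/(R*T).
    Internal sign convention: secretory (outward Cl-) current is
    negative.  The removable V = 0 singularity is served by
    :func:`membrane_current_v0_limit`.
    """
    if cl_out <= 0:
        raise InvalidInputError("cl_out must be > 0")
    if np.any(np.asarray(cl_in) < 0):
        raise InvalidInputError("cl_in must be non-negative")
    if g < 0:
        raise InvalidInputError("conductance must be >= 0")
    if v_membrane == 0:
        raise InvalidInputError(
            "V = 0 is a removable singularity; use membrane_current_v0_limit"
        )
    e_u = boltzmann_factor(v_membrane, temperature)
    return g * v_membrane * (cl_in - cl_out * e_u) / (cl_out * (1.0 - e_u))


def membrane_current_v0_limit(
    g: float, cl_in: float | np.ndarray, cl_out: float, temperature: float
) -> float | np.ndarray:
    """Analytic V -> 0 limit of :func:`membrane_current`:
    -g*(R*T/F)*(cl_in - cl_out)/cl_out."""
    if cl_out <= 0:
        raise InvalidInputError("cl_out must be > 0")
    if np.any(np.asarray(cl_in) < 0):
        raise InvalidInputError("cl_in must be non-negative")
    if g < 0:
        raise InvalidInputError("conductance must be >= 0")
    return -g * (GAS_CONSTANT * temperature / FARADAY) * (cl_in - cl_out) / cl_out


def cl_in_from_current(
    g: float, v_membrane: float, i: float, cl_out: float, temperature: float
) -> float:
    """Invert the chord current for the intracellular concentration that
    produces current ``i`` (A, internal sign) at the given state."""
    if g <= 0:
        raise InvalidInputError("conductance must be > 0 to invert")
    if v_membrane == 0:
        # invert the V->0 limit instead
        return cl_out - i * cl_out * FARADAY / (g * GAS_CONSTANT * temperature)
    e_u = boltzmann_factor(v_membrane, temperature)
    return cl_out * e_u + i * cl_out * (1.0 - e_u) / (g * v_membrane)


def current_to_molar_flux(i: float | np.ndarray) -> float | np.ndarray:
    """Convert a Cl- current (A, internal sign) to a molar efflux
    (mol/s): J = -I/F, so secretory (negative) currents map to positive
    effluxes."""
    return -np.asarray(i) / FARADAY if isinstance(i, np.ndarray) else -i / FARADAY


def to_display_current(i: float | np.ndarray, area_cm2: float) -> float | np.ndarray:
    """Convert an internal whole-tissue current (A, secretion negative)
    to the display convention: uA/cm^2, secretion positive.

    This is the single place the sign flip happens.
    """
    if area_cm2 <= 0:
        raise InvalidInputError("area must be > 0")
    return -np.asarray(i) * 1e6 / area_cm2 if isinstance(i, np.ndarray) else -i * 1e6 / area_cm2


def transporter_timecourse(
    params: TransporterParams, ct_act_0: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Active transporter amount CT_Act(t) relaxing from ``ct_act_0``
    toward the fixed point with time constant tau2 = 1/(alpha+beta)."""
    if not (0.0 <= ct_act_0 <= params.ct_total):
        raise InvalidInputError("ct_act_0 must lie in [0, ct_total]")
    ct_inf = params.ct_act_inf
    return ct_inf + (ct_act_0 - ct_inf) * np.exp(-(params.alpha + params.beta) * np.asarray(t))


def uptake_flux(params: TransporterParams, ct_act: float | np.ndarray) -> float | np.ndarray:
    """Electro-neutral uptake flux J_C = j * CT_Act (mol/s); independent
    of intracellular Cl- and V by model assumption."""
    if np.any(np.asarray(ct_act) < 0):
        raise InvalidInputError("ct_act must be >= 0")
    return params.flux_per_unit * np.asarray(ct_act) if isinstance(ct_act, np.ndarray) else params.flux_per_unit * ct_act


def tau_cl(tissue: TissueParams, state: PathwayState) -> float:
    """Fast relaxation time tau1 of intracellular Cl-:

    tau1 = Cv*F*(e^u - 1)*[Cl-]o / (V*(G_A + G_B)),

    strictly positive for any V != 0 (the factors (e^u - 1) and V share
    a sign)."""
    if state.g_total <= 0:
        raise InvalidInputError("total conductance must be > 0")
    v = state.v_membrane
    if v == 0:
        # V->0 limit: tau1 = Cv*F^2*[Cl-]o/(R*T*(G_A+G_B))
        return (
            tissue.cell_volume
            * FARADAY**2
            * tissue.cl_out
            / (GAS_CONSTANT * tissue.temperature * state.g_total)
        )
    e_u = boltzmann_factor(v, tissue.temperature)
    return tissue.cell_volume * FARADAY * (e_u - 1.0) * tissue.cl_out / (v * state.g_total)


def steady_state_cl(tissue: TissueParams, state: PathwayState, j_c: float) -> float:
    """Steady intracellular Cl- at constant uptake flux ``j_c`` (mol/s):
    the root of J_A + J_B = J_C, i.e. cl_out*e^u + J_C*tau1/Cv."""
    if j_c < 0:
        raise InvalidInputError("j_c must be >= 0")
    eq = cl_equilibrium(tissue.cl_out, state.v_membrane, tissue.temperature)
    return eq + j_c * tau_cl(tissue, state) / tissue.cell_volume


def steady_state_current_ratio(
    ga_rel: float, gb_rel: float, gb0_over_ga0: float, jc_rel: float = 1.0
) -> float:
    """Steady-state apical current fold-change I_A(inf)/I_A0 for relative
    conductance changes at fixed V.

    At a steady state the apical current is the fraction
    G_A/(G_A + G_B) of the uptake flux, so

        I_A(inf)/I_A0 = jc_rel * [ga_rel/(ga_rel + gb_rel*r)] * (1 + r),

    with r = G_B0/G_A0.  Equal relative changes in both conductances
    with unchanged uptake leave the steady current unchanged.
    """
    for name, v in (
        ("ga_rel", ga_rel),
        ("gb_rel", gb_rel),
        ("gb0_over_ga0", gb0_over_ga0),
        ("jc_rel", jc_rel),
    ):
        if v <= 0:
            raise InvalidInputError(f"{name} must be > 0")
    return jc_rel * (ga_rel / (ga_rel + gb_rel * gb0_over_ga0)) * (1.0 + gb0_over_ga0)


def instantaneous_current(
    state_pre: PathwayState,
    state_post: PathwayState,
    tissue: TissueParams,
    i_a0: float,
) -> float:
    """Apical current I_A(0+) immediately after a conductance/potential
    step, in uA/cm^2 with the internal sign convention (``i_a0`` must be
    given in the same convention, e.g. -0.08 for a baseline secretion of
    0.08 uA/cm^2).

    Intracellular Cl- is continuous across the step, so with V unchanged
    I_A(0+)/I_A0 = G_A/G_A0 exactly; with V changed the chord current is
    re-evaluated at the old concentration and the new potential.
    """
    if i_a0 == 0:
        raise InvalidInputError("i_a0 must be nonzero")
    i_total = i_a0 * 1e-6 * tissue.area  # whole-tissue A
    cl0 = cl_in_from_current(
        state_pre.g_apical, state_pre.v_membrane, i_total, tissue.cl_out, tissue.temperature
    )
    if state_post.v_membrane == 0:
        i_post = membrane_current_v0_limit(
            state_post.g_apical, cl0, tissue.cl_out, tissue.temperature
        )
    else:
        i_post = membrane_current(
            state_post.g_apical, state_post.v_membrane, cl0, tissue.cl_out, tissue.temperature
        )
    return i_post * 1e6 / tissue.area


# ---------------------------------------------------------------------------
# closed-form solution
# ---------------------------------------------------------------------------

#: Fraction of the horizon shown before the step in default grids.
_PRE_FRACTION = 0.05


def default_grid(horizon: float, n: int = 600) -> np.ndarray:
    """Default sample grid: a short pre-stimulus tail plus ``n`` points
    over [0, horizon], with an exact sample at t = 0 so the
    instantaneous jump is representable."""
    if horizon <= 0:
        raise InvalidInputError("horizon must be > 0")
    pre = np.linspace(-_PRE_FRACTION * horizon, 0.0, max(2, n // 20), endpoint=False)
    post = np.linspace(0.0, horizon, n)
    return np.concatenate([pre, post])


def _membrane_current_any_v(g, v, cl_in, cl_out, temperature):
    if v == 0:
        return membrane_current_v0_limit(g, cl_in, cl_out, temperature)
    return membrane_current(g, v, cl_in, cl_out, temperature)


def build_trace(
    tissue: TissueParams,
    protocol: StepProtocol,
    t: np.ndarray,
    cl_post: np.ndarray,
) -> SecretionTrace:
    """Assemble a SecretionTrace from post-step concentrations.

    ``cl_post`` holds [Cl-]i at the grid points with t >= 0; samples at
    t < 0 sit at the pre-stimulus steady state.
    """
    t = np.asarray(t, dtype=float)
    pre_mask = t < 0
    f0 = steady_state_cl(tissue, protocol.pre, protocol.jc_pre)
    cl = np.empty_like(t)
    cl[pre_mask] = f0
    cl[~pre_mask] = cl_post

    i_ap = np.empty_like(t)
    i_bas = np.empty_like(t)
    i_up = np.empty_like(t)
    tr = protocol.transporter
    for mask, state in ((pre_mask, protocol.pre), (~pre_mask, protocol.post)):
        if not np.any(mask):
            continue
        i_ap[mask] = _membrane_current_any_v(
            state.g_apical, state.v_membrane, cl[mask], tissue.cl_out, tissue.temperature
        )
        i_bas[mask] = _membrane_current_any_v(
            state.g_basolateral, state.v_membrane, cl[mask], tissue.cl_out, tissue.temperature
        )
    jc = np.where(
        pre_mask,
        protocol.jc_pre,
        uptake_flux(tr, transporter_timecourse(tr, protocol.ct_act_pre, np.clip(t, 0.0, None))),
    )
    i_up = FARADAY * jc  # A, positive uptake

    area = tissue.area
    return SecretionTrace(
        t=t,
        cl_in=cl,
        i_apical=to_display_current(i_ap, area),
        i_basolateral=to_display_current(i_bas, area),
        i_uptake=np.asarray(i_up) * 1e6 / area,
    )


def analytic_solution(
    tissue: TissueParams,
    protocol: StepProtocol,
    t_grid: np.ndarray | None = None,
) -> SecretionTrace:
    """Closed-form biexponential solution of the post-step relaxation.

    f(t) = f(inf) + A1*exp(-t/tau1) + A2*exp(-t/tau2) with
    A2 = (j*dCT/Cv)*tau1*tau2/(tau2 - tau1), dCT = CT_Act(0) - CT_Act(inf),
    and A1 fixed by continuity of [Cl-]i at the step.  When tau1 and
    tau2 coincide (to 1e-10 relative) the confluent form
    (j*dCT/Cv)*t*exp(-t/tau) replaces the second exponential.
    """
    if t_grid is None:
        t_grid = default_grid(protocol.horizon)
    t = np.asarray(t_grid, dtype=float)
    tr = protocol.transporter

    f0 = steady_state_cl(tissue, protocol.pre, protocol.jc_pre)
    f_inf = steady_state_cl(tissue, protocol.post, protocol.jc_inf)
    tau1 = tau_cl(tissue, protocol.post)
    tau2 = tr.tau2
    d_ct = protocol.ct_act_pre - tr.ct_act_inf
    drive = tr.flux_per_unit * d_ct / tissue.cell_volume  # mM/s amplitude

    tp = t[t >= 0]
    if abs(1.0 - tau1 / tau2) < 1e-10:
        logger.info(
            "tau1 and tau2 coincide (%.6g s); using confluent t*exp(-t/tau) solution", tau1
        )
        a1 = f0 - f_inf
        cl_post = f_inf + a1 * np.exp(-tp / tau1) + drive * tp * np.exp(-tp / tau1)
    else:
        a2 = drive * tau1 * tau2 / (tau2 - tau1)
        a1 = f0 - f_inf - a2
        cl_post = f_inf + a1 * np.exp(-tp / tau1) + a2 * np.exp(-tp / tau2)
    return build_trace(tissue, protocol, t, cl_post)
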