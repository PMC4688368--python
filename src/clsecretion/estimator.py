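"""Measurement-side computations.

Everything an Ussing-chamber experiment provides for the model lives
here: conductance from constant-current pulse deflections (Ohm's law),
blocker-sensitive conductance differencing, the steady-state inversion
that recovers the electro-neutral transporter's fold-activation from six
measurables, and a biexponential fitter for recovering levels and time
constants from (noisy) current traces.

The activation estimator is the practical payoff of the model: an
electro-neutral carrier moves no net charge, so its activity is
invisible to any conductance measurement.  But at a steady state the
apical current is the fraction G_A/(G_A + G_B) of the uptake flux, so

    J_C(inf)/J_C0 = [I_A(inf) * (G_Ainf + G_Binf) / G_Ainf]
                  / [I_A0    * (G_A0  + G_B0 )  / G_A0 ],

which needs only the two currents and the four blocker-sensitive
conductances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .model import InvalidInputError, SecretionTrace

logger = logging.getLogger(__name__)

__all__ = [
    "UssingMeasurement",
    "PulseRecording",
    "BiexpFit",
    "conductance_from_pulse",
    "extract_pulse_deflections",
    "nppb_sensitive_conductance",
    "estimate_transporter_activation",
    "activation_confidence_interval",
    "steady_level",
    "fit_biexponential",
]

MEASUREMENT_FIELDS = ("i_a0", "i_a_inf", "g_a0", "g_b0", "g_a_inf", "g_b_inf")


@dataclass(frozen=True)
class UssingMeasurement:
    """The six measurables consumed by the activation estimator.

    Currents in uA/cm^2 (either sign convention), conductances in uS
    (whole tissue, blocker-sensitive).
    """

    i_a0: float
    i_a_inf: float
    g_a0: float
    g_b0: float
    g_a_inf: float
    g_b_inf: float

    def __post_init__(self) -> None:
        if self.i_a0 == 0:
            raise InvalidInputError("i_a0 must be nonzero")
        for name in ("g_a0", "g_b0", "g_a_inf", "g_b_inf"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class PulseRecording:
    """Transepithelial PD trace with periodic constant-current pulses."""

    t: np.ndarray  # s
    pd: np.ndarray  # mV
    pulse_times: np.ndarray  # pulse onsets, s
    pulse_current: float  # uA
    pulse_width: float = 0.5  # s

    def __post_init__(self) -> None:
        if len(self.t) != len(self.pd):
            raise InvalidInputError("t and pd must have equal length")
        if not np.all(np.isfinite(self.pd)):
            raise InvalidInputError("pd must be finite")
        onsets = np.asarray(self.pulse_times)
        if onsets.size > 1 and np.any(np.diff(onsets) <= self.pulse_width):
            raise InvalidInputError("pulses overlap")


def conductance_from_pulse(delta_pd: float, pulse_current: float = 1.0) -> float:
    """Ohm's-law conductance from a constant-current pulse: G = I/dPD.

    ``delta_pd`` in mV (positive by convention), ``pulse_current`` in
    uA; returns S (uA/mV = mS).
    """
    if delta_pd <= 0:
        raise InvalidInputError("delta_pd must be > 0 (convention: +1 uA pulse raises PD)")
    if pulse_current <= 0:
        raise InvalidInputError("pulse_current must be > 0")
    return pulse_current / delta_pd * 1e-3  # mS -> S


def extract_pulse_deflections(
    rec: PulseRecording, baseline_window: float = 1.0, plateau_window: float = 0.3
) -> np.ndarray:
    """Per-pulse PD deflection: mean over the pulse plateau minus mean
    over the immediately preceding baseline window (mV).

    The plateau window is anchored at the end of the pulse; the baseline
    window ends at pulse onset.  Windows must fit between pulses.
    """
    onsets = np.asarray(rec.pulse_times, dtype=float)
    if onsets.size == 0:
        return np.empty(0)
    if plateau_window > rec.pulse_width:
        raise InvalidInputError("plateau_window exceeds the pulse width")
    gap = np.min(np.diff(onsets)) if onsets.size > 1 else np.inf
    if baseline_window + rec.pulse_width > gap:
        raise InvalidInputError("baseline window overlaps the previous pulse")
    out = np.empty(onsets.size)
    for k, t0 in enumerate(onsets):
        base = (rec.t >= t0 - baseline_window) & (rec.t < t0)
        plat = (rec.t >= t0 + rec.pulse_width - plateau_window) & (
            rec.t < t0 + rec.pulse_width
        )
        if not (base.any() and plat.any()):
            raise InvalidInputError(f"no samples in baseline/plateau window of pulse {k}")
        out[k] = rec.pd[plat].mean() - rec.pd[base].mean()
    return out


def nppb_sensitive_conductance(g_before: float, g_after: float) -> float:
    """Blocker-sensitive conductance g_before - g_after (S), interpreted
    as the membrane's Cl- conductance."""
    if g_after < 0 or g_before < 0:
        raise InvalidInputError("conductances must be >= 0")
    if g_after > g_before:
        raise InvalidInputError(
            "conductance increased after the blocker: negative Cl- conductance "
            "(blocker paradox)"
        )
    return g_before - g_after


def estimate_transporter_activation(m: UssingMeasurement) -> float:
    """Fold-activation J_C(inf)/J_C0 of the electro-neutral transporter
    from the six steady-state measurables.

    Accepts currents in either sign convention (the ratio uses
    magnitudes); the detected convention is logged.
    """
    if (m.i_a0 < 0) != (m.i_a_inf < 0):
        raise InvalidInputError(
            "i_a0 and i_a_inf have opposite signs; mixed conventions?"
        )
    logger.info(
        "currents given in %s convention",
        "internal (secretion negative)" if m.i_a0 < 0 else "display (secretion positive)",
    )
    num = abs(m.i_a_inf) * (m.g_a_inf + m.g_b_inf) / m.g_a_inf
    den = abs(m.i_a0) * (m.g_a0 + m.g_b0) / m.g_a0
    return num / den


def activation_confidence_interval(
    m: UssingMeasurement,
    sigma_current_frac: float,
    sigma_conductance_frac: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """First-order (delta-method) confidence interval for the activation
    ratio under independent multiplicative Gaussian noise on each
    measurable.  An extension beyond the point estimator; assumes small
    relative errors.
    """
    if not (0 < level < 1):
        raise InvalidInputError("level must be in (0, 1)")
    r = estimate_transporter_activation(m)
    s_inf = m.g_a_inf + m.g_b_inf
    s_0 = m.g_a0 + m.g_b0
    # log-sensitivities of the ratio to each conductance
    var_log = 2 * sigma_current_frac**2 + sigma_conductance_frac**2 * (
        2 * (m.g_b_inf / s_inf) ** 2 + 2 * (m.g_b0 / s_0) ** 2
    )
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var_log)
    return r * math.exp(-half), r * math.exp(half)


def steady_level(t: np.ndarray, y: np.ndarray, tail_fraction: float = 0.1) -> float:
    """Steady level of a relaxing trace: mean of the final
    ``tail_fraction`` of samples, required to have a slope statistically
    indistinguishable from zero (|t-stat| < 3)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = max(2, int(round(tail_fraction * len(t))))
    tt, yy = t[-n:], y[-n:]
    A = np.vstack([tt - tt.mean(), np.ones_like(tt)]).T
    coef, res, *_ = np.linalg.lstsq(A, yy, rcond=None)
    dof = n - 2
    if dof > 0 and res.size:
        se = math.sqrt(res[0] / dof / np.sum((tt - tt.mean()) ** 2))
        scale = max(abs(yy.mean()), 1e-30)
        # significant slope AND a practically meaningful drift (> 1 ppm
        # of the level over the window)
        if se > 0 and abs(coef[0]) / se > 3 and abs(coef[0]) * (tt[-1] - tt[0]) > 1e-6 * scale:
            raise InvalidInputError(
                "trace tail still drifting; not at steady state"
            )
    return float(yy.mean())


@dataclass(frozen=True)
class BiexpFit:
    """Result of a biexponential fit y(t) = y_inf + A1 e^{-t/tau1} + A2 e^{-t/tau2}."""

    level_inf: float
    a1: float
    tau1: float
    a2: float
    tau2: float
    rms_residual: float
    success: bool
    message: str = ""


def _peel_exponential(
    t: np.ndarray, r: np.ndarray, thresh: float
) -> tuple[float, float] | None:
    """Log-linear fit of a single decaying component to residuals ``r``.

    Only samples above ``thresh`` in magnitude and before the first sign
    flip are used.  Returns (amplitude at t = 0 of the *original* time
    axis, tau) or None when no consistent decaying component is present.
    """
    idx = np.flatnonzero(np.abs(r) > thresh)
    if idx.size < 3:
        return None
    sign = np.sign(r[idx[0]])
    flips = np.flatnonzero(np.sign(r[idx]) != sign)
    if flips.size:
        idx = idx[: flips[0]]
    if idx.size < 3:
        return None
    coef = np.polyfit(t[idx], np.log(np.abs(r[idx])), 1)
    if coef[0] >= 0:
        return None
    return sign * math.exp(coef[1]), -1.0 / coef[0]


def _smooth(r: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return r
    return np.convolve(r, np.ones(w) / w, mode="same")


def fit_biexponential(
    t: np.ndarray,
    y: np.ndarray,
    init_strategy: str = "peel",
) -> BiexpFit:
    """Least-squares biexponential fit with tau1 < tau2 enforced by
    ordering; deterministic given the data and strategy.

    Initialization is log-linear peeling: the slow tail (second half of
    the samples) is fitted first on a log scale, subtracted, and the
    residual's early part fitted for the fast component; the full
    five-parameter model is then refined by Levenberg-Marquardt.  Traces
    carrying only one (or zero) exponential components collapse to the
    corresponding reduced model with the absent amplitude set to zero.
    Non-convergence is reported through ``success``/``message``, never
    silently.
    """
    if init_strategy != "peel":
        raise InvalidInputError(f"unknown init_strategy {init_strategy!r}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 8:
        raise InvalidInputError("need at least 8 samples for a biexponential fit")
    t = t - t[0]

    n = len(y)
    tail = max(2, n // 10)
    y_inf = np.mean(y[-tail:])
    r = y - y_inf
    scale = max(np.max(np.abs(y)), 1e-30)
    if np.max(np.abs(r)) < 1e-10 * scale:
        return BiexpFit(float(np.mean(y)), 0.0, math.nan, 0.0, math.nan, 0.0, True,
                        "constant trace")

    # locate the slow-fit window: from just after the last extremum of
    # the (lightly smoothed) residual to where it sinks into the noise
    noise = float(np.std(y[-tail:]))
    r_amp = float(np.max(np.abs(r)))
    thresh = max(3.0 * noise, 1e-3 * r_amp)
    rs = _smooth(r, max(1, n // 50))
    above = np.flatnonzero(np.abs(rs) > thresh)
    if above.size < 4:
        return BiexpFit(y_inf, 0.0, math.nan, 0.0, math.nan,
                        float(np.sqrt(np.mean(r**2))), False,
                        "no decaying component found")
    i_end = above[-1]
    d = np.diff(rs[: i_end + 1])
    interior = np.flatnonzero(d[:-1] * d[1:] < 0)
    i_ext = int(interior[-1]) + 1 if interior.size else 0
    lo = i_ext + max(1, (i_end - i_ext) // 3)
    slow = _peel_exponential(t[lo : i_end + 1], r[lo : i_end + 1], thresh)
    if slow is None:
        slow = _peel_exponential(t, r, thresh)
    if slow is None:
        return BiexpFit(y_inf, 0.0, math.nan, 0.0, math.nan,
                        float(np.sqrt(np.mean(r**2))), False,
                        "no decaying component found")
    a_s, tau_s = slow
    r_fast = r - a_s * np.exp(-t / tau_s)
    i_fast = max(8, i_ext if i_ext > 0 else n // 4)
    fast = _peel_exponential(t[:i_fast], r_fast[:i_fast], thresh)

    def biexp(tt, yi, a1, lt1, a2, lt2):
        return yi + a1 * np.exp(-tt / np.exp(lt1)) + a2 * np.exp(-tt / np.exp(lt2))

    def single(tt, yi, a1, lt1):
        return yi + a1 * np.exp(-tt / np.exp(lt1))

    import warnings

    from scipy.optimize import OptimizeWarning

    try:
        if fast is not None and abs(fast[0]) > 1e-6 * abs(a_s) and fast[1] < tau_s:
            p0 = [y_inf, fast[0], math.log(fast[1]), a_s, math.log(tau_s)]
            with warnings.catch_warnings():
                # degenerate covariance is expected when one amplitude -> 0
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(biexp, t, y, p0=p0, maxfev=20000)
            yi, a1, lt1, a2, lt2 = popt
            tau1, tau2 = math.exp(lt1), math.exp(lt2)
            if tau1 > tau2:
                a1, a2, tau1, tau2 = a2, a1, tau2, tau1
        else:
            popt, _ = curve_fit(single, t, y, p0=[y_inf, a_s, math.log(tau_s)],
                                maxfev=20000)
            yi, a1, lt1 = popt
            tau1, tau2, a2 = math.exp(lt1), math.nan, 0.0
            pred = single(t, *popt)
            rms = float(np.sqrt(np.mean((y - pred) ** 2)))
            return BiexpFit(yi, a1, tau1, a2, tau2, rms, True, "single exponential")
    except RuntimeError as exc:  # curve_fit non-convergence
        return BiexpFit(y_inf, math.nan, math.nan, math.nan, math.nan, math.nan,
                        False, f"fit did not converge: {exc}")
    pred = biexp(t, yi, a1, math.log(tau1), a2, math.log(tau2))
    rms = float(np.sqrt(np.mean((y - pred) ** 2)))
    return BiexpFit(yi, a1, tau1, a2, tau2, rms, True)


def fit_trace(trace: SecretionTrace, field: str = "i_apical") -> BiexpFit:
    """Fit the post-step (t >= 0) portion of a trace field."""
    mask = trace.t >= 0
    return fit_biexponential(trace.t[mask], getattr(trace, field)[mask])
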