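"""Synthetic raw-data generators.

Emulates the two kinds of raw recordings the measurement pipeline
consumes — noisy secretion-current traces and transepithelial PD
recordings with constant-current pulse trains — with the true generating
parameters recorded alongside so recovery can be tested.  All
randomness flows from an explicit integer seed; noise without a seed is
refused.
"""

from __future__ import annotations

import numpy as np

from .estimator import PulseRecording
from .model import (
    InvalidInputError,
    SecretionTrace,
    StepProtocol,
    TissueParams,
    analytic_solution,
)

__all__ = ["noisy_trace", "generate_pulse_recording"]


def noisy_trace(
    tissue: TissueParams,
    protocol: StepProtocol,
    *,
    noise_fraction: float = 0.0,
    seed: int | None = None,
    t_grid: np.ndarray | None = None,
) -> tuple[SecretionTrace, dict]:
    """Analytic trace plus multiplicative Gaussian noise on the currents.

    Each current sample is multiplied by ``1 + noise_fraction * z`` with
    independent standard-normal ``z``; [Cl-]i is left noise-free (it is
    not a measured quantity).  Returns the trace and a metadata dict
    holding the generating truth.
    """
    if noise_fraction < 0:
        raise InvalidInputError("noise_fraction must be >= 0")
    if noise_fraction > 0 and seed is None:
        raise InvalidInputError("noise requested without a seed")
    clean = analytic_solution(tissue, protocol, t_grid)
    meta = {
        "noise_fraction": noise_fraction,
        "seed": seed,
        "jc_ratio_true": protocol.jc_inf / protocol.jc_pre if protocol.jc_pre else float("inf"),
        "g_apical_pre_S": protocol.pre.g_apical,
        "g_basolateral_pre_S": protocol.pre.g_basolateral,
        "g_apical_post_S": protocol.post.g_apical,
        "g_basolateral_post_S": protocol.post.g_basolateral,
        "v_pre_V": protocol.pre.v_membrane,
        "v_post_V": protocol.post.v_membrane,
        "tau2_s": protocol.transporter.tau2,
        "horizon_s": protocol.horizon,
    }
    if noise_fraction == 0:
        return clean, meta
    rng = np.random.default_rng(seed)

    def jitter(x: np.ndarray) -> np.ndarray:
        return x * (1.0 + noise_fraction * rng.standard_normal(x.shape))

    noisy = SecretionTrace(
        t=clean.t,
        cl_in=clean.cl_in,
        i_apical=jitter(clean.i_apical),
        i_basolateral=jitter(clean.i_basolateral),
        i_uptake=jitter(clean.i_uptake),
    )
    return noisy, meta


def generate_pulse_recording(
    g_true: float,
    *,
    n_pulses: int,
    pulse_current: float = 1.0,  # uA
    pulse_period: float = 10.0,  # s
    pulse_width: float = 0.5,  # s
    dt: float = 0.05,  # s
    baseline_pd: float = -10.0,  # mV
    noise_sd: float = 0.0,  # mV, additive Gaussian
    seed: int | None = None,
) -> tuple[PulseRecording, dict]:
    """Synthetic PD recording with square deflections dPD = I/G.

    ``g_true`` in S; the deflection in mV is pulse_current[uA] /
    (g_true[S] * 1e3).  Returns the recording and a metadata dict with
    the generating truth.
    """
    if n_pulses <= 0:
        raise InvalidInputError("need at least one pulse")
    if g_true <= 0:
        raise InvalidInputError("g_true must be > 0")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise InvalidInputError("noise requested without a seed")
    duration = n_pulses * pulse_period
    t = np.arange(0.0, duration, dt)
    onsets = np.arange(n_pulses) * pulse_period + pulse_period / 2
    deflection = pulse_current / (g_true * 1e3)  # mV
    pd = np.full_like(t, baseline_pd)
    for t0 in onsets:
        pd[(t >= t0) & (t < t0 + pulse_width)] += deflection
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pd = pd + noise_sd * rng.standard_normal(pd.shape)
    rec = PulseRecording(
        t=t, pd=pd, pulse_times=onsets, pulse_current=pulse_current,
        pulse_width=pulse_width,
    )
    meta = {
        "g_true_S": g_true,
        "deflection_true_mV": deflection,
        "noise_sd_mV": noise_sd,
        "seed": seed,
        "n_pulses": n_pulses,
    }
    return rec, meta
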