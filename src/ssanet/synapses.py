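"""Kinetic synapses with three-state short-term depression.

The transmitter resource of each synapse is split between *recovered* (R),
*effective* (E) and *inactive* (I) fractions with R + E + I = 1.  A
presynaptic spike opens (or re-opens) a square transmitter pulse; while the
pulse is active, R converts to E at rate R/tau_rise.  E inactivates at
E/tau_decay and I returns to R at I/tau_rec.  Slow recovery (tau_rec on the
order of hundreds of ms) is what produces paired-pulse depression; the
non-depressing excitatory and inhibitory classes use the same code path
with an instantaneous I -> R return.

The postsynaptic current is proportional to the effective fraction:
``I = w * E * (E_rev - V)``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .params import DepressingSynapseState, JitterSpec, KineticSynapseParams

CONSERVATION_TOL = 1e-6


def synapse_step(
    state: DepressingSynapseState,
    params: KineticSynapseParams,
    presyn_spike: bool,
    dt_ms: float,
) -> DepressingSynapseState:
    """Advance one synapse by ``dt_ms`` (exponential transfers).

    Each state's outflow over the step is integrated exactly for its own
    rate (``x * (1 - exp(-h/tau))``, exponential-Euler form) and the three
    transfers are applied simultaneously, so the R + E + I sum is conserved
    exactly (up to float rounding) regardless of step size.  When the
    transmitter pulse ends inside the step, the recovered->effective
    transfer only integrates over the remaining pulse time.  A spike
    arriving while the pulse is still open resets the timer to the full
    pulse duration; pulses do not stack.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    r, e, i = state.recovered, state.effective, state.inactive
    timer = params.pulse_ms if presyn_spike else state.pulse_timer_ms
    h_on = min(timer, dt_ms)
    t_re = r * -math.expm1(-h_on / params.tau_rise_ms) if h_on > 0.0 else 0.0
    t_ei = e * -math.expm1(-dt_ms / params.tau_decay_ms)
    if params.depressing:
        t_ir = i * -math.expm1(-dt_ms / params.tau_rec_ms)
    else:
        t_ir = i  # instantaneous return: the non-depressing limit
    r_new = r + t_ir - t_re
    e_new = e + t_re - t_ei
    i_new = i + t_ei - t_ir
    if not (
        -CONSERVATION_TOL <= r_new <= 1 + CONSERVATION_TOL
        and -CONSERVATION_TOL <= e_new <= 1 + CONSERVATION_TOL
        and -CONSERVATION_TOL <= i_new <= 1 + CONSERVATION_TOL
    ):
        raise FloatingPointError(
            "synapse fractions left [0, 1]; the step size is too large for "
            "the configured time constants"
        )
    return DepressingSynapseState(
        r_new, e_new, i_new, max(0.0, timer - dt_ms)
    )


def synaptic_current(
    state: DepressingSynapseState,
    params: KineticSynapseParams,
    postsyn_potential_mV: float,
) -> float:
    """Postsynaptic current (pA): weight x effective fraction x driving force."""
    return (
        params.weight_nS
        * state.effective
        * (params.e_rev_mV - postsyn_potential_mV)
    )


def run_train(
    params: KineticSynapseParams,
    spike_times_ms,
    t_end_ms: float,
    dt_ms: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a synapse over a presynaptic spike train.

    Returns (times_ms, effective_fraction_trace).  Spike times are snapped
    to the step grid.
    """
    n_steps = int(round(t_end_ms / dt_ms))
    spike_steps = {int(round(t / dt_ms)) for t in spike_times_ms}
    state = DepressingSynapseState()
    eff = np.empty(n_steps)
    for k in range(n_steps):
        state = synapse_step(state, params, k in spike_steps, dt_ms)
        eff[k] = state.effective
    return (np.arange(1, n_steps + 1) * dt_ms), eff


def peak_effective(
    params: KineticSynapseParams, spike_times_ms, dt_ms: float = 0.1
) -> float:
    """Peak effective fraction reached after the *last* spike of a train."""
    last = max(spike_times_ms)
    t_end = last + 10.0 * params.tau_decay_ms
    times, eff = run_train(params, spike_times_ms, t_end, dt_ms)
    return float(eff[times > last].max())


def recovery_curve(
    params: KineticSynapseParams,
    conditioning_train_ms,
    probe_delays_ms,
    dt_ms: float = 0.1,
) -> np.ndarray:
    """Paired-pulse recovery protocol.

    For each delay, a probe spike follows the end of the conditioning train
    and the ratio of its peak effective fraction to the unconditioned
    (single-spike) peak is returned.  The ratio approaches 1 as the delay
    grows, with the configured recovery time constant.
    """
    delays = np.asarray(list(probe_delays_ms), dtype=float)
    if delays.size == 0:
        raise ValueError("probe_delays_ms must not be empty")
    if np.any(delays <= 0):
        raise ValueError("probe delays must be > 0")
    train = sorted(conditioning_train_ms)
    t_last = train[-1]
    unconditioned = peak_effective(params, [0.0], dt_ms)
    ratios = np.empty(delays.size)
    for k, d in enumerate(delays):
        ratios[k] = (
            peak_effective(params, train + [t_last + d], dt_ms) / unconditioned
        )
    return ratios


def fit_recovery_tau(delays_ms, ratios, tau_guess_ms: float = 500.0) -> float:
    """Exponential fit of ``1 - ratio ~ c * exp(-delay/tau)``; returns tau (ms)."""
    from scipy.optimize import curve_fit

    delays = np.asarray(delays_ms, dtype=float)
    deficit = 1.0 - np.asarray(ratios, dtype=float)
    popt, _ = curve_fit(
        lambda d, c, tau: c * np.exp(-d / tau),
        delays,
        deficit,
        p0=(max(deficit.max(), 1e-3), tau_guess_ms),
        maxfev=10_000,
    )
    return float(popt[1])


def jitter_params(
    params: KineticSynapseParams, spec: JitterSpec, rng: np.random.Generator
) -> KineticSynapseParams:
    """Perturb each listed parameter by an independent log-normal factor.

    The factors have log-mean 0, so the median of every jittered parameter
    equals its nominal value and positivity (and sign) is preserved.
    """
    if spec.sigma_log == 0:
        return params
    changes = {}
    for name in spec.param_names:
        value = getattr(params, name)
        if not np.isfinite(value):
            continue  # the non-depressing tau_rec sentinel is not jittered
        changes[name] = value * rng.lognormal(0.0, spec.sigma_log)
    return dataclasses.replace(params, **changes)
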