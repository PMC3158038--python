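"""Single-unit dynamics: AdEx integration, Poisson spiking, background noise.

These scalar reference functions define the semantics of one integration
step; the network engine (:mod:`ssanet.network`) applies the identical
update rules vectorised over whole populations.
"""

from __future__ import annotations

import math

import numpy as np

from .params import AdExParams, AdExState, OUNoiseParams, OUNoiseState

# Cap on the exponential spike-initiation argument; beyond this the membrane
# is guaranteed to reach the detection cutoff within a step, and an
# unclamped exponent overflows float64.
_EXP_ARG_MAX = 30.0


def adex_step(
    state: AdExState,
    params: AdExParams,
    input_current_pA: float,
    dt_ms: float,
) -> tuple[AdExState, bool]:
    """Advance one AdEx unit by ``dt_ms`` using Heun's method.

    The explicit-trapezoid (Heun) step keeps the discretization error of
    spike times well below a millisecond at the default 0.1 ms step.
    Returns the new state and a spike flag.  When the membrane crosses the
    detection cutoff the potential is reset and the adaptation current is
    incremented by the spike-triggered amount within the same step.
    """
    if not 0 < dt_ms <= 1.0:
        raise ValueError("dt must satisfy 0 < dt <= 1 ms")
    v, w = state.v_mV, state.w_pA
    p = params

    def dvdw(v_, w_):
        exp_arg = min((v_ - p.v_threshold_mV) / p.delta_T_mV, _EXP_ARG_MAX)
        dv = (
            -p.g_leak_nS * (v_ - p.e_leak_mV)
            + p.g_leak_nS * p.delta_T_mV * math.exp(exp_arg)
            - w_
            + input_current_pA
        ) / p.capacitance_pF
        dw = (p.a_nS * (v_ - p.e_leak_mV) - w_) / p.tau_w_ms
        return dv, dw

    dv1, dw1 = dvdw(v, w)
    v_pred = v + dt_ms * dv1
    w_pred = w + dt_ms * dw1
    if v_pred >= p.v_cutoff_mV:
        # already past the detection cutoff at the predictor stage
        v_new, w_new = v_pred, w_pred
    else:
        dv2, dw2 = dvdw(v_pred, w_pred)
        v_new = v + 0.5 * dt_ms * (dv1 + dv2)
        w_new = w + 0.5 * dt_ms * (dw1 + dw2)
    spike = v_new >= p.v_cutoff_mV
    if spike:
        v_new = p.v_reset_mV
        w_new += p.b_pA
    if not (math.isfinite(v_new) and math.isfinite(w_new)):
        raise FloatingPointError(
            "AdEx state became non-finite; the step size is too large"
        )
    return AdExState(v_new, w_new), spike


def poisson_spike(rate_hz: float, dt_ms: float, rng: np.random.Generator) -> bool:
    """Emit a spike with probability ``1 - exp(-rate*dt)`` for this step."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return False
    return rng.random() < -math.expm1(-rate_hz * dt_ms / 1000.0)


def spike_probability(rate_hz: np.ndarray | float, dt_ms: float):
    """Per-step spike probability of a Poisson unit at ``rate_hz``."""
    return -np.expm1(-np.asarray(rate_hz, dtype=float) * dt_ms / 1000.0)


def ou_noise_step(
    state: OUNoiseState,
    params: OUNoiseParams,
    dt_ms: float,
    rng: np.random.Generator,
) -> OUNoiseState:
    """Advance both noise conductances by the exact OU discretization.

    The update ``g <- g0 + (g - g0) e^{-dt/tau} + sigma sqrt(1 - e^{-2dt/tau}) N``
    is distributionally exact for any step size, with stationary mean ``g0``
    and stationary standard deviation ``sigma``.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    p = params
    ge = _ou_update(state.g_e_nS, p.g_e0_nS, p.sigma_e_nS, p.tau_e_ms, dt_ms, rng)
    gi = _ou_update(state.g_i_nS, p.g_i0_nS, p.sigma_i_nS, p.tau_i_ms, dt_ms, rng)
    return OUNoiseState(ge, gi)


def _ou_update(g, g0, sigma, tau, dt, rng) -> float:
    decay = math.exp(-dt / tau)
    diffusion = sigma * math.sqrt(max(0.0, 1.0 - decay * decay))
    return g0 + (g - g0) * decay + diffusion * rng.standard_normal()


def noise_current(
    state: OUNoiseState, params: OUNoiseParams, membrane_potential_mV: float
) -> float:
    """Ohmic current (pA) injected by the two noise conductances."""
    p = params
    return p.area_scale * (
        state.g_e_nS * (p.e_e_mV - membrane_potential_mV)
        + state.g_i_nS * (p.e_i_mV - membrane_potential_mV)
    )


def simulate_adex(
    params: AdExParams,
    input_current_pA: np.ndarray,
    dt_ms: float,
    initial: AdExState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one AdEx unit over a current trace.

    Returns (spike_times_ms, membrane_trace_mV).  Used both as a public
    convenience and as the refined-step oracle in the test-suite.
    """
    state = initial or AdExState(params.e_leak_mV, 0.0)
    n = len(input_current_pA)
    v_trace = np.empty(n)
    spikes = []
    for k in range(n):
        state, fired = adex_step(state, params, float(input_current_pA[k]), dt_ms)
        v_trace[k] = state.v_mV
        if fired:
            spikes.append((k + 1) * dt_ms)
    return np.asarray(spikes), v_trace


def spontaneous_rate(
    adex: AdExParams,
    noise: OUNoiseParams,
    duration_ms: float = 20_000.0,
    dt_ms: float = 0.1,
    seed: int = 0,
) -> float:
    """Mean firing rate (Hz) of one AdEx unit driven by noise alone."""
    rng = np.random.default_rng(seed)
    state = AdExState(adex.e_leak_mV, 0.0)
    ou = OUNoiseState(noise.g_e0_nS, noise.g_i0_nS)
    n_steps = int(round(duration_ms / dt_ms))
    count = 0
    for _ in range(n_steps):
        ou = ou_noise_step(ou, noise, dt_ms, rng)
        i_noise = noise_current(ou, noise, state.v_mV)
        state, fired = adex_step(state, adex, i_noise, dt_ms)
        count += fired
    return count / (duration_ms / 1000.0)


def calibrate_noise_sigma(
    adex: AdExParams,
    noise: OUNoiseParams,
    target_rate_hz: float,
    sigma_bounds_nS: tuple[float, float] = (1.0, 30.0),
    tol_hz: float = 0.5,
    duration_ms: float = 20_000.0,
    seed: int = 0,
) -> float:
    """Tune the excitatory noise sigma to a requested spontaneous rate.

    Bisects ``sigma_e`` between ``sigma_bounds_nS`` until the measured
    spontaneous rate of an isolated unit is within ``tol_hz`` of the
    target.  The spontaneous rate is monotone in sigma_e over the relevant
    range (larger fluctuations cross threshold more often).
    """
    from .params import replace

    lo, hi = sigma_bounds_nS
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        rate = spontaneous_rate(
            adex, replace(noise, sigma_e_nS=mid), duration_ms, seed=seed
        )
        if abs(rate - target_rate_hz) <= tol_hz:
            return mid
        if rate < target_rate_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
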