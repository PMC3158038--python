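"""Parameter containers and the versioned defaults file.

All quantities use a fixed unit system: time in ms, voltage in mV,
conductance in nS, current in pA, capacitance in pF, rates in Hz and
frequency in octaves relative to the centre of the input range.  With these
units ``g [nS] * V [mV] = I [pA]`` and ``I [pA] * t [ms] / C [pF] = V [mV]``
hold numerically, so no conversion factors appear in the dynamics code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import yaml


def load_defaults() -> dict:
    """Load the package defaults file (AdEx, noise, synapse, tuning sets)."""
    with resources.files(__package__).joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire parameters.

    The model is a leaky integrator with an exponential spike-initiation
    term plus a sub-threshold (``a``) and spike-triggered (``b``) adaptation
    current ``w``:

        C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T) - w + I
        tau_w dw/dt = a (V - E_L) - w

    A spike is registered when ``V`` crosses ``v_cutoff_mV`` (a numerical
    detection level well above threshold); ``V`` is then reset and ``w``
    incremented by ``b``.
    """

    capacitance_pF: float = 281.0
    g_leak_nS: float = 30.0
    e_leak_mV: float = -70.6
    delta_T_mV: float = 2.0
    v_threshold_mV: float = -50.4
    tau_w_ms: float = 144.0
    a_nS: float = 4.0
    b_pA: float = 80.5
    v_reset_mV: float = -70.6
    v_cutoff_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0 or self.g_leak_nS <= 0:
            raise ValueError("capacitance and leak conductance must be > 0")
        if self.delta_T_mV <= 0 or self.tau_w_ms <= 0:
            raise ValueError("slope factor and adaptation time constant must be > 0")
        if self.v_cutoff_mV <= self.v_threshold_mV:
            raise ValueError("spike-detection cutoff must exceed the effective threshold")


@dataclass
class AdExState:
    """Membrane potential (mV) and adaptation current (pA) of one unit."""

    v_mV: float
    w_pA: float


@dataclass(frozen=True)
class OUNoiseParams:
    """Point-conductance background-noise parameters.

    Two independent Ornstein-Uhlenbeck conductances (excitatory and
    inhibitory) model in-vivo-like synaptic bombardment.  ``area_scale``
    multiplies the resulting current to compensate for membrane-area
    differences between the neuron the noise model was fitted on and the
    one simulated here.
    """

    g_e0_nS: float = 12.1
    g_i0_nS: float = 57.3
    sigma_e_nS: float = 3.0
    sigma_i_nS: float = 6.6
    tau_e_ms: float = 2.728
    tau_i_ms: float = 10.49
    e_e_mV: float = 0.0
    e_i_mV: float = -75.0
    area_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_e_nS < 0 or self.sigma_i_nS < 0:
            raise ValueError("conductance standard deviations must be >= 0")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("correlation time constants must be > 0")
        if self.area_scale <= 0:
            raise ValueError("area scaling factor must be > 0")


@dataclass
class OUNoiseState:
    """Instantaneous excitatory/inhibitory noise conductances (nS).

    Negative excursions are admitted by the underlying OU process and are
    not clipped by default.
    """

    g_e_nS: float
    g_i_nS: float


SYNAPSE_KINDS = ("excitatory", "inhibitory", "depressing")


@dataclass(frozen=True)
class KineticSynapseParams:
    """Kinetic synapse with a three-state transmitter resource cycle.

    A unit supply of transmitter is split between *recovered*, *effective*
    and *inactive* states.  A presynaptic spike opens a square transmitter
    pulse of ``pulse_ms`` during which recovered resource converts to
    effective at rate ``1/tau_rise_ms``; effective resource inactivates at
    ``1/tau_decay_ms`` and inactive resource recovers at ``1/tau_rec_ms``.
    The non-depressing excitatory/inhibitory classes are the same scheme
    with an instantaneous inactive->recovered return (``tau_rec_ms`` = inf
    sentinel; see :func:`ssanet.synapses.synapse_step`).
    """

    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 5.26
    pulse_ms: float = 1.0
    tau_rec_ms: float = 800.0
    weight_nS: float = 1.0
    e_rev_mV: float = 0.0
    kind: str = "depressing"

    def __post_init__(self) -> None:
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.kind == "depressing" and not self.tau_rec_ms > 0:
            raise ValueError("recovery time constant must be > 0")
        if self.pulse_ms <= 0:
            raise ValueError("transmitter pulse duration must be > 0")
        if self.weight_nS < 0:
            raise ValueError("synaptic weight must be >= 0")
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")

    @property
    def depressing(self) -> bool:
        return self.kind == "depressing"


@dataclass
class DepressingSynapseState:
    """Resource fractions and transmitter-pulse timer of one synapse."""

    recovered: float = 1.0
    effective: float = 0.0
    inactive: float = 0.0
    pulse_timer_ms: float = 0.0


@dataclass(frozen=True)
class JitterSpec:
    """Log-normal multiplicative heterogeneity applied to synapse parameters."""

    sigma_log: float = 0.1
    param_names: Sequence[str] = (
        "tau_rise_ms",
        "tau_decay_ms",
        "pulse_ms",
        "tau_rec_ms",
        "weight_nS",
        "e_rev_mV",
    )

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("log-scale standard deviation must be >= 0")


def adex_from_defaults(name: str = "default", defaults: dict | None = None) -> AdExParams:
    d = (defaults or load_defaults())["adex"][name]
    return AdExParams(**d)


def noise_from_defaults(preset: str = "high_spontaneous", defaults: dict | None = None) -> OUNoiseParams:
    d = (defaults or load_defaults())["noise"][preset]
    return OUNoiseParams(**d)


def synapse_from_defaults(pathway: str, defaults: dict | None = None) -> KineticSynapseParams:
    d = dict((defaults or load_defaults())["synapses"][pathway])
    kind = d.pop("kind")
    return KineticSynapseParams(kind=kind, **{k: float(v) for k, v in d.items()})


def jitter_from_defaults(defaults: dict | None = None) -> JitterSpec:
    d = (defaults or load_defaults())["jitter"]
    return JitterSpec(sigma_log=float(d["sigma_log"]), param_names=tuple(d["params"]))


def replace(obj, **changes):
    """dataclasses.replace re-export (convenient for parameter tweaking)."""
    return dataclasses.replace(obj, **changes)
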