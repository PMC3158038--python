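"""Network construction and the clock-driven simulation wrapper.

The three architectures share population A (frequency-tuned Poisson
sub-populations) feeding population B through depressing excitatory
synapses:

* **AB** — a single depressing layer; SSA is read out in B.
* **ABC** — adds inhibitory population C, driven from A through
  non-depressing excitatory synapses with the same connectivity as A->B;
  each B unit receives a fixed number of inhibitory afferents sampled at
  random from C.  The delayed shunting inhibition converts B's tonic
  response into near-binary onset spiking.
* **ABD** — adds population D, receiving all-to-all depressing synapses
  from B: two layers of depression in series, the substrate of the
  novelty (rarity-vs-novelty) effect.

Population A holds one distinct Poisson unit per (sub-population, B-unit)
pair; in ABC the C unit with index j reads the same Poisson column as B
unit j, so |A| = n_subpop x n_b in every architecture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import params as P
from ._engine import run_network
from .neurons import spike_probability
from .stimuli import ToneSequence, TuningSpec, tuning_rate

ARCHITECTURES = ("AB", "ABC", "ABD")
_POP_CODES = {0: "B", 1: "C", 2: "D"}

_JITTERED_FIELDS = ("tau_rise_ms", "tau_decay_ms", "pulse_ms", "tau_rec_ms",
                    "weight_nS", "e_rev_mV")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Everything needed to build one network deterministically."""

    architecture: str = "ABC"
    n_b: int = 48
    n_subpop: int = 96
    inhib_in_degree: int = 16
    pathways: dict = field(default_factory=dict)   # name -> KineticSynapseParams
    noise_preset: str | None = None                # defaults by architecture
    jitter: P.JitterSpec = field(default_factory=P.JitterSpec)
    adex: P.AdExParams = field(default_factory=P.AdExParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.n_b < 1 or self.n_subpop < 1:
            raise ValueError("population sizes must be >= 1")
        if self.architecture == "ABC" and self.inhib_in_degree > self.n_c:
            raise ValueError("inhibitory in-degree exceeds |C|")

    @property
    def n_c(self) -> int:
        return self.n_b if self.architecture == "ABC" else 0

    @property
    def n_d(self) -> int:
        return self.n_b if self.architecture == "ABD" else 0

    @property
    def n_a(self) -> int:
        return self.n_subpop * self.n_b

    def resolved_noise_preset(self) -> str:
        if self.noise_preset is not None:
            return self.noise_preset
        return "low_spontaneous" if self.architecture == "ABD" else "high_spontaneous"


@dataclass
class Pathway:
    """One synaptic pathway as flat per-synapse parameter arrays."""

    name: str
    nominal: P.KineticSynapseParams
    pre: np.ndarray          # presynaptic unit index per synapse
    post: np.ndarray
    arrays: dict             # field name -> jittered per-synapse array
    depressing: bool

    @property
    def n_syn(self) -> int:
        return self.pre.size


@dataclass
class Network:
    """A built network: jittered synapse instances plus neuron/noise params.

    The network itself is stateless; all dynamic state is created afresh
    inside :func:`simulate`, so repeated simulations of the same network
    with the same seed are identical.
    """

    spec: ArchitectureSpec
    adex: P.AdExParams
    noise: P.OUNoiseParams
    pathways: dict  # name -> Pathway

    def with_depression(self, pathway: str, enabled: bool) -> "Network":
        """Return a copy with one pathway switched between the depressing
        dynamics and the non-depressing (instantaneous-recovery) limit.

        Weights and jittered parameters are untouched, so toggling twice
        restores the original network exactly.
        """
        if pathway not in self.pathways:
            raise ValueError(f"unknown pathway {pathway!r}")
        new_paths = dict(self.pathways)
        new_paths[pathway] = dataclasses.replace(
            self.pathways[pathway], depressing=enabled
        )
        return Network(self.spec, self.adex, self.noise, new_paths)

    def scaled_weights(self, pathway: str, factor: float) -> "Network":
        """Return a copy with one pathway's weights multiplied by ``factor``."""
        pw = self.pathways[pathway]
        arrays = dict(pw.arrays)
        arrays["weight_nS"] = arrays["weight_nS"] * factor
        new_paths = dict(self.pathways)
        new_paths[pathway] = dataclasses.replace(pw, arrays=arrays)
        return Network(self.spec, self.adex, self.noise, new_paths)

    def manifest(self) -> dict:
        """Build summary (counts, degrees, seed) for reproducibility logs."""
        return {
            "architecture": self.spec.architecture,
            "seed": self.spec.seed,
            "n_subpop": self.spec.n_subpop,
            "n_a": self.spec.n_a,
            "n_b": self.spec.n_b,
            "n_c": self.spec.n_c,
            "n_d": self.spec.n_d,
            "inhib_in_degree": self.spec.inhib_in_degree if self.spec.n_c else 0,
            "noise_preset": self.spec.resolved_noise_preset(),
            "pathways": {
                name: {
                    "n_synapses": int(pw.n_syn),
                    "kind": pw.nominal.kind,
                    "depressing": bool(pw.depressing),
                    "nominal_weight_nS": pw.nominal.weight_nS,
                }
                for name, pw in self.pathways.items()
            },
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.manifest(), fh, sort_keys=False)


def _jittered_arrays(
    nominal: P.KineticSynapseParams, n: int, jitter: P.JitterSpec, rng
) -> dict:
    arrays = {}
    for name in _JITTERED_FIELDS:
        value = float(getattr(nominal, name))
        if name in jitter.param_names and jitter.sigma_log > 0 and np.isfinite(value):
            arrays[name] = value * rng.lognormal(0.0, jitter.sigma_log, size=n)
        else:
            arrays[name] = np.full(n, value)
    return arrays


def build_network(spec: ArchitectureSpec, rng: np.random.Generator | None = None) -> Network:
    """Instantiate a network with independently jittered synapse parameters."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    defaults = P.load_defaults()
    noise = P.noise_from_defaults(spec.resolved_noise_preset(), defaults)

    def pathway_params(name: str) -> P.KineticSynapseParams:
        if name in spec.pathways:
            return spec.pathways[name]
        return P.synapse_from_defaults(name, defaults)

    pathways = {}

    # A->B: one depressing synapse per (sub-population, B unit)
    n_ab = spec.n_subpop * spec.n_b
    ab = pathway_params("A_B")
    pre_ab = np.repeat(np.arange(spec.n_subpop), spec.n_b)
    post_ab = np.tile(np.arange(spec.n_b), spec.n_subpop)
    pathways["A_B"] = Pathway(
        "A_B", ab, pre_ab, post_ab,
        _jittered_arrays(ab, n_ab, spec.jitter, rng), ab.depressing,
    )

    if spec.architecture == "ABC":
        ac = pathway_params("A_C")
        pathways["A_C"] = Pathway(
            "A_C", ac, pre_ab.copy(), post_ab.copy(),
            _jittered_arrays(ac, n_ab, spec.jitter, rng), ac.depressing,
        )
        cb = pathway_params("C_B")
        n_cb = spec.n_b * spec.inhib_in_degree
        pre_cb = np.concatenate(
            [
                rng.choice(spec.n_c, size=spec.inhib_in_degree, replace=False)
                for _ in range(spec.n_b)
            ]
        )
        post_cb = np.repeat(np.arange(spec.n_b), spec.inhib_in_degree)
        pathways["C_B"] = Pathway(
            "C_B", cb, pre_cb, post_cb,
            _jittered_arrays(cb, n_cb, spec.jitter, rng), cb.depressing,
        )

    if spec.architecture == "ABD":
        bd = pathway_params("B_D")
        n_bd = spec.n_b * spec.n_d
        pre_bd = np.repeat(np.arange(spec.n_b), spec.n_d)
        post_bd = np.tile(np.arange(spec.n_d), spec.n_b)
        pathways["B_D"] = Pathway(
            "B_D", bd, pre_bd, post_bd,
            _jittered_arrays(bd, n_bd, spec.jitter, rng), bd.depressing,
        )

    return Network(spec, spec.adex, noise, pathways)


@dataclass
class SpikeRecord:
    """Raw simulation output: per-population (unit id, spike time) events."""

    spikes: dict          # population name -> (unit_ids int array, times_ms float array)
    dt_ms: float
    duration_ms: float

    def counts(self, population: str) -> int:
        return self.spikes[population][0].size

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"population": pop, "unit_id": units, "time_ms": times}
            )
            for pop, (units, times) in self.spikes.items()
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["population", "unit_id", "time_ms"]
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# dt_ms={self.dt_ms!r}\n")
            fh.write(f"# duration_ms={self.duration_ms!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SpikeRecord":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = float(val)
                else:
                    rows.append(line)
        import io as _io

        df = pd.read_csv(_io.StringIO("".join(rows)), sep="\t")
        spikes = {}
        for pop, grp in df.groupby("population"):
            spikes[str(pop)] = (
                grp["unit_id"].to_numpy(np.int64),
                grp["time_ms"].to_numpy(float),
            )
        return cls(spikes, meta["dt_ms"], meta["duration_ms"])


def _pathway_kernel_args(pw: Pathway | None, n_syn: int):
    if pw is None:
        z = np.ones(0)
        return z, z, z, z, z, z, False
    a = pw.arrays
    return (
        a["tau_rise_ms"], a["tau_decay_ms"], a["pulse_ms"], a["tau_rec_ms"],
        a["weight_nS"], a["e_rev_mV"], bool(pw.depressing),
    )


def simulate(
    network: Network,
    sequence: ToneSequence,
    tuning: TuningSpec,
    dt_ms: float = 0.1,
    t_end_ms: float | None = None,
    seed: int | np.random.Generator = 0,
) -> SpikeRecord:
    """Run the clock-driven simulation and return the spike record.

    Per step: the current tone sets each sub-population's Poisson
    probability; A spikes drive the A->B (and A->C) synapses; previous-step
    C spikes drive C->B, previous-step B spikes drive B->D; every AdEx unit
    then integrates its summed synaptic plus background-noise current.
    The result is a pure function of (network, sequence, tuning, dt, seed).
    """
    spec = network.spec
    if tuning.n_subpop != spec.n_subpop:
        raise ValueError("tuning n_subpop does not match the network")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    last = sequence.events[-1]
    if t_end_ms is None:
        t_end_ms = sequence.end_ms
    if t_end_ms < last.onset_ms + last.duration_ms:
        raise ValueError("t_end must cover the last tone offset")
    n_steps = int(round(t_end_ms / dt_ms))

    # per-step tone index and per-tone spike probabilities
    tone_idx = np.full(n_steps, -1, np.int32)
    n_tones = len(sequence)
    p_tone = np.empty((max(n_tones, 1), spec.n_subpop))
    best = tuning.best_freqs
    for k, ev in enumerate(sequence.events):
        p_tone[k] = spike_probability(tuning_rate(ev.freq_oct, best, tuning), dt_ms)
        k0 = int(np.ceil(ev.onset_ms / dt_ms))
        k1 = int(np.ceil((ev.onset_ms + ev.duration_ms) / dt_ms))
        tone_idx[k0:min(k1, n_steps)] = k
    p_gap = np.full(spec.n_subpop, float(spike_probability(tuning.spont_hz, dt_ms)))

    ab = _pathway_kernel_args(network.pathways.get("A_B"), 0)
    ac = _pathway_kernel_args(network.pathways.get("A_C"), 0)
    cb_pw = network.pathways.get("C_B")
    cb = _pathway_kernel_args(cb_pw, 0)
    cb_pre = cb_pw.pre.astype(np.int64) if cb_pw is not None else np.zeros(0, np.int64)
    bd = _pathway_kernel_args(network.pathways.get("B_D"), 0)

    noise = network.noise
    n_pops = 3
    g_e0 = np.full(n_pops, noise.g_e0_nS)
    g_i0 = np.full(n_pops, noise.g_i0_nS)
    sig_e = np.full(n_pops, noise.sigma_e_nS)
    sig_i = np.full(n_pops, noise.sigma_i_nS)
    tau_e = np.full(n_pops, noise.tau_e_ms)
    tau_i = np.full(n_pops, noise.tau_i_ms)
    e_e = np.full(n_pops, noise.e_e_mV)
    e_i = np.full(n_pops, noise.e_i_mV)
    scale = np.full(n_pops, noise.area_scale)

    adex = network.adex
    n_units = spec.n_b + spec.n_c + spec.n_d
    capacity = int(n_units * (t_end_ms / 1000.0) * 400) + 4096
    for _ in range(4):
        out_unit = np.empty(capacity, np.int64)
        out_time = np.empty(capacity, np.float64)
        out_pop = np.empty(capacity, np.int8)
        n_out, overflow = run_network(
            n_steps, dt_ms,
            tone_idx, p_tone, p_gap,
            spec.architecture == "ABC", spec.architecture == "ABD",
            spec.n_subpop, spec.n_b, spec.n_c, spec.n_d,
            spec.inhib_in_degree if spec.n_c else 0,
            *ab[:6], ab[6],
            *ac[:6], ac[6],
            cb_pre, *cb[:6], cb[6],
            *bd[:6], bd[6],
            adex.capacitance_pF, adex.g_leak_nS, adex.e_leak_mV,
            adex.delta_T_mV, adex.v_threshold_mV, adex.tau_w_ms,
            adex.a_nS, adex.b_pA, adex.v_reset_mV, adex.v_cutoff_mV,
            g_e0, g_i0, sig_e, sig_i, tau_e, tau_i, e_e, e_i, scale,
            int(seed) % 2**32,
            out_unit, out_time, out_pop,
        )
        if n_out < 0:
            raise FloatingPointError(
                "AdEx state became non-finite during the network simulation; "
                "reduce dt or the synaptic weights"
            )
        if not overflow:
            break
        capacity *= 4
    else:
        raise RuntimeError("spike buffer overflowed repeatedly")

    spikes = {}
    pops = ["B"] + (["C"] if spec.n_c else []) + (["D"] if spec.n_d else [])
    for code, pop in _POP_CODES.items():
        if pop not in pops:
            continue
        sel = out_pop[:n_out] == code
        spikes[pop] = (out_unit[:n_out][sel].copy(), out_time[:n_out][sel].copy())
    return SpikeRecord(spikes, dt_ms, float(t_end_ms))


def set_depression_enabled(network: Network, pathway: str, enabled: bool) -> Network:
    """Functional toggle of short-term depression on one pathway."""
    return network.with_depression(pathway, enabled)


def audit_connectivity(network: Network) -> None:
    """Exhaustively check the degree constraints of a built network.

    Raises AssertionError on any violation; used by tests and the CLI
    manifest step.
    """
    spec = network.spec
    ab = network.pathways["A_B"]
    assert ab.n_syn == spec.n_subpop * spec.n_b
    counts = np.bincount(ab.post, minlength=spec.n_b)
    assert np.all(counts == spec.n_subpop), "B in-degree from A must equal n_subpop"
    per_sub = ab.pre.reshape(spec.n_subpop, spec.n_b)
    assert np.all(per_sub == np.arange(spec.n_subpop)[:, None])
    if spec.architecture == "ABC":
        cb = network.pathways["C_B"]
        counts = np.bincount(cb.post, minlength=spec.n_b)
        assert np.all(counts == spec.inhib_in_degree)
        for j in range(spec.n_b):
            pres = cb.pre[cb.post == j]
            assert len(set(pres.tolist())) == spec.inhib_in_degree, (
                "inhibitory afferents must be sampled without replacement"
            )
    if spec.architecture == "ABD":
        bd = network.pathways["B_D"]
        counts = np.bincount(bd.post, minlength=spec.n_d)
        assert np.all(counts == spec.n_b), "D in-degree must equal |B|"
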