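"""Stimulus protocols and frequency-tuned Poisson drive.

Frequencies are expressed in octaves relative to the centre of the input
range, so a two-tone pair with separation ``delta_f`` sits at
``+/- delta_f / 2``.  All generators are pure functions of their arguments
and the supplied random generator, and every protocol is isochronous (one
constant inter-onset interval).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STANDARD = "standard"
DEVIANT = "deviant"


@dataclass(frozen=True)
class ToneEvent:
    onset_ms: float
    duration_ms: float
    freq_oct: float
    role: str

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError("onset must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class ToneSequence:
    """An ordered, non-overlapping, isochronous train of tone events."""

    events: tuple[ToneEvent, ...]
    iai_ms: float
    protocol: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        ev = self.events
        for a, b in zip(ev, ev[1:]):
            if b.onset_ms < a.onset_ms + a.duration_ms:
                raise ValueError("tone events must be sorted and non-overlapping")
            if abs((b.onset_ms - a.onset_ms) - self.iai_ms) > 1e-9:
                raise ValueError("inter-onset interval must be constant")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def end_ms(self) -> float:
        last = self.events[-1]
        return last.onset_ms + self.iai_ms

    @property
    def roles(self) -> list[str]:
        return [e.role for e in self.events]

    @property
    def freqs(self) -> np.ndarray:
        return np.array([e.freq_oct for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": [e.onset_ms for e in self.events],
                "duration_ms": [e.duration_ms for e in self.events],
                "freq_octaves": [e.freq_oct for e in self.events],
                "role": [e.role for e in self.events],
            }
        )

    def write_tsv(self, path) -> None:
        """Tab-separated annotation file, one row per tone, '#' metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# protocol={self.protocol}\n")
            fh.write(f"# iai_ms={self.iai_ms!r}\n")
            fh.write(f"# seed={self.seed!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ToneSequence":
        meta = {}
        body = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                body.append(line)
        df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
        events = tuple(
            ToneEvent(r.onset_ms, r.duration_ms, r.freq_octaves, str(r.role))
            for r in df.itertuples()
        )
        seed = meta.get("seed")
        return cls(
            events=events,
            iai_ms=float(meta["iai_ms"]),
            protocol=meta.get("protocol", ""),
            seed=None if seed in (None, "None") else int(seed),
        )


@dataclass(frozen=True)
class TuningSpec:
    """Raised-Gaussian frequency tuning of the Poisson input sub-populations.

    ``bandwidth_oct`` is the separation in octaves between the two
    frequencies that evoke a rate half-way between the maximal and
    spontaneous rates; best frequencies are uniformly spaced over
    ``span_octaves`` centred on zero.
    """

    n_subpop: int = 96
    span_octaves: float = 2.0
    spont_hz: float = 0.5
    max_hz: float = 100.0
    bandwidth_oct: float = 0.5

    def __post_init__(self) -> None:
        if self.spont_hz < 0 or self.max_hz <= self.spont_hz:
            raise ValueError("need 0 <= spontaneous rate < maximal rate")
        if self.bandwidth_oct <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.n_subpop < 1:
            raise ValueError("need at least one sub-population")

    @property
    def best_freqs(self) -> np.ndarray:
        half = self.span_octaves / 2.0
        return np.linspace(-half, half, self.n_subpop)

    @property
    def sigma_oct(self) -> float:
        # Half-rise definition: rate(best +/- bandwidth/2) is exactly midway
        # between max and spontaneous, hence the 2*sqrt(2 ln 2) conversion.
        return self.bandwidth_oct / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def tuning_rate(tone_freq_oct, best_freq_oct, spec: TuningSpec):
    """Firing rate (Hz) of a sub-population with the given best frequency."""
    delta = np.asarray(tone_freq_oct, dtype=float) - np.asarray(best_freq_oct, dtype=float)
    gauss = np.exp(-(delta**2) / (2.0 * spec.sigma_oct**2))
    return spec.spont_hz + (spec.max_hz - spec.spont_hz) * gauss


def drive_rates(sequence: ToneSequence, tuning: TuningSpec, t_ms: float) -> np.ndarray:
    """Per-sub-population Poisson rate at time ``t_ms`` (spontaneous in gaps)."""
    if t_ms < 0:
        raise ValueError("t must be >= 0")
    for ev in sequence.events:
        if ev.onset_ms <= t_ms < ev.onset_ms + ev.duration_ms:
            return np.asarray(tuning_rate(ev.freq_oct, tuning.best_freqs, tuning))
    return np.full(tuning.n_subpop, tuning.spont_hz)


def oddball_pair(delta_f_oct: float) -> tuple[float, float]:
    """Two frequencies equally spaced on the octave axis around the centre."""
    return (-delta_f_oct / 2.0, +delta_f_oct / 2.0)


def _build(events, iai_ms, protocol, seed=None) -> ToneSequence:
    return ToneSequence(tuple(events), iai_ms, protocol, seed)


def _sequence_from_roles(
    roles, freq_of_role, iai_ms, duration_ms, protocol, seed=None
) -> ToneSequence:
    events = [
        ToneEvent(k * iai_ms, duration_ms, freq_of_role[r], r)
        for k, r in enumerate(roles)
    ]
    return _build(events, iai_ms, protocol, seed)


def make_oddball(
    freq_pair: tuple[float, float],
    p: float,
    n_tones: int,
    iai_ms: float,
    duration_ms: float,
    rng: np.random.Generator,
) -> tuple[ToneSequence, ToneSequence]:
    """An i.i.d. oddball sequence and its frequency-swapped twin.

    Roles are drawn independently with deviant probability ``p``; the twin
    has the identical role pattern with the two frequencies exchanged, so
    each frequency is probed in both the standard and deviant context.
    ``p = 0.5`` is the equiprobable control condition.
    """
    if not 0 < p <= 0.5:
        raise ValueError("deviant probability must satisfy 0 < p <= 0.5")
    if n_tones < 1:
        raise ValueError("need at least one tone")
    f1, f2 = freq_pair
    roles = [DEVIANT if rng.random() < p else STANDARD for _ in range(n_tones)]
    seq = _sequence_from_roles(
        roles, {STANDARD: f1, DEVIANT: f2}, iai_ms, duration_ms, "oddball"
    )
    twin = _sequence_from_roles(
        roles, {STANDARD: f2, DEVIANT: f1}, iai_ms, duration_ms, "oddball-swap"
    )
    return seq, twin


@dataclass(frozen=True)
class MarkovSpec:
    """Two-state Markov chain stimulus specification.

    ``p`` is the stationary deviant probability and ``s`` the scaled
    switching metric: the deviant->standard transition probability as a
    fraction of its largest stationarity-compatible value, running from 0
    (a frozen chain that never switches) to 1 (switches at the highest
    possible rate).  The i.i.d. oddball is the special case
    ``s = (1 - p) / q_max``.
    """

    p: float
    s: float
    n_tones: int = 1000
    freq_pair: tuple[float, float] = field(default_factory=lambda: oddball_pair(0.5))
    iai_ms: float = 1000.0
    duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.p <= 0.5:
            raise ValueError("deviant probability must satisfy 0 < p <= 0.5")
        if not 0 <= self.s <= 1:
            raise ValueError("scaled switching metric must lie in [0, 1]")

    @property
    def q_max(self) -> float:
        return min(1.0, (1.0 - self.p) / self.p)

    @property
    def s_oddball(self) -> float:
        """The s value at which the chain degenerates to the i.i.d. oddball."""
        return (1.0 - self.p) / self.q_max


def markov_transition_matrix(p: float, s: float) -> np.ndarray:
    """Transition matrix over states (deviant, standard).

    Row-stochastic with stationary distribution ``(p, 1 - p)`` for every
    ``s > 0``.  The deviant->standard probability is ``s * q_max`` with
    ``q_max = min(1, (1-p)/p)``; the standard->deviant probability follows
    from the stationarity balance ``p * q_DS = (1 - p) * q_SD``.  At
    ``s = 0`` the matrix is the identity (a frozen, degenerate chain).
    """
    if not 0 < p <= 0.5:
        raise ValueError("deviant probability must satisfy 0 < p <= 0.5")
    if not 0 <= s <= 1:
        raise ValueError("scaled switching metric must lie in [0, 1]")
    q_max = min(1.0, (1.0 - p) / p)
    q_ds = s * q_max
    q_sd = p * q_ds / (1.0 - p)
    return np.array([[1.0 - q_ds, q_ds], [q_sd, 1.0 - q_sd]])


def make_markov(
    spec: MarkovSpec,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> tuple[ToneSequence, ToneSequence]:
    """Realize the chain and return the sequence plus its swapped twin.

    The chain starts from its stationary distribution unless an explicit
    ``initial_state`` (0 = deviant, 1 = standard) is given; a frozen chain
    (``s = 0``) has no stationary start and requires one.
    """
    mat = markov_transition_matrix(spec.p, spec.s)
    if spec.s == 0 and initial_state is None:
        raise ValueError(
            "s = 0 freezes the chain; supply an explicit initial_state"
        )
    if initial_state is None:
        state = 0 if rng.random() < spec.p else 1
    else:
        state = int(initial_state)
    roles = []
    for _ in range(spec.n_tones):
        roles.append(DEVIANT if state == 0 else STANDARD)
        state = 0 if rng.random() < mat[state, 0] else 1
    f1, f2 = spec.freq_pair
    seq = _sequence_from_roles(
        roles, {STANDARD: f1, DEVIANT: f2}, spec.iai_ms, spec.duration_ms, "markov"
    )
    twin = _sequence_from_roles(
        roles, {STANDARD: f2, DEVIANT: f1}, spec.iai_ms, spec.duration_ms, "markov-swap"
    )
    return seq, twin


GRID_MODES = ("block", "sequential", "random")


def make_grid_sequence(
    mode: str,
    n_freq: int,
    n_rep: int,
    octave_spacing: float,
    iai_ms: float,
    duration_ms: float,
    rng: np.random.Generator,
) -> ToneSequence:
    """Multi-frequency grid protocol: block, sequential or random ordering.

    ``n_freq`` frequencies, uniformly spaced by ``octave_spacing`` around
    the centre, each presented exactly ``n_rep`` times.  Block mode groups
    identical frequencies in ascending blocks; sequential mode repeats an
    ascending stepwise series; random mode permutes the same multiset.
    """
    if mode not in GRID_MODES:
        raise ValueError(f"mode must be one of {GRID_MODES}")
    if n_freq < 1 or n_rep < 1:
        raise ValueError("n_freq and n_rep must be >= 1")
    centre_offset = (n_freq - 1) / 2.0
    positions = (np.arange(n_freq) - centre_offset) * octave_spacing
    if mode == "block":
        order = np.repeat(np.arange(n_freq), n_rep)
    elif mode == "sequential":
        order = np.tile(np.arange(n_freq), n_rep)
    else:
        order = rng.permutation(np.repeat(np.arange(n_freq), n_rep))
    events = [
        ToneEvent(k * iai_ms, duration_ms, positions[idx], str(idx))
        for k, idx in enumerate(order)
    ]
    return _build(events, iai_ms, f"grid-{mode}")


def make_many_standards(
    positions: Sequence[float],
    deviant_index: int,
    n_tones: int,
    p: float,
    rng: np.random.Generator,
    iai_ms: float = 250.0,
    duration_ms: float = 50.0,
    standard_index: int | None = None,
) -> tuple[ToneSequence, ToneSequence]:
    """Matched oddball / many-standards control pair.

    The oddball sequence has exactly ``p * n_tones`` deviants at
    ``positions[deviant_index]`` (slots sampled without replacement) and a
    single standard frequency elsewhere (by default the position mirrored
    about the centre of the list).  The control keeps the deviant tones in
    the identical slots and fills the remaining slots with the non-deviant
    positions in exactly balanced counts, randomly ordered.
    """
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError("positions must be distinct")
    n_dev = p * n_tones
    if abs(n_dev - round(n_dev)) > 1e-9:
        raise ValueError("p * n_tones must be an integer")
    n_dev = int(round(n_dev))
    n_std = n_tones - n_dev
    n_other = len(positions) - 1
    if n_std % n_other != 0:
        feasible = n_dev + n_other * (n_std // n_other)
        raise ValueError(
            f"{n_std} standard slots cannot be balanced over {n_other} "
            f"positions; nearest feasible n_tones = {feasible}"
        )
    if standard_index is None:
        standard_index = len(positions) - 1 - deviant_index
    dev_slots = set(rng.choice(n_tones, size=n_dev, replace=False).tolist())
    dev_freq = positions[deviant_index]
    std_freq = positions[standard_index]

    events_odd = [
        ToneEvent(
            k * iai_ms,
            duration_ms,
            dev_freq if k in dev_slots else std_freq,
            DEVIANT if k in dev_slots else STANDARD,
        )
        for k in range(n_tones)
    ]
    other = [f for i, f in enumerate(positions) if i != deviant_index]
    fillers = np.repeat(other, n_std // n_other)
    rng.shuffle(fillers)
    filler_iter = iter(fillers)
    events_ctl = [
        ToneEvent(
            k * iai_ms,
            duration_ms,
            dev_freq if k in dev_slots else float(next(filler_iter)),
            DEVIANT if k in dev_slots else STANDARD,
        )
        for k in range(n_tones)
    ]
    return (
        _build(events_odd, iai_ms, "many-standards-oddball"),
        _build(events_ctl, iai_ms, "many-standards-control"),
    )
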