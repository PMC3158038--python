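import numpy as np
import pytest

from ssanet.network import SpikeRecord
from ssanet.params import AdExParams, KineticSynapseParams, OUNoiseParams
from ssanet.stimuli import ToneEvent, ToneSequence


@pytest.fixture
def adex():
    return AdExParams()


@pytest.fixture
def noise():
    return OUNoiseParams()


@pytest.fixture
def depressing():
    return KineticSynapseParams(kind="depressing")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_train(n_tones=10, iai=250.0, dur=50.0, roles=None, freqs=None):
    roles = roles or ["standard"] * n_tones
    freqs = freqs if freqs is not None else [0.0] * n_tones
    events = tuple(
        ToneEvent(k * iai, dur, freqs[k], roles[k]) for k in range(n_tones)
    )
    return ToneSequence(events, iai)


def synthetic_record(counts, sequence, n_units, offset_ms=10.0):
    """Spike record with exactly `counts[tone, unit]` spikes per tone window.

    Spikes are placed just after each tone onset, so any window containing
    `offset_ms` reproduces `counts` by construction.
    """
    counts = np.asarray(counts)
    units, times = [], []
    for k, ev in enumerate(sequence.events):
        for j in range(n_units):
            for m in range(counts[k, j]):
                units.append(j)
                times.append(ev.onset_ms + offset_ms + 0.1 * m)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(
        {"B": (np.asarray(units, np.int64)[order], np.asarray(times)[order])},
        dt_ms=0.1,
        duration_ms=sequence.end_ms,
    )


from hypothesis import settings as _hsettings

_hsettings.register_profile("ci", derandomize=True)
_hsettings.load_profile("ci")
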