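"""Stimulus generators: tuning curves, oddball/Markov/grid/many-standards."""

import numpy as np
import pytest

from ssanet.stimuli import (
    DEVIANT,
    STANDARD,
    MarkovSpec,
    ToneSequence,
    TuningSpec,
    drive_rates,
    make_grid_sequence,
    make_many_standards,
    make_markov,
    make_oddball,
    markov_transition_matrix,
    oddball_pair,
    tuning_rate,
)


class TestTuning:
    def test_peak_at_best_frequency(self):
        spec = TuningSpec()
        assert tuning_rate(0.3, 0.3, spec) == pytest.approx(spec.max_hz)

    def test_half_rise_at_half_bandwidth(self):
        """The half-bandwidth offset evokes the rate midway between max and
        spontaneous — the defining property of the bandwidth parameter."""
        spec = TuningSpec(bandwidth_oct=0.5)
        halfway = (spec.max_hz + spec.spont_hz) / 2.0
        for sign in (-1, 1):
            assert tuning_rate(sign * 0.25, 0.0, spec) == pytest.approx(halfway)

    def test_far_tones_evoke_spontaneous_rate(self):
        spec = TuningSpec()
        assert tuning_rate(50.0, 0.0, spec) == pytest.approx(spec.spont_hz)

    def test_best_frequencies_uniform(self):
        spec = TuningSpec(n_subpop=96, span_octaves=2.0)
        diffs = np.diff(spec.best_freqs)
        assert np.allclose(diffs, diffs[0])
        assert spec.best_freqs[0] == -1.0 and spec.best_freqs[-1] == 1.0


class TestOddball:
    def test_twin_has_same_roles_and_swapped_freqs(self, rng):
        seq, twin = make_oddball(oddball_pair(0.5), 0.1, 200, 500.0, 100.0, rng)
        assert seq.roles == twin.roles
        f1, f2 = oddball_pair(0.5)
        for a, b in zip(seq.events, twin.events):
            assert {a.freq_oct, b.freq_oct} == {f1, f2}
            assert a.freq_oct != b.freq_oct

    def test_deviant_count_binomial(self, rng):
        n, p = 800, 0.1
        seq, _ = make_oddball(oddball_pair(0.5), p, n, 500.0, 100.0, rng)
        n_dev = seq.roles.count(DEVIANT)
        assert abs(n_dev - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_p_above_half_rejected(self, rng):
        with pytest.raises(ValueError):
            make_oddball(oddball_pair(0.5), 0.6, 10, 500.0, 100.0, rng)

    def test_purity(self):
        a, _ = make_oddball(oddball_pair(0.5), 0.2, 50, 500.0, 100.0, np.random.default_rng(3))
        b, _ = make_oddball(oddball_pair(0.5), 0.2, 50, 500.0, 100.0, np.random.default_rng(3))
        assert a == b


class TestMarkovMatrix:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("s", [0.25, 0.5, 0.75, 1.0])
    def test_stationary_distribution(self, p, s):
        mat = markov_transition_matrix(p, s)
        assert np.allclose(mat.sum(axis=1), 1.0)
        pi = np.array([p, 1 - p])
        assert np.allclose(pi @ mat, pi, atol=1e-10)

    def test_oddball_point_gives_iid_rows(self):
        p = 0.2
        s_odd = MarkovSpec(p=p, s=1.0).s_oddball
        mat = markov_transition_matrix(p, s_odd)
        assert np.allclose(mat[0], [p, 1 - p])
        assert np.allclose(mat[1], [p, 1 - p])

    def test_equiprobable_maximal_switching_alternates(self):
        mat = markov_transition_matrix(0.5, 1.0)
        assert np.allclose(mat, [[0.0, 1.0], [1.0, 0.0]])

    def test_s_zero_is_identity(self):
        assert np.allclose(markov_transition_matrix(0.3, 0.0), np.eye(2))


class TestMarkovRealization:
    def test_transition_frequencies_match_matrix(self):
        p, s, n = 0.2, 0.6, 100_000
        spec = MarkovSpec(p=p, s=s, n_tones=n)
        seq, _ = make_markov(spec, np.random.default_rng(11))
        states = np.array([r == DEVIANT for r in seq.roles], dtype=int)  # 1 = deviant
        mat = markov_transition_matrix(p, s)
        for frm, to in [(1, 0), (0, 1)]:
            mask = states[:-1] == frm
            emp = np.mean(states[1:][mask] == to)
            idx_frm = 0 if frm else 1
            idx_to = 0 if to else 1
            expected = mat[idx_frm, idx_to]
            se = np.sqrt(expected * (1 - expected) / mask.sum())
            assert abs(emp - expected) < 3 * se

    def test_deviant_fraction_converges_to_p(self):
        spec = MarkovSpec(p=0.3, s=0.5, n_tones=100_000)
        seq, _ = make_markov(spec, np.random.default_rng(4))
        frac = np.mean([r == DEVIANT for r in seq.roles])
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_lower_s_gives_longer_deviant_runs(self):
        runs = {}
        for s in (0.3, 1.0):
            spec = MarkovSpec(p=0.3, s=s, n_tones=50_000)
            seq, _ = make_markov(spec, np.random.default_rng(9))
            states = np.array([r == DEVIANT for r in seq.roles])
            # mean run length of consecutive deviants
            changes = np.diff(states.astype(int))
            n_runs = np.sum(changes == 1) + states[0]
            runs[s] = states.sum() / max(n_runs, 1)
        assert runs[0.3] > runs[1.0]

    def test_frozen_chain_requires_initial_state(self, rng):
        spec = MarkovSpec(p=0.3, s=0.0, n_tones=10)
        with pytest.raises(ValueError):
            make_markov(spec, rng)
        seq, _ = make_markov(spec, rng, initial_state=1)
        assert set(seq.roles) == {STANDARD}


class TestGridSequences:
    def test_block_mode_predecessor_counts(self, rng):
        """Ten frequencies x ten repeats in block mode: 90 identical and 9
        adjacent-frequency predecessors."""
        seq = make_grid_sequence("block", 10, 10, 0.2, 250.0, 50.0, rng)
        freqs = seq.freqs
        same = np.sum(freqs[1:] == freqs[:-1])
        adjacent = np.sum(np.isclose(np.abs(freqs[1:] - freqs[:-1]), 0.2))
        assert (same, adjacent) == (90, 9)

    def test_sequential_mode_predecessor_counts(self, rng):
        seq = make_grid_sequence("sequential", 10, 10, 0.2, 250.0, 50.0, rng)
        freqs = seq.freqs
        adjacent = np.sum(np.isclose(np.abs(freqs[1:] - freqs[:-1]), 0.2))
        assert adjacent == 90

    def test_random_mode_is_a_permutation_of_block(self, rng):
        block = make_grid_sequence("block", 10, 10, 0.2, 250.0, 50.0, rng)
        rand = make_grid_sequence("random", 10, 10, 0.2, 250.0, 50.0, rng)
        assert sorted(block.freqs) == sorted(rand.freqs)

    def test_every_frequency_equally_often(self, rng):
        for mode in ("block", "sequential", "random"):
            seq = make_grid_sequence(mode, 7, 4, 0.3, 250.0, 50.0, rng)
            _, counts = np.unique(seq.freqs, return_counts=True)
            assert np.all(counts == 4)


class TestManyStandards:
    def test_deviant_slots_identical_between_conditions(self, rng):
        positions = [-0.5, -0.3, -0.1, 0.1, 0.3, 0.5]
        odd, ctl = make_many_standards(positions, 4, 100, 0.1, rng)
        slots_odd = [k for k, e in enumerate(odd.events) if e.role == DEVIANT]
        slots_ctl = [k for k, e in enumerate(ctl.events) if e.role == DEVIANT]
        assert slots_odd == slots_ctl
        for k in slots_odd:
            assert odd.events[k].freq_oct == ctl.events[k].freq_oct == positions[4]

    def test_control_fillers_exactly_balanced(self, rng):
        positions = list(np.linspace(-0.9, 0.9, 10))
        odd, ctl = make_many_standards(positions, 9, 900, 0.1, rng)
        filler = [e.freq_oct for e in ctl.events if e.role == STANDARD]
        _, counts = np.unique(filler, return_counts=True)
        assert len(counts) == 9
        assert np.all(counts == 90)

    def test_oddball_has_single_standard_frequency(self, rng):
        positions = [-0.5, -0.3, -0.1, 0.1, 0.3, 0.5]
        odd, _ = make_many_standards(positions, 5, 100, 0.1, rng)
        std_freqs = {e.freq_oct for e in odd.events if e.role == STANDARD}
        assert std_freqs == {positions[0]}  # mirrored position

    def test_unbalanced_counts_rejected_with_suggestion(self, rng):
        positions = list(np.linspace(-0.7, 0.7, 8))  # 7 filler positions
        with pytest.raises(ValueError, match="feasible"):
            make_many_standards(positions, 7, 100, 0.1, rng)  # 90 % 7 != 0


class TestDriveRates:
    def test_gap_gives_spontaneous_everywhere(self, rng):
        seq, _ = make_oddball(oddball_pair(0.5), 0.1, 5, 500.0, 100.0, rng)
        tuning = TuningSpec(n_subpop=24)
        rates = drive_rates(seq, tuning, 450.0)
        assert np.allclose(rates, tuning.spont_hz)

    def test_tone_drives_best_frequency_maximally(self, rng):
        seq, _ = make_oddball((0.0, 0.5), 0.5, 5, 500.0, 100.0, rng)
        tuning = TuningSpec(n_subpop=25, span_octaves=2.0)
        t = seq.events[0].onset_ms + 1.0
        rates = drive_rates(seq, tuning, t)
        k = np.argmin(np.abs(tuning.best_freqs - seq.events[0].freq_oct))
        assert rates[k] == pytest.approx(tuning.max_hz, rel=1e-6)
        # symmetry about the tone frequency on the octave axis
        assert rates[k - 3] == pytest.approx(rates[k + 3], rel=1e-9)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        seq, _ = make_oddball(oddball_pair(0.37), 0.25, 40, 300.0, 75.0, rng)
        path = tmp_path / "seq.tsv"
        seq.write_tsv(path)
        back = ToneSequence.read_tsv(path)
        assert back.iai_ms == seq.iai_ms
        assert back.roles == seq.roles
        assert np.allclose(back.freqs, seq.freqs)
        assert [e.onset_ms for e in back.events] == [e.onset_ms for e in seq.events]

    def test_overlapping_events_rejected(self):
        from ssanet.stimuli import ToneEvent

        with pytest.raises(ValueError):
            ToneSequence(
                (ToneEvent(0.0, 300.0, 0.0, STANDARD), ToneEvent(250.0, 300.0, 0.0, STANDARD)),
                250.0,
            )
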