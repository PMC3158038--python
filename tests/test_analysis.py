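"""Spike-count tables, SSA indices, PSTHs, history curves, fits, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tone_train, synthetic_record
from ssanet.analysis import (
    count_spikes,
    fit_exponential,
    history_conditioned,
    ks_test,
    psth,
    si_frequency,
    si_from_tables,
    si_neuron,
    sign_test_majority,
    signed_rank_test,
)
from ssanet.network import SpikeRecord
from ssanet.stimuli import DEVIANT, STANDARD


class TestCountSpikes:
    def test_empty_record_gives_zero_counts(self):
        seq = make_tone_train(5)
        rec = SpikeRecord({"B": (np.array([], np.int64), np.array([]))}, 0.1, seq.end_ms)
        tab = count_spikes(rec, seq, n_units=3)
        assert len(tab) == 15
        assert (tab["count"] == 0).all()

    def test_known_counts_recovered(self, rng):
        seq = make_tone_train(6, roles=["standard"] * 5 + ["deviant"])
        counts = rng.integers(0, 5, size=(6, 4))
        rec = synthetic_record(counts, seq, 4)
        tab = count_spikes(rec, seq, n_units=4)
        got = tab.pivot(index="tone_index", columns="unit", values="count").to_numpy()
        assert np.array_equal(got, counts)

    def test_right_edge_spike_counted_in_next_window(self):
        seq = make_tone_train(2, iai=250.0)
        # spike exactly at the second tone's onset = right edge of window 0
        rec = SpikeRecord({"B": (np.array([0]), np.array([250.0]))}, 0.1, seq.end_ms)
        tab = count_spikes(rec, seq, n_units=1)
        assert tab.loc[tab.tone_index == 0, "count"].item() == 0
        assert tab.loc[tab.tone_index == 1, "count"].item() == 1

    def test_overlong_window_rejected(self):
        seq = make_tone_train(3, iai=250.0)
        rec = SpikeRecord({"B": (np.array([], np.int64), np.array([]))}, 0.1, seq.end_ms)
        with pytest.raises(ValueError):
            count_spikes(rec, seq, window_ms=(0.0, 300.0))


class TestSIFormulas:
    def test_equal_responses_give_zero(self):
        assert si_frequency(2.0, 2.0) == 0.0
        assert si_neuron(1.0, 1.0, 1.0, 1.0) == 0.0

    def test_silent_standard_gives_one(self):
        assert si_frequency(3.0, 0.0) == 1.0
        assert si_neuron(2.0, 1.0, 0.0, 0.0) == 1.0

    def test_arithmetic(self):
        assert si_frequency(3.0, 1.0) == pytest.approx(0.5)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(si_frequency(0.0, 0.0))
        assert np.isnan(si_neuron(0.0, 0.0, 0.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            si_frequency(-1.0, 2.0)
        with pytest.raises(ValueError):
            si_neuron(1.0, -0.1, 0.0, 0.0)

    def test_label_swap_symmetry(self):
        assert si_neuron(3.0, 1.0, 0.5, 0.2) == pytest.approx(
            si_neuron(1.0, 3.0, 0.2, 0.5)
        )

    @given(
        d=st.floats(0, 1e6),
        s=st.floats(0, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_frequency_si_bounded(self, d, s):
        si = si_frequency(d, s)
        if not np.isnan(si):
            assert -1.0 <= si <= 1.0

    @given(st.lists(st.floats(0, 1e6), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_neuron_si_bounded(self, vals):
        si = si_neuron(*vals)
        if not np.isnan(si):
            assert -1.0 <= si <= 1.0

    def test_neuron_si_equals_frequency_si_for_identical_frequencies(self):
        d, s = 2.5, 1.5
        assert si_neuron(d, d, s, s) == pytest.approx(si_frequency(d, s))


class TestSIFromTables:
    def test_known_means(self):
        roles = [STANDARD] * 3 + [DEVIANT]
        seq = make_tone_train(4, roles=roles)
        # unit 0: standards 1, deviants 3 in both presentations
        counts = np.array([[1], [1], [1], [3]])
        rec = synthetic_record(counts, seq, 1)
        tab = count_spikes(rec, seq, n_units=1)
        res = si_from_tables(tab, tab)
        assert res.per_unit.loc[0, "si_neuron"] == pytest.approx(0.5)
        assert res.n_undefined == 0


class TestPSTH:
    def test_flat_for_homogeneous_poisson(self):
        rng = np.random.default_rng(0)
        seq = make_tone_train(50, iai=200.0, roles=[STANDARD] * 50)
        rate, n_units = 50.0, 4
        n_spikes = rng.poisson(rate * n_units * seq.end_ms / 1000.0)
        times = np.sort(rng.uniform(0, seq.end_ms, n_spikes))
        units = rng.integers(0, n_units, n_spikes)
        rec = SpikeRecord({"B": (units, times)}, 0.1, seq.end_ms)
        df = psth(rec, seq, bin_ms=10.0, n_units=n_units)
        assert df["rate_standard"].mean() == pytest.approx(rate, rel=0.1)
        assert df["rate_standard"].std() < 0.5 * rate

    def test_mass_equals_mean_count_per_epoch(self, rng):
        seq = make_tone_train(8, roles=[STANDARD] * 8)
        counts = rng.integers(0, 6, size=(8, 3))
        rec = synthetic_record(counts, seq, 3)
        df = psth(rec, seq, bin_ms=2.0, n_units=3)
        mass = df["rate_standard"].sum() * 2.0 / 1000.0
        assert mass == pytest.approx(counts.mean(axis=1).mean(), rel=1e-9)

    def test_difference_of_identical_traces_is_zero(self, rng):
        roles = [STANDARD, DEVIANT] * 10
        seq = make_tone_train(20, roles=roles)
        counts = np.ones((20, 2), dtype=int)
        rec = synthetic_record(counts, seq, 2)
        df = psth(rec, seq, bin_ms=5.0, n_units=2)
        assert np.allclose(df["rate_diff"], 0.0)


class TestHistoryCurve:
    @staticmethod
    def _table(roles, dev_counts):
        seq = make_tone_train(len(roles), roles=roles)
        counts = np.zeros((len(roles), 1), dtype=int)
        k = 0
        run = 0
        for i, role in enumerate(roles):
            if role == DEVIANT:
                counts[i, 0] = dev_counts(min(run, 10))
                run = 0
            else:
                counts[i, 0] = 1
                run += 1
        rec = synthetic_record(counts, seq, 1)
        return count_spikes(rec, seq, n_units=1)

    def test_history_independent_responses_give_flat_curve(self, rng):
        roles = [DEVIANT if rng.random() < 0.3 else STANDARD for _ in range(400)]
        tab = self._table(roles, lambda k: 2)
        curve = history_conditioned(tab)
        ratio = 2.0 / tab["count"].mean()
        assert np.allclose(curve.table["mean_norm"], ratio, rtol=1e-9)

    def test_saturating_exponential_recovered(self, rng):
        """Counts following a(1 - exp(-k/tau)) recover (a, tau) within 10%."""
        a_true, tau_true = 20.0, 3.0
        roles = [DEVIANT if rng.random() < 0.25 else STANDARD for _ in range(3000)]
        tab = self._table(
            roles, lambda k: int(round(a_true * (1 - np.exp(-k / tau_true))))
        )
        curve = history_conditioned(tab)
        grand = tab["count"].mean()
        assert curve.converged
        assert curve.asymptote * grand == pytest.approx(a_true, rel=0.10)
        assert 1.0 / curve.rate_per_tone == pytest.approx(tau_true, rel=0.25)

    def test_pool_bin_collects_long_runs(self, rng):
        roles = ([STANDARD] * 15 + [DEVIANT]) * 20
        tab = self._table(roles, lambda k: 2)
        curve = history_conditioned(tab)
        assert curve.table["k"].tolist() == [10]
        assert curve.table["n"].item() == 20

    def test_no_deviants_rejected(self):
        tab = self._table([STANDARD] * 20, lambda k: 0)
        with pytest.raises(ValueError):
            history_conditioned(tab)


class TestFitExponential:
    def test_exact_recovery_decay(self):
        x = np.linspace(0, 10, 30)
        y = 0.5 + 2.0 * np.exp(-0.7 * x)
        fit = fit_exponential(x, y, form="decay")
        assert fit.converged
        assert fit.asymptote == pytest.approx(0.5, abs=1e-6)
        assert fit.scale == pytest.approx(2.0, abs=1e-6)
        assert fit.rate == pytest.approx(0.7, abs=1e-6)

    def test_exact_recovery_saturating(self):
        x = np.linspace(0, 10, 30)
        y = 3.0 - 3.0 * np.exp(-0.4 * x)
        fit = fit_exponential(x, y, form="saturating")
        assert fit.converged
        assert fit.asymptote == pytest.approx(3.0, abs=1e-5)
        assert fit.rate == pytest.approx(0.4, abs=1e-5)

    def test_constant_input_degenerates_gracefully(self):
        x = np.linspace(0, 5, 10)
        fit = fit_exponential(x, np.full(10, 2.0), form="decay")
        assert fit(100.0) == pytest.approx(2.0, abs=0.05)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 8, 40)
        errs = []
        for _ in range(50):
            y = 1.0 + 4.0 * np.exp(-0.5 * x) + rng.normal(0, 0.05, x.size)
            fit = fit_exponential(x, y, form="decay")
            errs.append(fit.rate - 0.5)
        assert abs(np.mean(errs)) < 3 * np.std(errs) / np.sqrt(len(errs)) + 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 2], [1, 2])


class TestPopulationTests:
    def test_signed_rank_type_one_error_near_nominal(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            vals = rng.normal(0, 1, 20)
            if signed_rank_test(vals) < 0.05:
                rejections += 1
        assert rejections / n_sim < 0.10

    def test_identical_samples_ks_p_one(self):
        a = np.arange(10, dtype=float)
        assert ks_test(a, a) == pytest.approx(1.0)

    def test_sign_test_closed_form_all_positive(self):
        n = 10
        above, below, p = sign_test_majority(np.ones(n))
        assert (above, below) == (n, 0)
        assert p == pytest.approx(2.0 ** (1 - n))

    def test_small_samples_refused(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0, 2.0])
        with pytest.raises(ValueError):
            ks_test([1.0], [2.0])
        with pytest.raises(ValueError):
            sign_test_majority([1.0, -1.0])
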