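"""In vivo pipeline: filtering, detection, unit labels, PSTHs, modulation
index, excitation criterion, latency/jitter, inhibition duration and late
sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from ffikit import extracellular as ec
from ffikit import synth


class TestBandpass:
    def test_dc_removed(self):
        out = ec.bandpass(np.full(25_000, 3.0), 25_000.0)
        assert np.max(np.abs(out[1000:-1000])) < 1e-6

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(50_000) / 25_000.0
        x = np.sin(2 * np.pi * 1000.0 * t)
        out = ec.bandpass(x, 25_000.0)
        mid = out[5000:-5000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_line_noise_attenuated_20db(self):
        t = np.arange(250_000) / 25_000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = ec.bandpass(x, 25_000.0)
        assert np.abs(out[25_000:-25_000]).max() < 0.1

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ec.bandpass(np.zeros(100), 25_000.0, low=5000, high=300)


class TestDetectEvents:
    def test_recall_at_snr8(self, snr8_session):
        """>= 95% of planted SNR-8 spikes recovered within 0.5 ms."""
        session, truth = snr8_session
        filtered = ec.bandpass(session.trace, session.fs)
        train = ec.detect_events(filtered, session.fs)
        planted = truth.spike_times["u0"]
        matched = sum(np.min(np.abs(train.event_times - t0)) < 0.0005
                      for t0 in planted if 0.01 < t0 < session.duration - 0.01)
        assert matched / planted.size >= 0.95

    def test_noise_false_rate_below_gaussian_tail(self, noise_only_trace):
        """Events on pure noise stay below the per-sample tail bound
        fs * Phi(-4) (each event needs at least one sample beyond 4 SD)."""
        trace, fs = noise_only_trace
        filtered = ec.bandpass(trace, fs)
        train = ec.detect_events(filtered, fs)
        bound = fs * sps.norm.sf(4.0) * 60.0
        assert train.n_events < bound

    def test_zero_trace_yields_no_events(self):
        train = ec.detect_events(np.zeros(50_000), 25_000.0)
        assert train.n_events == 0


class TestUnitLabels:
    def test_regular_train_is_single(self):
        t = np.arange(0, 100, 0.1)
        train = ec.SpikeTrain("u", t)
        assert ec.classify_isolation(train) == "single"

    def test_isi_fraction_boundary(self):
        # 1000 ISIs: 2 short ones (0.2%) -> multi; exactly 1 (0.1%, not
        # strictly greater than the rule's 0.1%) -> still single
        base = np.arange(999) * 0.1
        two = np.sort(np.concatenate([base, [base[10] + 0.001,
                                             base[20] + 0.001]]))
        base1 = np.arange(1000) * 0.1
        one = np.sort(np.concatenate([base1, [base1[10] + 0.001]]))
        assert ec.classify_isolation(ec.SpikeTrain("a", two)) == "multi"
        assert ec.classify_isolation(ec.SpikeTrain("b", one)) == "single"

    def test_too_few_events_flagged(self):
        with pytest.raises(ValueError):
            ec.classify_isolation(ec.SpikeTrain("u", np.array([1.0])))

    @pytest.mark.parametrize("width", [0.3, 1.2])
    def test_spike_width_round_trip(self, width):
        tem, _ = synth.spike_template(width, 5.0, 25_000.0)
        measured = ec.spike_width(tem, 25_000.0)
        assert abs(measured - width) <= 1.0 / 25_000.0 * 1000.0 + 1e-9

    def test_reversed_template_flagged(self):
        tem, _ = synth.spike_template(0.5, 5.0, 25_000.0)
        with pytest.raises(ValueError):
            ec.spike_width(tem[::-1], 25_000.0)

    @pytest.mark.parametrize("width,expected", [(0.3, "IN"), (0.6, "PC"),
                                                (0.4, "PC")])
    def test_cell_type_rule_strict_boundary(self, width, expected):
        assert ec.classify_cell_type(width) == expected

    def test_end_to_end_cell_type_recovery(self):
        """Detection -> width -> type recovers >= 95% of labels at SNR 8."""
        widths = [0.7] * 6 + [0.25] * 6
        correct = 0
        for i, w in enumerate(widths):
            unit = synth.UnitSpec(f"u{i}", synth.RateProfile(10.0),
                                  waveform_width=w, snr=8.0, refractory=2.5)
            session, _ = synth.gen_extracellular_session(
                [unit], n_trials=15, stim_period=2.0, seed=300 + i)
            filtered = ec.bandpass(session.trace, session.fs)
            train = ec.detect_events(filtered, session.fs)
            mean_wf = train.waveforms.mean(axis=0)
            label = ec.classify_cell_type(ec.spike_width(mean_wf, session.fs))
            correct += label == ("PC" if w >= 0.4 else "IN")
        assert correct / len(widths) >= 0.95


class TestPsth:
    def test_flat_unit_bins_near_baseline(self):
        t = synth.gen_spike_times(synth.RateProfile(10.0), 500, 2.0,
                                  refractory_ms=0.0, seed=0)
        psth = ec.build_psth(t, np.arange(1, 500) * 2.0, window=(-0.5, 0.5),
                             binsize=0.05, t_stop=1000.0)
        se = np.sqrt(10.0 / (499 * 0.05))
        assert np.all(np.abs(psth.rates - 10.0) < 5 * se)

    def test_silenced_window_bins_zero(self):
        prof = synth.RateProfile(10.0, segments=((0.0, 0.1, 0.0),))
        t = synth.gen_spike_times(prof, 200, 2.0, seed=1)
        psth = ec.build_psth(t, np.arange(1, 200) * 2.0, window=(-0.2, 0.2),
                             binsize=0.01, t_stop=400.0)
        starts = psth.bin_edges[:-1]
        in_window = (starts >= -1e-9) & (psth.bin_edges[1:] <= 0.1 + 1e-9)
        assert np.all(psth.rates[in_window] == 0)

    def test_empty_train_all_zero(self):
        psth = ec.build_psth(np.empty(0), np.array([1.0, 2.0]),
                             window=(-0.5, 0.5), binsize=0.1)
        assert np.all(psth.rates == 0)

    def test_no_valid_trials_raises(self):
        with pytest.raises(ValueError):
            ec.build_psth(np.array([1.0]), np.array([0.1]), window=(-1.0, 0.5))

    def test_normalized_baseline_averages_one(self):
        t = synth.gen_spike_times(synth.RateProfile(7.0), 100, 2.0, seed=2)
        psth = ec.build_psth(t, np.arange(1, 100) * 2.0, window=(-1.0, 0.5),
                             binsize=0.05, t_stop=200.0)
        norm = ec.normalize_psth(psth)
        assert norm.baseline_rate() == pytest.approx(1.0)

    def test_normalization_scale_invariant(self):
        t = synth.gen_spike_times(synth.RateProfile(7.0), 100, 2.0, seed=2)
        psth = ec.build_psth(t, np.arange(1, 100) * 2.0, window=(-1.0, 0.5),
                             binsize=0.05, t_stop=200.0)
        doubled = ec.Psth(psth.bin_edges, psth.rates * 2, psth.n_trials)
        a = ec.normalize_psth(psth)
        b = ec.normalize_psth(doubled)
        assert np.allclose(a.rates, b.rates)

    def test_zero_baseline_unit_excluded(self):
        psth = ec.Psth(np.arange(-1.0, 0.51, 0.05), np.zeros(30), 10)
        with pytest.raises(ValueError, match="zero baseline"):
            ec.normalize_psth(psth)


class TestModulationIndex:
    def test_complete_suppression_is_minus_one(self):
        # spikes only before the stimulus: MI must be exactly -1
        stims = np.arange(1, 50) * 2.0
        events = np.sort(np.concatenate([stims - 0.5, stims - 0.25]))
        res = ec.modulation_index(events, stims, t_stop=100.0)
        assert res.MI == -1.0
        assert res.FR_pre > 0 and res.FR_post == 0

    def test_equal_rates_give_zero(self):
        # one spike in each window at matched rates: FR_pre == FR_post
        stims = np.arange(1, 50) * 2.0
        events = np.sort(np.concatenate([stims - 0.05, stims + 0.05]))
        res = ec.modulation_index(events, stims, pre_window=0.1,
                                  post_window=0.1, t_stop=100.0)
        assert res.FR_pre == pytest.approx(res.FR_post)
        assert res.MI == pytest.approx(0.0)

    def test_undefined_when_both_windows_empty(self):
        stims = np.array([10.0])
        with pytest.warns(UserWarning, match="MI undefined"):
            res = ec.modulation_index(np.array([100.0]), stims, t_stop=200.0)
        assert res.MI is None

    @given(hst.lists(hst.floats(0.0, 100.0), min_size=1, max_size=300))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mi_bounded_property(self, times):
        """MI always lies in [-1, 1]; -1 iff silent post window."""
        events = np.sort(np.asarray(times))
        stims = np.arange(2, 99, 2.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ec.modulation_index(events, stims, t_stop=120.0)
        if res.MI is not None:
            assert -1.0 <= res.MI <= 1.0
            if res.MI == -1.0:
                assert res.FR_post == 0.0 and res.FR_pre > 0.0


class TestExcitation:
    @staticmethod
    def _psth5(times, stims, t_stop):
        return ec.build_psth(times, stims, window=(-1.0, 0.03), binsize=0.005,
                             t_stop=t_stop)

    def test_null_false_positive_rate(self):
        """Flat units: the 4-SD rule almost never flags excitation."""
        stims = np.arange(1, 200) * 5.0
        hits = 0
        for i in range(100):
            t = synth.gen_spike_times(synth.RateProfile(10.0), 200, 5.0,
                                      refractory_ms=0.0, seed=600 + i)
            excited, _ = ec.detect_excitation(self._psth5(t, stims, 1000.0))
            hits += excited
        assert hits <= 3

    def test_biphasic_units_detected(self):
        stims = np.arange(1, 200) * 5.0
        hits = 0
        n = 40
        for i in range(n):
            t = synth.gen_spike_times(synth.profile_preset("in_biphasic"),
                                      200, 5.0, seed=900 + i)
            excited, bins = ec.detect_excitation(self._psth5(t, stims, 1000.0))
            hits += excited
        assert hits / n >= 0.95

    def test_silenced_unit_not_excited(self):
        prof = synth.RateProfile(10.0, segments=((0.0, 0.1, 0.0),))
        stims = np.arange(1, 200) * 5.0
        t = synth.gen_spike_times(prof, 200, 5.0, seed=5)
        excited, bins = ec.detect_excitation(self._psth5(t, stims, 1000.0))
        assert not excited and bins == []


class TestLatency:
    def test_latency_of_short_epoch(self):
        prof = synth.RateProfile(5.0, segments=((0.009, 0.011, 40.0),))
        stims = np.arange(1, 400) * 2.0
        t = synth.gen_spike_times(prof, 400, 2.0, seed=8)
        lat, jit, prob = ec.response_latency(t, stims, t_stop=800.0)
        assert lat == pytest.approx(10.0, abs=1.5)

    def test_single_reliable_spike(self):
        stims = np.arange(1, 100) * 2.0
        events = stims + 0.008
        lat, jit, prob = ec.response_latency(events, stims, t_stop=200.0)
        assert prob == 1.0
        assert jit == pytest.approx(0.0, abs=1e-9)
        assert lat == pytest.approx(8.5, abs=1.0)

    def test_silent_unit_returns_absent(self):
        stims = np.arange(1, 50) * 2.0
        lat, jit, prob = ec.response_latency(stims - 0.5, stims, t_stop=100.0)
        assert lat is None and jit is None and prob is None


class TestInhibitionDuration:
    @staticmethod
    def _recovery_psth(tau, binsize=0.01):
        edges = np.arange(-1.0, 2.0 + binsize / 2, binsize)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rates = np.where(centers < 0, 1.0, 1.0 - np.exp(-np.maximum(centers, 0)
                                                        / tau))
        return ec.Psth(edges, rates, 100)

    @pytest.mark.parametrize("tau,expected", [(0.352, 244.0), (0.1717, 119.0)])
    def test_exponential_recovery_crossing(self, tau, expected):
        dur = ec.inhibition_duration(self._recovery_psth(tau),
                                     baseline_rate=1.0)
        assert abs(dur - expected) <= 10.0  # one bin of resolution

    def test_flat_control_has_no_duration(self):
        edges = np.arange(-1.0, 2.0, 0.01)
        psth = ec.Psth(edges, np.ones(edges.size - 1), 100)
        assert ec.inhibition_duration(psth, baseline_rate=1.0) is None

    def test_never_recovering_returns_absent(self):
        edges = np.arange(-1.0, 2.0, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rates = np.where(centers < 0, 1.0, 0.0)
        psth = ec.Psth(edges, rates, 100)
        assert ec.inhibition_duration(psth, baseline_rate=1.0) is None


class TestLateSort:
    @staticmethod
    def _psth_with_late(rate):
        edges = np.arange(-1.0, 1.0, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rates = np.where((centers >= 0.2) & (centers < 0.5), rate, 1.0)
        return ec.Psth(edges, rates, 100, normalized=True)

    def test_distinct_rates_quartile_counts(self):
        psths = [self._psth_with_late(r) for r in [0.1, 0.2, 0.9, 1.0, 1.1,
                                                   1.2, 2.0, 3.0]]
        labels = ec.late_response_sort(psths)
        assert labels.count("late_excited") == 2
        assert labels.count("late_inhibited") == 2
        assert labels[0] == "late_inhibited" and labels[-1] == "late_excited"

    def test_identical_rates_flagged_degenerate(self):
        psths = [self._psth_with_late(1.0) for _ in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            ec.late_response_sort(psths)

    def test_fewer_than_four_units_rejected(self):
        with pytest.raises(ValueError):
            ec.late_response_sort([self._psth_with_late(1.0)] * 3)

    def test_planted_rebound_units_occupy_top_quartile(self):
        """Units with a 2x rebound in 200-500 ms land in the top quartile."""
        stims = np.arange(1, 200) * 5.0
        psths = []
        rebound_idx = {0, 1}
        for i in range(8):
            segs = ((0.2, 0.5, 2.0),) if i in rebound_idx else ()
            t = synth.gen_spike_times(synth.RateProfile(10.0, segments=segs),
                                      200, 5.0, seed=40 + i)
            psth = ec.build_psth(t, stims, window=(-1.0, 0.6), binsize=0.01,
                                 t_stop=1000.0)
            psths.append(ec.normalize_psth(psth))
        labels = ec.late_response_sort(psths)
        assert all(labels[i] == "late_excited" for i in rebound_idx)
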