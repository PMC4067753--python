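"""Spike/trace measurements against constructed and generator oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nigranet.errors import (
    DegenerateBaselineError,
    NoThresholdError,
    UndefinedCorrelationError,
    UndefinedFWHMError,
    WindowCollisionError,
)
from nigranet.ephys_analysis import (
    classify_response,
    detect_spikes,
    ipsc_kinetics,
    percent_inhibition,
    phase_metrics,
    psth,
    psth_fwhm,
    train_amplitudes,
)
from nigranet.io import Trace
from nigranet.neuron_model import simulate_neuron
from nigranet.synth_data import gen_ipsc_trace


class TestDetectSpikes:
    def test_pacemaker_count_matches_simulation(self, params25):
        v, spk = simulate_neuron(params25, duration=10.0)
        det = detect_spikes(v)
        assert abs(det.size - spk.size) <= 1

    def test_flat_trace_empty(self):
        v = Trace(np.full(10_000, -60.0), 0.05)
        assert detect_spikes(v).size == 0

    def test_close_events_merged(self):
        # two constructed spikes 0.5 ms apart collapse to one
        dt = 0.05
        v = np.full(4000, -60.0)
        for t0 in (100.0, 100.5):
            i = int(t0 / dt)
            v[i:i + 10] = np.linspace(-60, 10, 10)
            v[i + 10:i + 14] = np.linspace(10, -60, 4)
        n = detect_spikes(Trace(np.maximum.reduce([v]), dt)).size
        assert n == 1


class TestPhaseMetrics:
    @staticmethod
    def _ramp_waveform(v_at_crossing=-45.0):
        # dV/dt rises linearly; crosses 10 mV/ms exactly at the chosen V
        dt = 0.05
        t = np.arange(0, 20, dt)
        dvdt = t  # mV/ms, crosses 10 at t = 10 ms
        v = -55.0 + np.cumsum(dvdt) * dt
        shift = v_at_crossing - np.interp(10.0, t, v)
        return Trace(v + shift, dt)

    def test_threshold_at_constructed_crossing(self):
        m = phase_metrics(self._ramp_waveform(-45.0))
        # half-sample derivative offset bounds the error at dV(tc) * dt/2
        assert m.voltage_threshold == pytest.approx(-45.0, abs=0.3)

    def test_subthreshold_raises(self):
        dt = 0.05
        v = -60 + 2.0 * np.sin(np.arange(0, 50, dt) / 5.0)
        with pytest.raises(NoThresholdError):
            phase_metrics(Trace(v, dt))

    def test_time_offset_invariance(self):
        w = self._ramp_waveform(-45.0)
        padded = Trace(np.concatenate([np.full(100, w.data[0]), w.data]),
                       w.dt)
        a, b = phase_metrics(w), phase_metrics(padded)
        assert a.voltage_threshold == pytest.approx(b.voltage_threshold,
                                                    abs=0.2)


class TestPSTH:
    def test_rate_mode_recovers_homogeneous_rate(self, rng):
        trials = [np.sort(rng.uniform(0, 2, rng.poisson(40)))
                  for _ in range(100)]
        p = psth(trials, 1.0, bin=5.0, window=(-500, 500), normalize="rate")
        assert p.values.mean() == pytest.approx(20.0, rel=0.05)

    def test_zscore_baseline_identity(self, rng):
        trials = [np.sort(rng.uniform(0, 2, 50)) for _ in range(50)]
        p = psth(trials, 1.0, bin=5.0, window=(-500, 500),
                 normalize="zscore")
        base = p.values[p.centers < 0]
        assert base.mean() == pytest.approx(0.0, abs=1e-9)
        assert base.std() == pytest.approx(1.0, abs=1e-9)

    def test_counts_match_independent_histogram(self, rng):
        for _ in range(20):
            trials = [np.sort(rng.uniform(0, 2, rng.integers(0, 80)))
                      for _ in range(5)]
            p = psth(trials, 1.0, bin=10.0, window=(-200, 200))
            # brute-force oracle: loop and count
            edges = np.arange(-200, 201, 10.0)
            expected = np.zeros(edges.size - 1)
            for tr in trials:
                for s in tr:
                    rel = (s - 1.0) * 1e3
                    for b in range(edges.size - 1):
                        if edges[b] <= rel < edges[b + 1]:
                            expected[b] += 1
            assert np.array_equal(p.counts, expected)

    def test_counts_conserved(self, rng):
        trials = [np.sort(rng.uniform(0.5, 1.5, 60)) for _ in range(10)]
        p = psth(trials, 1.0, bin=5.0, window=(-500, 500))
        total = sum(np.count_nonzero((t >= 0.5) & (t < 1.5)) for t in trials)
        assert p.counts.sum() == total


class TestFWHM:
    @staticmethod
    def _series(values, bin=5.0, n_pre=40):
        v = np.concatenate([np.zeros(n_pre), values, np.zeros(10)])
        edges = (np.arange(v.size + 1) - n_pre) * bin
        from nigranet.ephys_analysis import PSTH
        return PSTH(edges=edges, counts=v, values=v, mode="counts",
                    n_trials=1)

    def test_rectangular_bump(self):
        assert psth_fwhm(self._series(np.full(4, 10.0))) == pytest.approx(
            20.0)

    def test_triangular_bump(self):
        # symmetric triangle (apex on a bin center): half-height chord is
        # half the base — apex 17.5 ms, base 35 ms -> 17.5 ms
        centers = np.arange(8) * 5.0 + 2.5
        tri = 10.0 * np.maximum(0.0, 1.0 - np.abs(centers - 17.5) / 17.5)
        assert psth_fwhm(self._series(tri)) == pytest.approx(17.5, abs=0.1)

    def test_flat_series_undefined(self):
        with pytest.raises(UndefinedFWHMError):
            psth_fwhm(self._series(np.zeros(4)))


class TestIPSCKinetics:
    def test_conductance_formula(self):
        # 100 pA at +20 mV with E_Cl = -70 -> 100/90 nS
        tr = gen_ipsc_trace(amplitude=100.0, noise_sd=0.0, v_hold=20.0,
                            n_stimuli=1)
        k = ipsc_kinetics(tr)[0]
        assert k.peak_conductance == pytest.approx(100.0 / 90.0, rel=0.02)

    def test_flat_trace_no_events(self):
        tr = Trace(np.zeros(20_000), 0.05, units="pA", v_hold=20.0,
                   stim_times=[20.0, 120.0])
        assert ipsc_kinetics(tr) == [None, None]

    def test_feedforward_kinetics_round_trip(self):
        tr = gen_ipsc_trace(latency=2.51, rise_tau=0.75, decay_tau=9.00,
                            noise_sd=0.0, dt=0.025, n_stimuli=1)
        k = ipsc_kinetics(tr)[0]
        assert k.latency == pytest.approx(2.51, rel=0.02)
        assert k.decay_tau == pytest.approx(9.00, rel=0.02)

    def test_kinetics_round_trip_property(self):
        """Noiseless random draws recover latency/rise/decay within 2%."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            lat = rng.uniform(1.5, 3.0)
            rt = rng.uniform(0.4, 1.0)
            dtau = rng.uniform(4.0, 10.0)
            tr = gen_ipsc_trace(latency=lat, rise_tau=rt, decay_tau=dtau,
                                amplitude=rng.uniform(50, 300),
                                n_stimuli=1, noise_sd=0.0, dt=0.025)
            k = ipsc_kinetics(tr)[0]
            assert k.latency == pytest.approx(lat, rel=0.02)
            assert k.rise_20_80 == pytest.approx(tr.meta["rise_20_80"],
                                                 rel=0.02)
            assert k.decay_tau == pytest.approx(dtau, rel=0.02)


class TestTrainAmplitudes:
    def test_constructed_ppr(self):
        # constructed peaks of 100 and 91 pA -> PPR 0.91
        dt = 0.05
        from nigranet.neuron_model import dual_exp_kernel
        kern = dual_exp_kernel(0.53, 5.64, dt)
        data = np.zeros(8000)
        for st_ms, amp in [(20.0, 100.0), (120.0, 91.0)]:
            i = int(st_ms / dt)
            data[i:i + kern.size] += amp * kern
        tr = Trace(data, dt, units="pA", v_hold=20.0,
                   stim_times=[20.0, 120.0])
        res = train_amplitudes(tr)
        assert res["ppr"] == pytest.approx(0.91, abs=0.01)

    def test_identical_events_unity_ppr(self):
        tr = gen_ipsc_trace(n_stimuli=5, stim_rate=10.0, noise_sd=0.0)
        res = train_amplitudes(tr)
        assert res["ppr"] == pytest.approx(1.0, abs=0.02)
        assert res["steady_state_ratio"] == pytest.approx(1.0, abs=0.02)
        # tonic amplitudes carry the summation tail
        assert np.all(res["tonics"][1:] >= res["peaks"][1:] - 1e-9)

    def test_window_collision(self):
        tr = gen_ipsc_trace(n_stimuli=3, stim_rate=10.0)
        with pytest.raises(WindowCollisionError):
            train_amplitudes(tr, stim_times=[10.0, 14.0, 18.0])


class TestPercentInhibition:
    @pytest.mark.parametrize("nc, nr, expected", [
        (0, 10, 100.0), (10, 10, 0.0), (4, 16, 75.0)])
    def test_arithmetic(self, nc, nr, expected, rng):
        ctl = [rng.uniform(0, 0.1, nc)]
        ref = [rng.uniform(0, 0.1, nr)]
        assert percent_inhibition(ctl, ref, (0.0, 0.1)) == pytest.approx(
            expected)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            percent_inhibition([np.array([0.05])], [np.array([])],
                               (0.0, 0.1))


class TestClassifyResponse:
    @staticmethod
    def _make(post, rng, n_base=60):
        base = rng.poisson(5, n_base).astype(float)
        v = np.concatenate([base, post])
        edges = (np.arange(v.size + 1) - n_base) * 5.0
        from nigranet.ephys_analysis import PSTH
        return PSTH(edges=edges, counts=v, values=v, mode="counts",
                    n_trials=10)

    def test_mixed_excitation_then_suppression(self, rng):
        post = np.array([30.0, 30.0, 0.0, 0.0, 0.0, 0.0, 5.0, 5.0])
        label, lat = classify_response(self._make(post, rng))
        assert label == "mixed"
        assert 0.0 <= lat <= 5.0

    def test_pure_delayed_suppression(self, rng):
        post = np.array([5.0, 0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0])
        label, lat = classify_response(self._make(post, rng))
        assert label == "inhibited"
        assert lat == pytest.approx(5.0)

    def test_flat_is_none(self, rng):
        post = rng.poisson(5, 8).astype(float)
        label, lat = classify_response(self._make(post, rng))
        assert label == "none"
        assert np.isnan(lat)

    def test_deeper_suppression_never_unclassifies(self, rng):
        # scaling a suppression deeper cannot flip inhibited -> none
        post = np.array([5.0, 1.0, 1.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        p = self._make(post, rng)
        label1, _ = classify_response(p)
        post2 = np.array([5.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        p2 = self._make(post2, rng)
        label2, _ = classify_response(p2)
        if label1 == "inhibited":
            assert label2 == "inhibited"

    def test_degenerate_baseline(self):
        from nigranet.ephys_analysis import PSTH
        v = np.concatenate([np.full(60, 5.0), np.zeros(8)])
        edges = (np.arange(v.size + 1) - 60) * 5.0
        p = PSTH(edges=edges, counts=v, values=v, mode="counts", n_trials=1)
        with pytest.raises(DegenerateBaselineError):
            classify_response(p)
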