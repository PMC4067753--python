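"""Trace- and spike-level measurements.

Voltage traces: spike detection at the point of maximum acceleration,
phase-plot threshold metrics. Spike trains: peristimulus time histograms
(counts / rate / z-score), FWHM of the evoked peak, percent inhibition, and
response classification for in vivo photostimulation. Clamp traces: IPSC
onset/latency, 20-80% rise time, single-exponential decay fit, peak
amplitude and conductance (g = IPSC_peak / (V_m - E_Cl), E_Cl = -70 mV),
and evoked-train amplitude/depression statistics (PPR, steady-state ratio).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    InvalidSpecError,
    NoThresholdError,
    UndefinedCorrelationError,
    UndefinedFWHMError,
    WindowCollisionError,
)
from .io import Trace

E_CL = -70.0  # mV, GABA-A reversal from the Nernst estimate


# ---------------------------------------------------------------------------
# voltage traces
# ---------------------------------------------------------------------------

def detect_spikes(voltage: Trace, prominence: float = 20.0,
                  merge_window: float = 1.0) -> np.ndarray:
    """Spike times (ms) at the threshold of maximum acceleration.

    Candidate events are voltage peaks with at least ``prominence`` mV of
    excursion (rejects noise); within each event's upstroke the spike time
    is the sample of maximal d2V/dt2. Events closer than ``merge_window`` ms
    are merged. A flat trace yields an empty result.
    """
    v = voltage.data
    dt = voltage.dt
    peaks, _ = signal.find_peaks(v, prominence=prominence)
    if peaks.size == 0:
        return np.empty(0)
    accel = np.gradient(np.gradient(v, dt), dt)
    back = int(round(3.0 / dt))
    times = []
    for p in peaks:
        i0 = max(0, p - back)
        times.append((i0 + int(np.argmax(accel[i0:p + 1]))) * dt)
    times = np.sort(np.asarray(times))
    merged = [times[0]]
    for t in times[1:]:
        if t - merged[-1] >= merge_window:
            merged.append(t)
    return np.asarray(merged)


@dataclass
class PhaseMetrics:
    """Phase-plot (dV/dt vs V) metrics of an average spike waveform."""

    voltage_threshold: float      # mV, V where dV/dt first reaches 10 mV/ms
    threshold_slope: float        # (mV/ms)/mV from a linear fit at crossing
    perithreshold_slope: float    # (mV/ms)/mV over 7 ms after the
                                  # perithreshold dV/dt peak


def phase_metrics(waveform: Trace, dvdt_criterion: float = 10.0,
                  kink_window: float = 7.0,
                  fit_halfwidth: int = 3) -> PhaseMetrics:
    """Voltage threshold and phase-plot slopes of one spike waveform.

    The threshold is the membrane potential at which the phase-plot slope
    (dV/dt) first reaches ``dvdt_criterion`` mV/ms (linear interpolation
    between samples). The perithreshold slope is the slope of dV/dt vs V
    over ``kink_window`` ms following the peak of the perithreshold dV/dt
    (the last subthreshold local maximum before the upstroke), truncated at
    the threshold crossing.
    """
    v = waveform.data
    dt = waveform.dt
    if v.size * dt < 5.0:
        raise InvalidSpecError("waveform needs >= 5 ms of context")
    dvdt = np.gradient(v, dt)
    above = np.nonzero(dvdt >= dvdt_criterion)[0]
    if above.size == 0:
        raise NoThresholdError(
            f"dV/dt never reaches {dvdt_criterion} mV/ms")
    i = int(above[0])
    if i == 0:
        v_thr = v[0]
    else:
        f = (dvdt_criterion - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
        v_thr = v[i - 1] + f * (v[i] - v[i - 1])
    lo = max(0, i - fit_halfwidth)
    hi = min(v.size, i + fit_halfwidth + 1)
    thr_slope = _safe_slope(v[lo:hi], dvdt[lo:hi])
    # perithreshold dV/dt peak: maximum of dV/dt before the upstroke
    pre = dvdt[:i] if i > 1 else dvdt[:1]
    ip = int(np.argmax(pre))
    iw = min(i + 1, ip + int(round(kink_window / dt)) + 1)
    peri_slope = _safe_slope(v[ip:iw], dvdt[ip:iw])
    return PhaseMetrics(float(v_thr), float(thr_slope), float(peri_slope))


def _safe_slope(x, y):
    if x.size < 2 or np.ptp(x) == 0:
        return np.nan
    return np.polyfit(x, y, 1)[0]


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

@dataclass
class PSTH:
    """Binned peristimulus series. ``values`` are in the requested
    normalization; ``counts`` are always raw summed counts per bin."""

    edges: np.ndarray      # ms, relative to the align event
    counts: np.ndarray
    values: np.ndarray
    mode: str
    n_trials: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin(self) -> float:
        return float(self.edges[1] - self.edges[0])


def psth(spike_trials, align_events, bin: float = 5.0,
         window: tuple = (-500.0, 500.0), normalize: str = "counts") -> PSTH:
    """Peristimulus time histogram across trials.

    spike_trials : list of per-trial spike-time arrays, in seconds.
    align_events : one alignment time (s) per trial (scalar broadcast).
    bin, window : ms; bin must divide the window length.
    normalize : "counts", "rate" (Hz) or "zscore" (z against the pre-event
        bins, i.e. bins whose centers fall before the align event).
    """
    if len(spike_trials) == 0:
        raise InvalidSpecError("empty trial set")
    t0, t1 = window
    span = t1 - t0
    nbins = span / bin
    if abs(nbins - round(nbins)) > 1e-9:
        raise InvalidSpecError("bin must divide the window length")
    nbins = int(round(nbins))
    align = np.broadcast_to(np.asarray(align_events, dtype=float),
                            (len(spike_trials),))
    edges = t0 + np.arange(nbins + 1) * bin
    counts = np.zeros(nbins)
    for spikes, ev in zip(spike_trials, align):
        rel = (np.asarray(spikes, dtype=float) - ev) * 1e3  # ms
        counts += np.histogram(rel, bins=edges)[0]
    n_trials = len(spike_trials)
    if normalize == "counts":
        values = counts.copy()
    elif normalize == "rate":
        values = counts / (n_trials * bin * 1e-3)
    elif normalize == "zscore":
        centers = 0.5 * (edges[:-1] + edges[1:])
        base = counts[centers < 0]
        if base.size < 2 or base.std() == 0:
            raise DegenerateBaselineError("cannot z-score: degenerate baseline")
        values = (counts - base.mean()) / base.std()
    else:
        raise InvalidSpecError(f"unknown normalize mode {normalize!r}")
    return PSTH(edges=edges, counts=counts, values=values, mode=normalize,
                n_trials=n_trials)


def psth_fwhm(p: PSTH) -> float:
    """Full width at half maximum (ms) of the evoked peak above baseline.

    Baseline is the mean of the pre-event bins; the half level is
    baseline + (peak - baseline)/2, with linear interpolation between bin
    centers on each flank.
    """
    centers = p.centers
    base_bins = p.values[centers < 0]
    if base_bins.size == 0:
        raise InvalidSpecError("PSTH window contains no pre-event bins")
    baseline = base_bins.mean()
    post = centers >= 0
    if not np.any(p.values[post] > baseline):
        raise UndefinedFWHMError("no bin above baseline")
    ipk = int(np.argmax(np.where(post, p.values, -np.inf)))
    peak = p.values[ipk]
    half = baseline + 0.5 * (peak - baseline)
    y = p.values
    # walk left from the peak
    i = ipk
    while i > 0 and y[i - 1] > half:
        i -= 1
    if i == 0:
        left = centers[0]
    else:
        f = (y[i] - half) / (y[i] - y[i - 1])
        left = centers[i] - f * p.bin
    j = ipk
    while j < y.size - 1 and y[j + 1] > half:
        j += 1
    if j == y.size - 1:
        right = centers[-1]
    else:
        f = (y[j] - half) / (y[j] - y[j + 1])
        right = centers[j] + f * p.bin
    return float(right - left)


# ---------------------------------------------------------------------------
# IPSC kinetics
# ---------------------------------------------------------------------------

@dataclass
class IPSCKinetics:
    """Measured kinetics of one evoked synaptic current."""

    latency: float          # ms from stimulus to onset
    rise_20_80: float       # ms
    decay_tau: float        # ms (NaN when the fit is rejected)
    peak_amplitude: float   # pA relative to the pre-stimulus baseline
    peak_conductance: float  # nS, amplitude / (V_hold - E_Cl)
    r2: float               # decay-fit quality

    @property
    def decay_ok(self) -> bool:
        return np.isfinite(self.decay_tau)


def ipsc_kinetics(trace: Trace, stim_times=None, baseline: float = 5.0,
                  search_window: float = 10.0, detection_nsd: float = 3.0,
                  sustain: float = 0.5, e_cl: float = E_CL,
                  min_r2: float = 0.5) -> list:
    """Per-stimulus IPSC kinetics; entries are None where no event onset is
    found within ``search_window`` ms of the stimulus.

    Onset: first sample of an excursion exceeding ``detection_nsd`` baseline
    SDs sustained for ``sustain`` ms; the reported onset is the sample
    preceding the crossing. Rise: 20-80% time on the rising limb
    (interpolated). Decay: single-exponential fit from the peak to 90%
    recovery; fits with R^2 < ``min_r2`` are flagged (decay NaN).
    Amplitude: peak relative to the mean of the ``baseline`` ms preceding
    the stimulus; outward currents positive when holding above E_Cl.
    """
    stims = np.asarray(trace.stim_times if stim_times is None else stim_times,
                       dtype=float)
    dt = trace.dt
    sgn = 1.0
    if trace.v_hold is not None and trace.v_hold < e_cl:
        sgn = -1.0
    data = sgn * trace.data
    nb = int(round(baseline / dt))
    nw = int(round(search_window / dt))
    nsus = max(1, int(round(sustain / dt)))
    out = []
    stim_idx = np.round(stims / dt).astype(int)
    for k, i0 in enumerate(stim_idx):
        i_next = stim_idx[k + 1] if k + 1 < stim_idx.size else data.size
        base = data[max(0, i0 - nb):i0]
        if base.size == 0:
            out.append(None)
            continue
        bmean = base.mean()
        thr = max(detection_nsd * base.std(), 1e-9)
        seg = data[i0:min(i0 + nw + nsus, data.size)] - bmean
        above = seg > thr
        onset_rel = None
        run = 0
        for idx, a in enumerate(above):
            run = run + 1 if a else 0
            if run == nsus and idx - nsus + 1 <= nw:
                onset_rel = idx - nsus + 1
                break
        if onset_rel is None:
            out.append(None)
            continue
        i_on = i0 + max(onset_rel - 1, 0)  # sample before the crossing
        latency = (i_on - i0) * dt
        ev = data[i_on:i_next] - bmean
        ipk = int(np.argmax(ev))
        peak = ev[ipk]
        rise = _rise_20_80(ev[:ipk + 1], dt)
        tau, r2 = _fit_decay(ev, ipk, dt, skip=5.0 * rise)
        if r2 < min_r2:
            tau = np.nan
        v_hold = trace.v_hold
        g = np.nan if v_hold is None else peak * sgn / (v_hold - e_cl)
        out.append(IPSCKinetics(
            latency=float(latency), rise_20_80=float(rise),
            decay_tau=float(tau), peak_amplitude=float(peak),
            peak_conductance=float(g), r2=float(r2)))
    return out


def _rise_20_80(up: np.ndarray, dt: float) -> float:
    peak = up[-1]
    lo, hi = 0.2 * peak, 0.8 * peak
    i80 = np.nonzero(up >= hi)[0][0]
    i20 = np.nonzero(up[:i80 + 1] >= lo)[0][0]
    t80 = _cross_time(up, i80, hi, dt)
    t20 = _cross_time(up, i20, lo, dt)
    return t80 - t20


def _cross_time(y, i, level, dt):
    if i == 0 or y[i] == y[i - 1]:
        return i * dt
    f = (level - y[i - 1]) / (y[i] - y[i - 1])
    return (i - 1 + f) * dt


def _fit_decay(ev: np.ndarray, ipk: int, dt: float, skip: float = 0.0):
    # ``skip`` ms after the peak are excluded: there the rising exponential
    # still contaminates the decay and biases the fitted tau upward
    peak = ev[ipk]
    rec = np.nonzero(ev[ipk:] <= 0.1 * peak)[0]
    iend = ipk + (rec[0] if rec.size else ev[ipk:].size)
    i0 = min(ipk + int(round(skip / dt)), max(iend - 4, ipk))
    y = ev[i0:iend + 1]
    if y.size < 4:
        return np.nan, 0.0
    t = np.arange(y.size) * dt
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
            p0=[peak, max(t[-1] / 3, dt)], maxfev=5000)
    except RuntimeError:
        return np.nan, 0.0
    pred = popt[0] * np.exp(-t / popt[1])
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(popt[1]), float(r2)


# ---------------------------------------------------------------------------
# evoked trains
# ---------------------------------------------------------------------------

def train_amplitudes(trace: Trace, stim_times=None, window: float = 15.0,
                     pre_window: float = 1.0, e_cl: float = E_CL):
    """Per-stimulus peak and tonic amplitudes of an evoked train.

    peak_i is measured relative to the baseline immediately preceding
    stimulus i (``pre_window`` ms); tonic_i relative to the pre-train
    baseline, so it includes the summating tail of earlier events.
    Returns a dict with peaks, tonics, ``ppr`` = peak2/peak1 and
    ``steady_state_ratio`` = peak_last/peak1. Stimulus rates above 200 Hz
    leave no room for the measurement window and raise.
    """
    stims = np.asarray(trace.stim_times if stim_times is None else stim_times,
                       dtype=float)
    if stims.size < 2:
        raise InsufficientDataError("need >= 2 stimuli for train statistics")
    isi = np.diff(stims).min()
    if isi < 5.0:
        raise WindowCollisionError(
            f"stimulus interval {isi:.2f} ms (> 200 Hz): windows overlap")
    dt = trace.dt
    sgn = 1.0
    if trace.v_hold is not None and trace.v_hold < e_cl:
        sgn = -1.0
    data = sgn * trace.data
    npre = max(1, int(round(pre_window / dt)))
    win = min(window, isi)
    nwin = int(round(win / dt))
    i_first = int(round(stims[0] / dt))
    train_base = data[max(0, i_first - npre):i_first].mean()
    peaks, tonics = [], []
    for st in stims:
        i0 = int(round(st / dt))
        local_base = data[max(0, i0 - npre):i0].mean()
        seg = data[i0:i0 + nwin]
        peaks.append(seg.max() - local_base)
        tonics.append(seg.max() - train_base)
    peaks = np.asarray(peaks)
    tonics = np.asarray(tonics)
    return {
        "peaks": peaks, "tonics": tonics,
        "ppr": float(peaks[1] / peaks[0]),
        "steady_state_ratio": float(peaks[-1] / peaks[0]),
    }


# ---------------------------------------------------------------------------
# spiking responses
# ---------------------------------------------------------------------------

def percent_inhibition(spikes_control, spikes_reference,
                       window: tuple) -> float:
    """100 * (1 - count_control / count_reference) within the evoked window.

    The reference is the inhibition-blocked (or uncoupled) condition. Inputs
    are lists of per-trial spike-time arrays in seconds; window in seconds.
    Undefined (raises) when the reference count is zero.
    """
    t0, t1 = window
    c = sum(np.count_nonzero((np.asarray(s) >= t0) & (np.asarray(s) < t1))
            for s in spikes_control)
    r = sum(np.count_nonzero((np.asarray(s) >= t0) & (np.asarray(s) < t1))
            for s in spikes_reference)
    if r == 0:
        raise UndefinedCorrelationError(
            "reference spike count is zero; percent inhibition undefined")
    return float(min(100.0 * (1.0 - c / r), 100.0))


def classify_response(p: PSTH, excite_window: float = 10.0,
                      excite_nsd: float = 3.0, inhibit_nsd: float = 2.0,
                      min_baseline: float = 200.0):
    """Classify a photostimulation PSTH as excited/inhibited/mixed/none.

    Requires 5 ms bins and >= ``min_baseline`` ms of pre-stimulus baseline.
    Excited: any bin within ``excite_window`` ms post-stimulus above
    baseline + 3 SD. Inhibited: >= 2 consecutive post-stimulus bins below
    baseline - 2 SD. Returns (label, onset latency ms) where the latency is
    the start of the first significant bin (5 ms resolution); latency is
    NaN for "none".
    """
    centers = p.centers
    base = p.values[centers < 0]
    if base.size * p.bin < min_baseline:
        raise InvalidSpecError("need >= 200 ms of baseline bins")
    m, sd = base.mean(), base.std()
    if sd == 0:
        raise DegenerateBaselineError("baseline SD is zero")
    post = centers >= 0
    starts = p.edges[:-1]
    exc_bins = post & (starts < excite_window) & (p.values > m + excite_nsd * sd)
    low = post & (p.values < m - inhibit_nsd * sd)
    inh_start = None
    idx = np.nonzero(post)[0]
    for i in idx[:-1]:
        if low[i] and low[i + 1]:
            inh_start = starts[i]
            break
    excited = bool(np.any(exc_bins))
    inhibited = inh_start is not None
    if excited and inhibited:
        label = "mixed"
    elif excited:
        label = "excited"
    elif inhibited:
        label = "inhibited"
    else:
        return "none", float("nan")
    if excited:
        latency = float(starts[np.nonzero(exc_bins)[0][0]])
    else:
        latency = float(inh_start)
    return label, latency
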