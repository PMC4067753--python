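"""Pacemaker neuron model and dynamic-clamp-style conductance synthesis.

The single-neuron model is an exponential integrate-and-fire (EIF) neuron
with a constant depolarizing drive. This is the minimal model exhibiting the
two features that SNr projection neurons use to implement their peculiar
insensitivity to background inhibition: (i) a net inward membrane current
everywhere between the spike reset and threshold, so the cell fires
tonically with no synaptic input, and (ii) a positive slope conductance in
the perithreshold regime (the EIF exponential term), so hyperpolarizing
input is opposed by regenerative inward current. Combined with the small
driving force of GABA-A inhibition (E_inh = -70 mV) near the interspike
trajectory, the firing rate is far more sensitive to added excitatory
conductance (E_exc = 0 mV) than to added inhibitory conductance.

Membrane equation (units: pF, nS, mV, ms, pA; note pA/pF = mV/ms)::

    C dV/dt = -g_L (V - E_L) + g_L * dT * exp((V - V_T)/dT) + I_drive
              - g_e(t) (V - E_exc) - g_i(t) (V - E_inh) + I_stim(t)

A spike is recorded when V crosses ``v_cut`` (well above V_T, where the
exponential has diverged); V is then clamped to ``v_reset`` for the
refractory period. Integration is fixed-step exponential Euler at
dt = 0.025 ms by default (finer than a 30 kHz dynamic-clamp update).

Synaptic conductances are synthesized exactly as a digital dynamic clamp
would: Poisson event times convolved with a unit-peak dual-exponential
kernel (difference of exponentials, rise 0.5 ms / decay 5 ms class) scaled
by the unitary conductance (~0.15 nS for collateral inhibition).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

from ._util import rng_from, child_seeds
from .errors import (
    AccuracyError,
    DegenerateKernelError,
    IntegrationError,
    InvalidSpecError,
)
from .io import Trace

KERNEL_CUTOFF = 1e-4  # truncate kernel below this fraction of its peak


@dataclass(frozen=True)
class SynapseKernelSpec:
    """Dual-exponential synaptic kernel parameters.

    rise_tau, decay_tau : ms (decay > rise > 0)
    reversal : mV
    unitary_g : nS, peak conductance of one quantal event
    """

    rise_tau: float = 0.5
    decay_tau: float = 5.0
    reversal: float = -70.0
    unitary_g: float = 0.15

    def __post_init__(self):
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise InvalidSpecError("time constants must be positive")
        if self.decay_tau == self.rise_tau:
            raise DegenerateKernelError(
                "rise_tau == decay_tau: dual-exponential kernel degenerate "
                "(alpha function not silently substituted)"
            )
        if self.decay_tau < self.rise_tau:
            raise InvalidSpecError("decay_tau must exceed rise_tau")


# canonical kernels
COLLATERAL_IPSC = SynapseKernelSpec(0.5, 5.0, -70.0, 0.15)
DYNCLAMP_EPSC = SynapseKernelSpec(0.5, 5.0, 0.0, 0.15)


@dataclass
class ConductanceTrain:
    """A sampled non-negative conductance waveform (nS) at fixed dt (ms)."""

    g: np.ndarray
    dt: float
    events: np.ndarray  # event times, ms
    kernel: SynapseKernelSpec

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.events = np.asarray(self.events, dtype=float)


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Closed-form argmax of exp(-t/decay) - exp(-t/rise), in ms."""
    return (np.log(decay_tau / rise_tau)
            * rise_tau * decay_tau / (decay_tau - rise_tau))


def dual_exp_kernel(rise_tau: float, decay_tau: float, dt: float) -> np.ndarray:
    """Unit-peak dual-exponential kernel sampled at dt.

    k(t) = [exp(-t/decay) - exp(-t/rise)] / k_peak, truncated once the tail
    falls below ``KERNEL_CUTOFF`` of the peak.
    """
    if rise_tau <= 0 or decay_tau <= 0 or dt <= 0:
        raise InvalidSpecError("taus and dt must be positive")
    if decay_tau == rise_tau:
        raise DegenerateKernelError("rise_tau == decay_tau")
    if decay_tau < rise_tau:
        raise InvalidSpecError("decay_tau must exceed rise_tau")
    tp = kernel_peak_time(rise_tau, decay_tau)
    peak = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    # beyond the peak the tail is < exp(-t/decay)/peak; bound the support
    t_end = decay_tau * np.log(1.0 / (KERNEL_CUTOFF * peak)) + tp
    t = np.arange(0.0, t_end + dt, dt)
    k = (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / peak
    ip = int(np.argmax(k))
    below = np.nonzero(k[ip:] < KERNEL_CUTOFF)[0]
    if below.size:
        k = k[: ip + below[0]]
    return k


def kernel_integral(rise_tau: float, decay_tau: float) -> float:
    """Integral (ms) of the unit-peak kernel, closed form, untruncated."""
    tp = kernel_peak_time(rise_tau, decay_tau)
    peak = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    return (decay_tau - rise_tau) / peak


def poisson_event_times(rate: float, duration: float, seed=None) -> np.ndarray:
    """Homogeneous Poisson event times.

    rate in Hz, duration in seconds; returns sorted times in ms.
    """
    if rate < 0:
        raise InvalidSpecError("rate must be non-negative")
    rng = rng_from(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration * 1e3, size=n))


def synth_conductance(events, kernel_spec: SynapseKernelSpec, unitary_g: float,
                      duration: float, dt: float) -> ConductanceTrain:
    """Superpose unit-peak kernels scaled by ``unitary_g`` at event times.

    events in ms, duration in s, dt in ms. Events are binned to the nearest
    sample before convolution.
    """
    if dt > kernel_spec.rise_tau / 5:
        raise AccuracyError(
            f"dt={dt} ms too coarse for rise_tau={kernel_spec.rise_tau} ms "
            "(need dt <= rise_tau/5)")
    events = np.asarray(events, dtype=float)
    dur_ms = duration * 1e3
    if events.size and (events.min() < 0 or events.max() > dur_ms):
        raise InvalidSpecError("event times outside [0, duration]")
    n = int(round(dur_ms / dt))
    impulses = np.zeros(n)
    if events.size:
        idx = np.minimum(np.round(events / dt).astype(int), n - 1)
        np.add.at(impulses, idx, 1.0)
    k = dual_exp_kernel(kernel_spec.rise_tau, kernel_spec.decay_tau, dt)
    g = fftconvolve(impulses, k)[:n] * unitary_g
    np.clip(g, 0.0, None, out=g)  # fftconvolve round-off can dip below 0
    return ConductanceTrain(g=g, dt=dt, events=events, kernel=kernel_spec)


# ---------------------------------------------------------------------------
# neuron model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Exponential integrate-and-fire pacemaker parameters.

    Defaults give a tonically firing cell whose rate is weakly sensitive to
    inhibitory conductance but strongly sensitive to excitatory conductance,
    the SNr operating regime. ``drive`` (pA) is normally set by
    :func:`calibrate_drive` to hit a target tonic rate.
    """

    capacitance: float = 150.0   # pF
    g_leak: float = 5.0          # nS
    e_leak: float = -60.0        # mV
    drive: float = 0.0           # pA, constant pacemaker drive
    sharpness: float = 3.0       # mV, EIF spike-initiation sharpness (dT)
    threshold: float = -50.0     # mV, EIF soft threshold V_T
    reset: float = -70.0         # mV; AHP trough sits at E_inh, where the
                                 # inhibitory driving force vanishes
    refractory: float = 1.5      # ms
    e_inh: float = -70.0         # mV
    e_exc: float = 0.0           # mV
    # Saturating subthreshold inward current (persistent-Na / Ih class):
    # I = nap_max * sigmoid((nap_vhalf - V)/nap_k). Its negative slope
    # conductance below threshold compensates small tonic hyperpolarizing
    # currents (rate insensitivity to background inhibition) but saturates
    # at nap_max, so large synchronized inhibitory volleys remain
    # effective. This is the perithreshold positive-slope-conductance
    # mechanism of SNr pacemakers.
    nap_max: float = 250.0       # pA
    nap_vhalf: float = -55.0     # mV
    nap_k: float = 4.0           # mV

    @property
    def v_cut(self) -> float:
        """Hard spike-detection voltage (exponential has diverged)."""
        return self.threshold + 15.0 * self.sharpness


@njit(cache=True)
def _eif_loop(v0, c, gl, el, drive, dT, vT, vcut, vreset, refr_steps,
              einh, eexc, nap_max, nap_vhalf, nap_k,
              g_exc, g_inh, i_stim, dt):
    n = g_exc.shape[0]
    v = np.empty(n)
    spikes = np.empty(n, np.int64)
    k = 0
    vv = v0
    refr = 0
    for t in range(n):
        if refr > 0:
            refr -= 1
            vv = vreset
        else:
            x = (vv - vT) / dT
            if x > 40.0:
                x = 40.0  # cap the exponential; vv is about to be reset
            iexp = gl * dT * np.exp(x)
            inap = nap_max / (1.0 + np.exp((nap_vhalf - vv) / nap_k))
            b = gl + g_exc[t] + g_inh[t]
            a = (gl * el + g_exc[t] * eexc + g_inh[t] * einh
                 + drive + i_stim[t] + iexp + inap)
            vinf = a / b
            vv = vinf + (vv - vinf) * np.exp(-b * dt / c)
            if vv >= vcut:
                spikes[k] = t
                k += 1
                vv = vreset
                refr = refr_steps
        v[t] = vv
    return v, spikes[:k]


def simulate_neuron(params: NeuronParams, g_exc: ConductanceTrain | None = None,
                    g_inh: ConductanceTrain | None = None,
                    i_stim: np.ndarray | None = None,
                    duration: float = 1.0, dt: float = 0.025,
                    v0: float | None = None) -> tuple[Trace, np.ndarray]:
    """Integrate the EIF pacemaker; returns (voltage Trace, spike times ms).

    duration in s, dt in ms. Deterministic given its inputs; stochasticity
    enters only through the conductance trains.
    """
    if dt > 0.1:
        raise AccuracyError(f"dt={dt} ms too coarse (need <= 0.1 ms)")
    n = int(round(duration * 1e3 / dt))
    ge = np.zeros(n) if g_exc is None else _resampled(g_exc, dt, n)
    gi = np.zeros(n) if g_inh is None else _resampled(g_inh, dt, n)
    ist = np.zeros(n) if i_stim is None else np.asarray(i_stim, dtype=float)
    if ist.size != n:
        raise InvalidSpecError("i_stim length does not match duration/dt")
    v0 = params.reset if v0 is None else v0
    v, spk_idx = _eif_loop(
        v0, params.capacitance, params.g_leak, params.e_leak, params.drive,
        params.sharpness, params.threshold, params.v_cut, params.reset,
        int(round(params.refractory / dt)), params.e_inh, params.e_exc,
        params.nap_max, params.nap_vhalf, params.nap_k,
        ge, gi, ist, dt)
    if not np.all(np.isfinite(v)):
        bad = int(np.nonzero(~np.isfinite(v))[0][0])
        raise IntegrationError(
            f"non-finite voltage at step {bad} (t={bad * dt:.3f} ms)")
    return Trace(v, dt, units="mV"), spk_idx * dt


def _resampled(train: ConductanceTrain, dt: float, n: int) -> np.ndarray:
    if abs(train.dt - dt) > 1e-12:
        raise InvalidSpecError("conductance train dt differs from simulation dt")
    g = train.g
    if g.size < n:
        g = np.concatenate([g, np.zeros(n - g.size)])
    return g[:n]


def firing_rate(params: NeuronParams, duration: float = 2.0,
                dt: float = 0.025, discard: float = 0.2, **kw) -> float:
    """Tonic firing rate (Hz) over ``duration`` s, discarding a transient."""
    _, spikes = simulate_neuron(params, duration=duration, dt=dt, **kw)
    spikes = spikes[spikes >= discard * 1e3]
    return spikes.size / (duration - discard)


def calibrate_drive(params: NeuronParams, target_rate: float,
                    tol: float = 0.5, duration: float = 2.0,
                    drive_range: tuple = (-500.0, 2000.0)) -> NeuronParams:
    """Bisection on the pacemaker drive to hit ``target_rate`` +/- tol Hz."""
    if not (0 < target_rate <= 200):
        raise InvalidSpecError("target rate must be in (0, 200] Hz")
    lo, hi = drive_range
    f_lo = firing_rate(replace(params, drive=lo), duration)
    f_hi = firing_rate(replace(params, drive=hi), duration)
    if not (f_lo <= target_rate <= f_hi):
        raise InvalidSpecError(
            f"target rate {target_rate} Hz outside achievable range "
            f"[{f_lo:.1f}, {f_hi:.1f}] Hz for drive in {drive_range}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = firing_rate(replace(params, drive=mid), duration)
        if abs(f - target_rate) <= tol * 0.5:
            break
        if f < target_rate:
            lo = mid
        else:
            hi = mid
    return replace(params, drive=0.5 * (lo + hi))


def rate_sensitivity_curve(params: NeuronParams, deltas, which: str,
                           base_rates: tuple = (1000.0, 1000.0),
                           trial_duration: float = 2.0, seed: int = 0,
                           n_trials: int = 3,
                           exc_kernel: SynapseKernelSpec = DYNCLAMP_EPSC,
                           inh_kernel: SynapseKernelSpec = COLLATERAL_IPSC,
                           dt: float = 0.025, discard: float = 0.2):
    """Dynamic-clamp rate-sensitivity experiment.

    The neuron receives independent Poisson excitatory and inhibitory
    conductance barrages at ``base_rates`` (Hz of events). One of the two
    rates is incremented by each value in ``deltas`` and the mean firing
    rate is measured. Returns (deltas array, mean rates array, slope) with
    the slope in Hz of firing per Hz of added events (least squares).
    """
    if which not in ("exc", "inh"):
        raise InvalidSpecError("which must be 'exc' or 'inh'")
    deltas = np.asarray(deltas, dtype=float)
    base_e, base_i = base_rates
    if np.any(base_e + (deltas if which == "exc" else 0) > 5000 + 1e-9) or \
       np.any(base_i + (deltas if which == "inh" else 0) > 5000 + 1e-9):
        raise InvalidSpecError("total event rates must stay within [0, 5000] Hz")
    seeds = child_seeds(seed, deltas.size * n_trials * 2)
    rates = np.empty(deltas.size)
    si = 0
    for j, d in enumerate(deltas):
        re = base_e + (d if which == "exc" else 0.0)
        ri = base_i + (d if which == "inh" else 0.0)
        acc = 0.0
        for _ in range(n_trials):
            ev_e = poisson_event_times(re, trial_duration, seeds[si]); si += 1
            ev_i = poisson_event_times(ri, trial_duration, seeds[si]); si += 1
            ge = synth_conductance(ev_e, exc_kernel, exc_kernel.unitary_g,
                                   trial_duration, dt)
            gi = synth_conductance(ev_i, inh_kernel, inh_kernel.unitary_g,
                                   trial_duration, dt)
            _, spk = simulate_neuron(params, ge, gi, duration=trial_duration,
                                     dt=dt)
            spk = spk[spk >= discard * 1e3]
            acc += spk.size / (trial_duration - discard)
        rates[j] = acc / n_trials
    if deltas.size > 1 and np.ptp(deltas) > 0:
        slope = np.polyfit(deltas, rates, 1)[0]
    else:
        slope = np.nan
    return deltas, rates, slope


def predict_uipsc_rate(n_pre: float, r_pre: float, p_release: float) -> float:
    """Predicted rate (Hz) of unitary IPSCs from convergent presynaptic
    pacemakers: N_pre * R_pre * P_release."""
    if n_pre < 0 or r_pre < 0:
        raise InvalidSpecError("n_pre and r_pre must be non-negative")
    if not (0.0 <= p_release <= 1.0):
        raise InvalidSpecError("p_release must be a probability")
    return n_pre * r_pre * p_release
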