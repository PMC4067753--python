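"""Synthetic-data generators with known ground truth.

Every input class the analysis stack consumes can be generated here:

* :func:`gen_session` — in-vivo-like spike sessions: tonically firing units
  (gamma-renewal pacemakers at ~10-40 Hz) with a CS-locked rate transient
  whose amplitude is divisively attenuated by the pre-CS population
  activity, ``amplitude / (1 + g * A_pre)``. With feedback gain g = 0 the
  transient is independent of the population; g > 0 plants the negative
  PRE/RESP correlation the population-feedback pipeline is built to detect.
* :func:`gen_ipsc_trace` — voltage-clamp current traces with
  dual-exponential IPSC deflections at known latency/rise/decay, for
  round-trip testing of the kinetics measurements. Defaults follow the
  feedback-collateral kinetics class (latency 1.93 ms, fast rise, decay
  5.64 ms).
* :func:`gen_cracm_dataset` — photostimulation grids in the 1670 x 1000 um
  anatomical frame with Gaussian-footprint input maps per cell, optionally
  decoupled from soma positions.

All generators are pure functions of their spec including the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from ._util import rng_from, child_seeds
from .errors import InvalidSpecError, ResolutionError
from .io import SpikeSession, Trace
from .neuron_model import dual_exp_kernel
from .cracm_maps import StimGrid, ResponseMap, SN_WIDTH, SN_HEIGHT


# ---------------------------------------------------------------------------
# spike sessions
# ---------------------------------------------------------------------------

# Feedback gain at which generated sessions of the in-vivo scale (12 units,
# 71 trials) yield per-session PRE/RESP correlations near the experimentally
# observed scale (mean r about -0.13, vs the reported -0.12 +/- 0.05).
REFERENCE_FEEDBACK_GAIN = 0.3

@dataclass(frozen=True)
class SessionGenSpec:
    """Parameters of a synthetic recording session.

    feedback_gain g >= 0 couples each trial's transient to the population's
    normalized pre-CS rate A_pre: added rate = amplitude / (1 + g * A_pre).
    noise_cv adds multiplicative trial-to-trial amplitude variability.
    gamma_shape = 4 gives pacemaker-like ISI regularity (CV = 0.5).
    """

    n_units: int = 12
    n_trials: int = 71
    baseline_rate_range: tuple = (10.0, 40.0)
    transient_amplitude: float = 20.0  # Hz
    transient_duration: float = 0.2    # s
    feedback_gain: float = 0.0
    cs_time: float = 1.0               # s
    trial_duration: float = 2.0        # s
    noise_cv: float = 0.2
    pre_window: float = 0.5            # s before CS used to form A_pre
    gamma_shape: float = 4.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.baseline_rate_range
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("baseline rate range needs 0 < low <= high")
        if self.trial_duration <= 0 or self.transient_duration <= 0:
            raise InvalidSpecError("durations must be positive")
        if self.transient_amplitude < 0 or self.feedback_gain < 0:
            raise InvalidSpecError("amplitude and gain must be non-negative")
        if not (0 < self.cs_time < self.trial_duration):
            raise InvalidSpecError("cs_time must fall inside the trial")
        if self.cs_time + self.transient_duration > self.trial_duration:
            raise InvalidSpecError("transient extends past the trial end")
        if self.cs_time < self.pre_window:
            raise InvalidSpecError("pre-CS window extends before trial start")


def _gamma_renewal_trains(rate: float, shape: float, duration: float,
                          n_trials: int, rng) -> list:
    """Equilibrium gamma-renewal spike trains, one per trial (times in s).

    Simulated from a burn-in interval before t = 0 so the process is
    stationary on [0, duration]; mean rate equals ``rate`` exactly.
    """
    burn = 5.0 / rate
    total = duration + burn
    mean_isi = 1.0 / rate
    n_isi = int(np.ceil(total * rate + 6 * np.sqrt(total * rate) + 10))
    isi = rng.gamma(shape, scale=mean_isi / shape, size=(n_trials, n_isi))
    t = np.cumsum(isi, axis=1) - burn
    # random stationary start: shift by a uniform fraction of one ISI
    t = t - rng.uniform(0, mean_isi, size=(n_trials, 1))
    return [row[(row >= 0) & (row < duration)] for row in t]


def gen_session(spec: SessionGenSpec) -> SpikeSession:
    """Generate a synthetic spike session per ``spec``.

    The per-trial population drive A_pre is the mean across units of each
    unit's z-scored pre-CS spike count (z-scored against that unit's own
    across-trial distribution), mirroring how the analysis pipeline
    normalizes population activity. Each unit's CS transient on a trial adds
    Poisson spikes at rate amplitude * (1 + noise_cv * eps) / (1 + g * A_pre)
    for ``transient_duration`` seconds; the divisor is floored at 0.1.
    """
    rng = rng_from(spec.seed)
    rates = rng.uniform(*spec.baseline_rate_range, size=spec.n_units)
    baseline = {
        u: _gamma_renewal_trains(rates[u], spec.gamma_shape,
                                 spec.trial_duration, spec.n_trials, rng)
        for u in range(spec.n_units)
    }
    # population pre-CS activation per trial
    pre0 = spec.cs_time - spec.pre_window
    counts = np.array([
        [np.count_nonzero((s >= pre0) & (s < spec.cs_time))
         for s in baseline[u]]
        for u in range(spec.n_units)
    ], dtype=float)
    mu = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    z = np.divide(counts - mu, sd, out=np.zeros_like(counts), where=sd > 0)
    a_pre = z.mean(axis=0)  # per trial

    divisor = np.maximum(1.0 + spec.feedback_gain * a_pre, 0.1)
    spikes = {}
    for u in range(spec.n_units):
        trials = []
        for j in range(spec.n_trials):
            amp = spec.transient_amplitude * max(
                0.0, 1.0 + spec.noise_cv * rng.standard_normal())
            rate_add = amp / divisor[j]
            n_add = rng.poisson(rate_add * spec.transient_duration)
            add = rng.uniform(spec.cs_time,
                              spec.cs_time + spec.transient_duration,
                              size=n_add)
            trials.append(np.sort(np.concatenate([baseline[u][j], add])))
        spikes[u] = trials
    return SpikeSession(
        spikes=spikes, cs_time=spec.cs_time,
        trial_duration=spec.trial_duration,
        meta={"generator": asdict(spec), "unit_rates": rates.tolist(),
              "a_pre": a_pre.tolist()},
    )


# ---------------------------------------------------------------------------
# IPSC traces
# ---------------------------------------------------------------------------

# printed kinetics of the two inhibitory input classes (ms)
FEEDBACK_KINETICS = {"latency": 1.93, "rise_tau": 0.53, "decay_tau": 5.64}
FEEDFORWARD_KINETICS = {"latency": 2.51, "rise_tau": 0.75, "decay_tau": 9.00}


def gen_ipsc_trace(latency: float = 1.93, rise_tau: float = 0.53,
                   decay_tau: float = 5.64, amplitude: float = 100.0,
                   n_stimuli: int = 5, stim_rate: float = 10.0,
                   noise_sd: float = 0.0, dt: float = 0.05,
                   seed=None, v_hold: float = 20.0,
                   pre_time: float = 20.0) -> Trace:
    """Voltage-clamp trace with dual-exponential IPSCs after each stimulus.

    Times in ms, amplitude in pA (outward positive, the convention when
    holding above E_Cl). The returned trace's ``meta`` carries the ground
    truth, including the kernel's true 20-80% rise time, for round-trip
    tests. White Gaussian noise of SD ``noise_sd`` is added throughout.
    """
    if not (decay_tau > rise_tau > 0):
        raise InvalidSpecError("need decay_tau > rise_tau > 0")
    if dt > rise_tau / 5:
        raise ResolutionError(
            f"dt={dt} ms too coarse to resolve rise_tau={rise_tau} ms")
    if n_stimuli < 1 or stim_rate <= 0:
        raise InvalidSpecError("need n_stimuli >= 1 and stim_rate > 0")
    isi = 1e3 / stim_rate
    stim_times = pre_time + np.arange(n_stimuli) * isi
    dur = stim_times[-1] + latency + 12 * decay_tau
    n = int(round(dur / dt))
    data = np.zeros(n)
    kern = amplitude * dual_exp_kernel(rise_tau, decay_tau, dt)
    for st in stim_times:
        i0 = int(round((st + latency) / dt))
        seg = min(kern.size, n - i0)
        if seg > 0:
            data[i0:i0 + seg] += kern[:seg]
    if noise_sd > 0:
        data = data + rng_from(seed).normal(0, noise_sd, size=n)
    return Trace(
        data, dt, units="pA", v_hold=v_hold, stim_times=stim_times,
        meta={"latency": latency, "rise_tau": rise_tau,
              "decay_tau": decay_tau, "amplitude": amplitude,
              "rise_20_80": _true_rise_20_80(rise_tau, decay_tau)},
    )


def _true_rise_20_80(rise_tau: float, decay_tau: float) -> float:
    """20-80% rise time of the noiseless kernel, by fine-grid interpolation."""
    ddt = rise_tau / 200.0
    k = dual_exp_kernel(rise_tau, decay_tau, ddt)
    ip = int(np.argmax(k))
    up = k[: ip + 1]
    t20 = np.interp(0.2, up, np.arange(up.size) * ddt)
    t80 = np.interp(0.8, up, np.arange(up.size) * ddt)
    return t80 - t20


# ---------------------------------------------------------------------------
# circuit-mapping datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridGenSpec:
    """Photostimulation grid + Gaussian-footprint response generator spec.

    The grid covers the anatomical frame (1670 x 1000 um); ``rotation``
    (degrees) and ``aspect`` (width/height ratio of the generated grid)
    distort it away from the reference frame so the alignment step has real
    work to do. Supported shapes are the two used experimentally.
    """

    grid_shape: tuple = (9, 9)
    field_center: tuple = (800.0, 500.0)  # um, in the reference frame
    field_sigma: float = 150.0            # um
    peak_amplitude: float = 100.0         # pA
    noise_sd: float = 0.0                 # pA
    rotation: float = 0.0                 # degrees
    aspect: float = 1.67                  # width/height of generated grid
    seed: int = 0

    def __post_init__(self):
        if tuple(self.grid_shape) not in ((9, 9), (10, 14)):
            raise InvalidSpecError("grid_shape must be 9x9 or 10x14")
        if self.field_sigma <= 0:
            raise InvalidSpecError("field_sigma must be positive")
        if self.aspect <= 0:
            raise InvalidSpecError("aspect must be positive")


def _reference_sites(shape: tuple) -> np.ndarray:
    rows, cols = shape
    xs = np.linspace(0.0, SN_WIDTH, cols)
    ys = np.linspace(0.0, SN_HEIGHT, rows)
    xx, yy = np.meshgrid(xs, ys)  # row-major, (0,0) at dorso-medial corner
    return np.column_stack([xx.ravel(), yy.ravel()])


def gen_stim_grid(spec: GridGenSpec) -> StimGrid:
    """Grid of stimulation sites, distorted by ``aspect`` and ``rotation``."""
    sites = _reference_sites(spec.grid_shape)
    # aspect distortion about the grid centroid
    c = sites.mean(axis=0)
    sites = sites - c
    sites[:, 0] *= spec.aspect / (SN_WIDTH / SN_HEIGHT)
    th = np.deg2rad(spec.rotation)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    sites = sites @ rot.T + c
    rows, cols = spec.grid_shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    return StimGrid(
        sites=sites, shape=tuple(spec.grid_shape),
        dorsal_edge=idx[0, :].tolist(), medial_edge=idx[:, 0].tolist(),
        plane="coronal",
    )


def gen_cracm_dataset(spec: GridGenSpec, n_cells: int = 1,
                      soma_positions=None, field_centers=None,
                      seed=None, latency_base: float = 1.93,
                      velocity: float = 2.0, latency_jitter: float = 0.0):
    """Stimulation grid plus one Gaussian-footprint response map per cell.

    Response at each site: peak * exp(-d^2 / (2 sigma^2)) + noise, with d the
    distance from the site to the cell's field center *in the reference
    frame* (site positions are mapped back through the grid distortion), so
    generated amplitudes are geometrically consistent after alignment.
    Latencies grow with distance at 1/velocity (ms per mm = 1 / (m/s)),
    emulating action-potential propagation from the stimulation site.

    field_centers default to the soma positions; pass explicit centers to
    emulate input fields that are displaced from the recorded soma. Returns
    ``(grid, [ResponseMap, ...])``; amplitudes are rectified at zero.
    """
    rng = rng_from(spec.seed if seed is None else seed)
    grid = gen_stim_grid(spec)
    ref_sites = _reference_sites(spec.grid_shape)
    if soma_positions is None:
        soma_positions = np.column_stack([
            rng.uniform(0.2 * SN_WIDTH, 0.8 * SN_WIDTH, n_cells),
            rng.uniform(0.2 * SN_HEIGHT, 0.8 * SN_HEIGHT, n_cells)])
    soma_positions = np.atleast_2d(np.asarray(soma_positions, dtype=float))
    if soma_positions.shape[0] != n_cells:
        raise InvalidSpecError("need one soma position per cell")
    lo = ref_sites.min(axis=0) - 1e-9
    hi = ref_sites.max(axis=0) + 1e-9
    if np.any(soma_positions < lo) or np.any(soma_positions > hi):
        raise InvalidSpecError("soma positions outside the grid bounding box")
    if field_centers is None:
        centers = soma_positions
    else:
        centers = np.atleast_2d(np.asarray(field_centers, dtype=float))
    maps = []
    for i in range(n_cells):
        d = np.linalg.norm(ref_sites - centers[i], axis=1)
        amp = spec.peak_amplitude * np.exp(-d**2 / (2 * spec.field_sigma**2))
        if spec.noise_sd > 0:
            amp = amp + rng.normal(0, spec.noise_sd, size=amp.size)
        lat = latency_base + (d / 1e3) / velocity
        if latency_jitter > 0:
            lat = lat + rng.normal(0, latency_jitter, size=lat.size)
        maps.append(ResponseMap(
            amplitudes=np.clip(amp, 0.0, None), latencies=lat,
            soma=soma_positions[i].copy(), v_hold=20.0,
            meta={"field_center": centers[i].tolist(),
                  "field_sigma": spec.field_sigma},
        ))
    return grid, maps
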