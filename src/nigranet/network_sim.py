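"""Microcircuit simulation of the SNr collateral network.

A population of EIF pacemaker neurons (see :mod:`nigranet.neuron_model`) is
embedded in the 1670 x 1000 um anatomical frame. Every ordered pair is
connected with probability p * f(d) (f an isotropic spatial kernel,
Gaussian with a 600 um length scale by default), giving each neuron on the
order of 50-100 presynaptic collateral inputs. Collateral synapses are
GABAergic (E = -70 mV), weak (~0.15 nS unitary), fast (rise 0.53 ms /
decay 5.64 ms), conducted with a 1.93 ms synaptic latency plus axonal
propagation at 2 m/s, and depress with resource-depletion dynamics
calibrated so the paired-pulse ratio at 100 ms is 0.91.

Photostimulation injects a square current pulse into the
channelrhodopsin-expressing fraction of the population; the "gabazine"
flag zeroes all collateral conductances while keeping connectivity,
reproducing the pharmacological reference condition. The gain experiment
sweeps stimulus durations under both conditions and summarizes per-neuron
normalized responses — the divisive-gain signature is a control/gabazine
response ratio that falls with stimulus duration while unstimulated rates
are unchanged.

The default population is 1000 neurons, a desk-scale stand-in for the
~30,000-neuron nucleus, with connection probability scaled to preserve the
biological in-degree.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import rng_from, child_seeds
from .errors import InsufficientDataError, InvalidSpecError
from .cracm_maps import SN_WIDTH, SN_HEIGHT
from .neuron_model import (
    NeuronParams,
    SynapseKernelSpec,
    calibrate_drive,
    firing_rate,
    kernel_peak_time,
)

COLLATERAL_KERNEL = SynapseKernelSpec(rise_tau=0.53, decay_tau=5.64,
                                      reversal=-70.0, unitary_g=0.15)


# ---------------------------------------------------------------------------
# short-term depression (resource depletion)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepressionParams:
    """Resource-depletion synapse: on a spike a fraction U of the available
    resource R is released and removed; R recovers toward 1 with time
    constant tau_rec (ms). The conductance of an event scales with R at the
    moment of release (so a synapse at rest produces the full unitary
    conductance)."""

    u: float = 0.14835          # release fraction; solves PPR(100 ms) = 0.91
    tau_rec: float = 200.0      # ms

    def __post_init__(self):
        if not (0 < self.u <= 1):
            raise InvalidSpecError("need 0 < U <= 1")
        if self.tau_rec <= 0:
            raise InvalidSpecError("tau_rec must be positive")


def depressing_synapse_step(r: float, spike: bool, dt: float,
                            params: DepressionParams):
    """One time step of the depletion dynamics.

    Returns (new resource, released fraction); the released fraction is
    U * R on a spike step, else 0. Recovery is applied before release.
    """
    r = 1.0 - (1.0 - r) * np.exp(-dt / params.tau_rec)
    released = 0.0
    if spike:
        released = params.u * r
        r -= released
    return r, released


def ppr_from_params(params: DepressionParams, interval: float) -> float:
    """Closed-form paired-pulse ratio at ``interval`` ms from rest:
    PPR = R2/R1 = 1 - U exp(-interval/tau_rec)."""
    return 1.0 - params.u * np.exp(-interval / params.tau_rec)


def calibrate_depression(ppr_target: float = 0.91, interval: float = 100.0,
                         tau_rec: float = 200.0) -> DepressionParams:
    """Solve for the release fraction giving ``ppr_target`` at ``interval``
    ms (1-D closed form: U = (1 - PPR) exp(interval/tau_rec))."""
    u = (1.0 - ppr_target) * np.exp(interval / tau_rec)
    if not (0 < u <= 1):
        raise InvalidSpecError(
            f"PPR target {ppr_target} unreachable with tau_rec={tau_rec}")
    return DepressionParams(u=u, tau_rec=tau_rec)


def steady_state_release(params: DepressionParams, rate: float) -> float:
    """Fixed point of the depletion recursion under regular firing at
    ``rate`` Hz: the steady-state resource just before each spike,
    R* = (1 - e) / (1 - (1 - U) e) with e = exp(-1/(rate tau_rec) * 1e3).
    The steady-state/first-pulse amplitude ratio equals R*."""
    if rate <= 0:
        return 1.0
    e = np.exp(-1e3 / (rate * params.tau_rec))
    return float((1.0 - e) / (1.0 - (1.0 - params.u) * e))


# ---------------------------------------------------------------------------
# network configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotostimSpec:
    """Square-pulse photostimulation of the expressing fraction."""

    duration: float = 8.0          # ms
    amplitude: float = 250.0       # pA, mean steady-state photocurrent
    amplitude_cv: float = 0.5      # lognormal cell-to-cell expression spread
    transient_ratio: float = 1.5   # ChR2 peak/steady current ratio at onset
    desensitization_tau: float = 8.0  # ms, decay of the onset transient
    expressing_fraction: float = 1.0
    onset: float = 500.0           # ms from trial start
    center: tuple | None = None    # um; None = spatially uniform
    sigma: float = 400.0           # um, Gaussian profile when center is set

    def __post_init__(self):
        if not (0.0 <= self.expressing_fraction <= 1.0):
            raise InvalidSpecError("expressing fraction must be in [0, 1]")
        if self.duration < 0:
            raise InvalidSpecError("duration must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the collateral microcircuit simulation."""

    n_neurons: int = 1000
    p_connect: float | None = None      # None: scaled to target_in_degree
    target_in_degree: float = 67.0
    kernel_scale: float = 600.0         # um; spatial kernel length scale
    kernel_shape: str = "gaussian"      # or "flat" (ablation)
    synapse: SynapseKernelSpec = COLLATERAL_KERNEL
    latency: float = 1.93               # ms synaptic latency
    velocity: float = 2.0               # m/s axonal conduction
    depression: DepressionParams = DepressionParams()
    baseline_rate_range: tuple = (10.0, 40.0)
    neuron: NeuronParams = NeuronParams()
    photostim: PhotostimSpec = PhotostimSpec()
    gabazine: bool = False
    dt: float = 0.05                    # ms
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise InvalidSpecError("need at least one neuron")
        if self.p_connect is not None and not (0 <= self.p_connect <= 1):
            raise InvalidSpecError("p_connect must be in [0, 1]")
        if self.kernel_scale <= 0:
            raise InvalidSpecError("kernel length scale must be positive")
        if self.kernel_shape not in ("gaussian", "flat"):
            raise InvalidSpecError("kernel_shape must be gaussian or flat")


@dataclass
class SimResult:
    """Spike times per neuron (seconds) plus stimulus metadata."""

    spikes: list
    duration: float
    config: NetworkConfig
    photostim: PhotostimSpec
    rates: np.ndarray          # target tonic rate per neuron, Hz
    positions: np.ndarray      # um
    voltages: dict = None      # tagged neuron -> Trace (mV)
    g_inh: dict = None         # tagged neuron -> Trace (nS)


@dataclass
class Connectivity:
    targets: list              # per source: int array of postsynaptic indices
    delay_steps: list          # per source: int array, in units of dt
    positions: np.ndarray
    in_degree: np.ndarray


def _spatial_kernel(d: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    if cfg.kernel_shape == "flat":
        return np.ones_like(d)
    return np.exp(-d**2 / (2.0 * cfg.kernel_scale**2))


def neuron_positions(cfg: NetworkConfig) -> np.ndarray:
    rng = rng_from(np.random.SeedSequence([cfg.seed, 11]))
    return np.column_stack([rng.uniform(0, SN_WIDTH, cfg.n_neurons),
                            rng.uniform(0, SN_HEIGHT, cfg.n_neurons)])


def build_connectivity(cfg: NetworkConfig,
                       positions: np.ndarray | None = None) -> Connectivity:
    """Sample the Bernoulli(p * f(d)) adjacency with per-edge delays.

    With ``p_connect=None`` the probability scale is set so the expected
    mean in-degree equals ``target_in_degree`` given the sampled positions.
    Per-edge delay = synaptic latency + distance / conduction velocity
    (2 m/s = 2 um/ms * 1e3, i.e. 0.5 ms per mm).
    """
    pos = neuron_positions(cfg) if positions is None else positions
    n = cfg.n_neurons
    rng = rng_from(np.random.SeedSequence([cfg.seed, 13]))
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    f = _spatial_kernel(d, cfg)
    np.fill_diagonal(f, 0.0)
    if cfg.p_connect is None:
        if n < 2:
            p = 0.0
        else:
            p = cfg.target_in_degree * n / f.sum()
    else:
        p = cfg.p_connect
    prob = np.clip(p * f, 0.0, 1.0)
    adj = rng.random((n, n)) < prob          # adj[j, i]: j -> i
    delays = cfg.latency + d / (cfg.velocity * 1e3)
    targets, steps = [], []
    for j in range(n):
        t = np.nonzero(adj[j])[0]
        targets.append(t)
        steps.append(np.round(delays[j, t] / cfg.dt).astype(np.int64))
    in_degree = adj.sum(axis=0)
    return Connectivity(targets=targets, delay_steps=steps, positions=pos,
                        in_degree=in_degree)


# drive-calibration curve, cached per NeuronParams
_CALIB_CACHE: dict = {}


def _drive_for_rates(params: NeuronParams, rates: np.ndarray) -> np.ndarray:
    key = params
    if key not in _CALIB_CACHE:
        lo = calibrate_drive(params, 5.0).drive
        hi = calibrate_drive(params, 60.0).drive
        grid = np.linspace(lo, hi, 25)
        f = np.array([firing_rate(replace(params, drive=g), duration=4.0)
                      for g in grid])
        _CALIB_CACHE[key] = (f, grid)
    f, grid = _CALIB_CACHE[key]
    return np.interp(rates, f, grid)


def run_network(cfg: NetworkConfig, duration: float,
                conn: Connectivity | None = None,
                trial_seed: int = 0, record=()) -> SimResult:
    """Simulate the microcircuit for ``duration`` seconds.

    Event-driven delivery of delayed, depression-scaled unitary
    conductances onto vectorized EIF pacemakers. ``trial_seed`` controls
    only the initial membrane-potential phases, so different conditions run
    with identical network realizations and initial states. Gabazine zeroes
    collateral conductances but leaves everything else untouched.
    """
    ps = cfg.photostim
    if duration * 1e3 < ps.onset + ps.duration + 500.0:
        raise InvalidSpecError(
            "duration must cover the stimulus window plus a 500 ms tail")
    if conn is None:
        conn = build_connectivity(cfg)
    n = cfg.n_neurons
    dt = cfg.dt
    n_steps = int(round(duration * 1e3 / dt))
    pos = conn.positions

    rng_cfg = rng_from(np.random.SeedSequence([cfg.seed, 17]))
    rates = rng_cfg.uniform(*cfg.baseline_rate_range, n)
    drives = _drive_for_rates(cfg.neuron, rates)

    rng_trial = rng_from(np.random.SeedSequence([cfg.seed, 19, trial_seed]))
    p0 = cfg.neuron
    v = rng_trial.uniform(p0.reset, p0.threshold, n)

    # photostim current per neuron
    expr = np.zeros(n)
    k_expr = int(round(ps.expressing_fraction * n))
    chosen = rng_cfg.permutation(n)[:k_expr]
    expr[chosen] = 1.0
    if ps.center is not None:
        w = np.exp(-((pos - np.asarray(ps.center)) ** 2).sum(1)
                   / (2 * ps.sigma ** 2))
        expr *= w
    if ps.amplitude_cv > 0:
        # lognormal cell-to-cell photocurrent spread (expression
        # heterogeneity); mean preserved
        s2 = np.log(1.0 + ps.amplitude_cv ** 2)
        expr = expr * rng_cfg.lognormal(-0.5 * s2, np.sqrt(s2), n)
    i_stim_amp = ps.amplitude * expr
    stim_a = int(round(ps.onset / dt))
    stim_b = int(round((ps.onset + ps.duration) / dt))

    # synaptic filter states (difference-of-exponentials, unit peak)
    syn = cfg.synapse
    a_d = np.exp(-dt / syn.decay_tau)
    a_r = np.exp(-dt / syn.rise_tau)
    tp = kernel_peak_time(syn.rise_tau, syn.decay_tau)
    peak_un = np.exp(-tp / syn.decay_tau) - np.exp(-tp / syn.rise_tau)
    w_scale = 0.0 if cfg.gabazine else syn.unitary_g / peak_un
    xd = np.zeros(n)
    xr = np.zeros(n)

    max_delay = 1
    for s in conn.delay_steps:
        if s.size:
            max_delay = max(max_delay, int(s.max()))
    lbuf = max_delay + 1
    buf = np.zeros((lbuf, n))

    # depression state per presynaptic neuron
    dep = cfg.depression
    r_dep = np.ones(n)
    rec = np.exp(-dt / dep.tau_rec)

    gl, el = p0.g_leak, p0.e_leak
    dT, vT = p0.sharpness, p0.threshold
    vcut, vreset = p0.v_cut, p0.reset
    einh = syn.reversal
    c_m = p0.capacitance
    refr_steps = int(round(p0.refractory / dt))
    refr = np.zeros(n, dtype=np.int64)

    record = list(record)
    v_rec = {i: np.empty(n_steps) for i in record}
    g_rec = {i: np.empty(n_steps) for i in record}

    spikes = [[] for _ in range(n)]
    for t in range(n_steps):
        row = t % lbuf
        inc = buf[row]
        xd += inc
        xr += inc
        inc[:] = 0.0
        xd *= a_d
        xr *= a_r
        gi = xd - xr

        i_ext = drives
        if stim_a <= t < stim_b:
            # ChR2-like photocurrent: desensitizing onset transient that
            # synchronizes first spikes, then a weaker steady-state current
            tr = 1.0 + (ps.transient_ratio - 1.0) * np.exp(
                -(t - stim_a) * dt / ps.desensitization_tau)
            i_ext = drives + i_stim_amp * tr

        x = np.clip((v - vT) / dT, None, 40.0)
        iexp = gl * dT * np.exp(x)
        inap = p0.nap_max / (1.0 + np.exp((p0.nap_vhalf - v) / p0.nap_k))
        b = gl + gi
        a = gl * el + gi * einh + i_ext + iexp + inap
        vinf = a / b
        v = vinf + (v - vinf) * np.exp(-b * (dt / c_m))

        in_refr = refr > 0
        v[in_refr] = vreset
        refr[in_refr] -= 1

        fired = (v >= vcut) & ~in_refr
        r_dep = 1.0 - (1.0 - r_dep) * rec
        if np.any(fired):
            idx = np.nonzero(fired)[0]
            v[idx] = vreset
            refr[idx] = refr_steps
            for j in idx:
                spikes[j].append(t * dt)
                if w_scale != 0.0 and conn.targets[j].size:
                    w = w_scale * r_dep[j]
                    rows = (t + conn.delay_steps[j]) % lbuf
                    np.add.at(buf, (rows, conn.targets[j]), w)
                r_dep[j] *= 1.0 - dep.u

        for i in record:
            v_rec[i][t] = v[i]
            g_rec[i][t] = gi[i]

    from .io import Trace
    spike_arrays = [np.asarray(s) * 1e-3 for s in spikes]
    return SimResult(
        spikes=spike_arrays, duration=duration, config=cfg, photostim=ps,
        rates=rates, positions=pos,
        voltages={i: Trace(v_rec[i], dt, units="mV") for i in record},
        g_inh={i: Trace(g_rec[i], dt, units="nS") for i in record})


# ---------------------------------------------------------------------------
# the gain experiment
# ---------------------------------------------------------------------------

RESPONSE_WINDOW = 50.0  # ms after stimulus onset


def run_gain_trials(cfg: NetworkConfig, durations=(0, 4, 8, 12, 20),
                    n_trials: int = 10, seed: int = 0,
                    trial_duration: float = 1.2) -> dict:
    """Run the full duration x condition x trial grid.

    Returns {(condition, duration): [SimResult, ...]} with identical trial
    seeds across conditions so control and gabazine runs are paired.
    """
    if 0 not in durations:
        raise InvalidSpecError("durations must include 0")
    conn = build_connectivity(cfg)
    out = {}
    seeds = child_seeds(seed, n_trials)
    for gbz in (False, True):
        cond = "gabazine" if gbz else "control"
        for d in durations:
            c = replace(cfg, gabazine=gbz,
                        photostim=replace(cfg.photostim, duration=float(d)))
            out[(cond, d)] = [
                run_network(c, trial_duration, conn=conn, trial_seed=s)
                for s in seeds]
    return out


def gain_experiment(cfg: NetworkConfig, durations=(0, 4, 8, 12, 20),
                    n_trials: int = 10, seed: int = 0,
                    response_window: float = RESPONSE_WINDOW,
                    min_reference: float = 1.0,
                    trials: dict | None = None):
    """Normalized response vs stimulus duration, control vs gabazine.

    The per-neuron response on a trial is the spike count in the
    ``response_window`` ms after stimulus onset minus the count expected
    from the same trial's pre-onset rate. Responses are normalized per
    neuron by that neuron's mean gabazine (inhibition-blocked) response at
    the longest duration; only responsive neurons — reference response of
    at least ``min_reference`` evoked spikes — enter the population
    summary, mirroring the experimental restriction to cells with reliable
    light-evoked spiking. Returns (per-trial DataFrame, population summary
    DataFrame with mean normalized response per duration x condition).
    """
    if trials is None:
        trials = run_gain_trials(cfg, durations, n_trials, seed)
    t_on = cfg.photostim.onset * 1e-3
    w = response_window * 1e-3
    rows = []
    for (cond, d), results in trials.items():
        for k, res in enumerate(results):
            for i, s in enumerate(res.spikes):
                evoked = np.count_nonzero((s >= t_on) & (s < t_on + w))
                if d == 0:
                    # zero-stimulus response = the background firing rate
                    # estimate itself (not baseline-subtracted, which would
                    # compare noise against noise)
                    resp = evoked
                else:
                    base = np.count_nonzero(s < t_on) / t_on
                    resp = evoked - base * w
                rows.append((cond, d, k, i, resp))
    df = pd.DataFrame(rows, columns=["condition", "duration", "trial",
                                     "neuron", "response"])
    dmax = max(d for (_, d) in trials)
    ref = (df[(df.condition == "gabazine") & (df.duration == dmax)]
           .groupby("neuron")["response"].mean())
    responsive = ref[ref >= min_reference].index
    df = df[df.neuron.isin(responsive)].copy()
    df["normalized"] = df["response"] / df["neuron"].map(ref)
    summary = (df.groupby(["condition", "duration"])["normalized"]
               .mean().reset_index())
    return df, summary


def paired_inhibition_experiment(n_slices: int = 6, n_neurons: int = 200,
                                 durations=(8.0, 20.0), n_trials: int = 10,
                                 seed: int = 0, coupling_scale_sd: float = 0.8,
                                 pairs_per_slice: int = 20,
                                 base_config: NetworkConfig | None = None):
    """Percent-inhibition correlation in pairs across a slice ensemble.

    Each "slice" is an independent network realization whose collateral
    coupling strength is scaled by a lognormal factor (SD
    ``coupling_scale_sd`` in log space), emulating slice-to-slice
    variability in collateral preservation and opsin expression — the
    dominant source of the shared suppression variability seen in
    simultaneously recorded pairs. Within each slice, pairs of responsive
    neurons are scored under control and inhibition-blocked conditions at
    each stimulus duration; returns (x, y, pooled Pearson r).
    """
    rng = rng_from(seed)
    xs, ys = [], []
    for k in range(n_slices):
        scale = float(rng.lognormal(0.0, coupling_scale_sd))
        base = base_config or NetworkConfig()
        syn = replace(base.synapse,
                      unitary_g=base.synapse.unitary_g * scale)
        cfg = replace(base, n_neurons=n_neurons, synapse=syn,
                      seed=seed * 100 + k)
        conn = build_connectivity(cfg)
        seeds = child_seeds(seed * 7919 + k, n_trials)
        trials = {}
        for gbz in (False, True):
            cond = "gabazine" if gbz else "control"
            for d in durations:
                c = replace(cfg, gabazine=gbz,
                            photostim=replace(cfg.photostim,
                                              duration=float(d)))
                trials[(cond, d)] = [
                    run_network(c, 1.2, conn=conn, trial_seed=s)
                    for s in seeds]
        t_on = cfg.photostim.onset * 1e-3
        w = RESPONSE_WINDOW * 1e-3
        dmax = max(durations)
        resp = []
        for i in range(n_neurons):
            g = np.mean([
                np.count_nonzero((s >= t_on) & (s < t_on + w))
                - s[s < t_on].size / t_on * w
                for res in trials[("gabazine", dmax)]
                for s in [res.spikes[i]]])
            if g >= 1.0:
                resp.append(i)
        pairs = [(resp[2 * i], resp[2 * i + 1])
                 for i in range(min(len(resp) // 2, pairs_per_slice))]
        if len(pairs) < 3:
            continue
        x, y, _ = paired_inhibition_correlation(trials, pairs)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise InsufficientDataError("too few usable pair observations")
    return x, y, float(stats.pearsonr(x, y)[0])


def paired_inhibition_correlation(trials: dict, pairs,
                                  onset_s: float | None = None,
                                  response_window: float = RESPONSE_WINDOW):
    """Percent inhibition of neuron pairs across stimulus conditions.

    For each (i, j) pair and each non-zero stimulus duration, the percent
    inhibition of each neuron (control vs gabazine spike counts in the
    evoked window, pooled over trials) forms one (x, y) point; returns
    (x, y, Pearson r).
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InsufficientDataError("need >= 3 neuron pairs")
    durations = sorted({d for (_, d) in trials if d > 0})
    any_res = next(iter(trials.values()))[0]
    t_on = (any_res.photostim.onset * 1e-3 if onset_s is None else onset_s)
    w = response_window * 1e-3

    def counts(cond, d, neuron):
        return sum(
            np.count_nonzero((s >= t_on) & (s < t_on + w))
            for res in trials[(cond, d)] for s in [res.spikes[neuron]])

    xs, ys = [], []
    for d in durations:
        for (i, j) in pairs:
            gi, gj = counts("gabazine", d, i), counts("gabazine", d, j)
            if gi == 0 or gj == 0:
                continue
            ci, cj = counts("control", d, i), counts("control", d, j)
            xs.append(100.0 * (1 - ci / gi))
            ys.append(100.0 * (1 - cj / gj))
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if xs.size < 3 or xs.std() == 0 or ys.std() == 0:
        raise InsufficientDataError("too few usable pair observations")
    return xs, ys, float(stats.pearsonr(xs, ys)[0])
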