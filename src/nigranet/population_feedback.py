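"""Population-feedback analysis of in vivo spike sessions.

For every unit i and trial: RESP_single = unit i's firing rate in the
response window after CS onset, minus its own across-trial mean;
PRE_population = the mean over all other units of each unit's z-scored
pre-CS rate. A session's feedback score is the Pearson correlation between
PRE_population and RESP_single over all (unit, trial) pairs; significance
comes from a permutation test that shuffles each unit's responses across
trials (breaking the trial linkage while preserving both marginals).
Pooled pairs from many sessions are binned on PRE_population and fit with a
four-parameter logistic to expose the divisive saturation.

Sessions enter the pipeline only if they contain at least eight
simultaneously recorded units.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import rng_from
from .errors import (
    FitNotIdentifiableError,
    InsufficientDataError,
    InvalidSpecError,
    UndefinedCorrelationError,
)
from .io import SpikeSession

MIN_UNITS = 8           # session-inclusion rule
RESP_WINDOW = 0.2       # s after CS onset
PRE_WINDOW = 0.5        # s before CS onset (default; not fixed by the data)


def unit_response_metrics(session: SpikeSession, unit,
                          pre_window: float = PRE_WINDOW,
                          resp_window: float = RESP_WINDOW):
    """Per-trial (PRE_population, RESP_single) for one unit.

    RESP_single is the unit's response-window rate (Hz) minus its
    across-trial mean. PRE_population is the across-unit mean (excluding
    this unit) of each unit's z-scored pre-CS count.
    """
    units = session.unit_ids
    if unit not in session.spikes:
        raise InvalidSpecError(f"unit {unit!r} not in session")
    pre_z = _pre_zscores(session, pre_window)
    i = units.index(unit)
    others = np.delete(np.arange(len(units)), i)
    pre_pop = pre_z[others].mean(axis=0)
    cs = session.cs_time
    counts = np.array([
        np.count_nonzero((np.asarray(s) >= cs) & (np.asarray(s) < cs + resp_window))
        for s in session.spikes[unit]], dtype=float)
    resp = counts / resp_window
    resp -= resp.mean()
    return pre_pop, resp


def _pre_zscores(session: SpikeSession, pre_window: float) -> np.ndarray:
    cs = session.cs_time
    counts = session.counts_in_window(cs - pre_window, cs)
    mu = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    return np.divide(counts - mu, sd, out=np.zeros_like(counts),
                     where=sd > 0)


def session_pairs(session: SpikeSession, pre_window: float = PRE_WINDOW,
                  resp_window: float = RESP_WINDOW) -> pd.DataFrame:
    """All (unit, trial) pairs of a session as a tidy frame with columns
    ``unit``, ``trial``, ``pre_population``, ``resp_single``.

    Units with zero spikes in every trial are excluded with a warning.
    Sessions with fewer than MIN_UNITS units are rejected.
    """
    if session.n_units < MIN_UNITS:
        raise InvalidSpecError(
            f"session has {session.n_units} units; "
            f"inclusion requires >= {MIN_UNITS}")
    rows = []
    for u in session.unit_ids:
        if all(len(s) == 0 for s in session.spikes[u]):
            warnings.warn(f"unit {u!r} has no spikes in any trial; excluded")
            continue
        pre, resp = unit_response_metrics(session, u, pre_window, resp_window)
        for j, (a, b) in enumerate(zip(pre, resp)):
            rows.append((u, j, a, b))
    return pd.DataFrame(rows, columns=["unit", "trial", "pre_population",
                                       "resp_single"])


def session_correlation(pairs: pd.DataFrame) -> float:
    """Pearson r between PRE_population and RESP_single over all pairs."""
    if len(pairs) < 10:
        raise InsufficientDataError("need >= 10 (unit, trial) pairs")
    x = pairs["pre_population"].to_numpy()
    y = pairs["resp_single"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in one coordinate")
    return float(stats.pearsonr(x, y)[0])


def permutation_pvalue(pairs: pd.DataFrame, n_perm: int = 999,
                       seed: int = 0) -> float:
    """Two-sided permutation p for the session correlation.

    The null shuffles RESP_single across trials independently within each
    unit, preserving both marginals; p = (1 + #{|r_perm| >= |r_obs|}) /
    (1 + n_perm).
    """
    if n_perm < 999:
        raise InvalidSpecError("n_perm must be >= 999")
    r_obs = session_correlation(pairs)
    x = pairs["pre_population"].to_numpy()
    y = pairs["resp_single"].to_numpy().copy()
    units = pairs["unit"].to_numpy()
    rng = rng_from(seed)
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())
    n = y.size
    perm_y = np.empty((n_perm, n))
    for u in np.unique(units):
        sel = np.nonzero(units == u)[0]
        block = y[sel]
        keys = rng.random((n_perm, sel.size))
        order = np.argsort(keys, axis=1)
        perm_y[:, sel] = block[order]
    yc = perm_y - perm_y.mean(axis=1, keepdims=True)
    ys = np.sqrt((yc ** 2).sum(axis=1))
    r_perm = (yc @ xc) / (ys * xs)
    k = np.count_nonzero(np.abs(r_perm) >= abs(r_obs))
    return float((1 + k) / (1 + n_perm))


@dataclass
class SessionResult:
    n_units: int
    n_trials: int
    r: float
    p: float
    pairs: pd.DataFrame


def analyze_session(session: SpikeSession, n_perm: int = 999, seed: int = 0,
                    pre_window: float = PRE_WINDOW,
                    resp_window: float = RESP_WINDOW) -> SessionResult:
    """Full per-session pipeline: pairs, correlation, permutation p."""
    pairs = session_pairs(session, pre_window, resp_window)
    r = session_correlation(pairs)
    p = permutation_pvalue(pairs, n_perm=n_perm, seed=seed)
    return SessionResult(session.n_units, session.n_trials, r, p, pairs)


def pooled_correlation(sessions_pairs: list) -> dict:
    """Population-level feedback score computed two ways.

    ``pooled_r``: Pearson r over all pairs pooled across sessions.
    ``mean_session_r``: the unweighted mean of per-session correlations.
    The two differ when sessions differ in size or spread; both are
    reported and labelled.
    """
    pooled = pd.concat(sessions_pairs, ignore_index=True)
    rs = [session_correlation(p) for p in sessions_pairs]
    return {"pooled_r": session_correlation(pooled),
            "mean_session_r": float(np.mean(rs))}


def _logistic4(x, floor, ceiling, midpoint, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-(x - midpoint) / slope))


def pooled_sigmoid_fit(sessions_pairs: list, n_bins: int = 20,
                       min_per_bin: int = 5):
    """Bin pooled pairs on PRE_population and fit a 4-parameter logistic.

    Pairs from >= 2 sessions are pooled, PRE_population is split into
    ``n_bins`` equal-width bins, bins with more than ``min_per_bin`` samples
    are retained, and the retained bin means (of RESP_single) are fit by
    least squares with floor/ceiling/midpoint/slope parameters. Returns
    (bin_centers, bin_means, params dict).
    """
    if len(sessions_pairs) < 2:
        raise InsufficientDataError("need pooled pairs from >= 2 sessions")
    pooled = pd.concat(sessions_pairs, ignore_index=True)
    x = pooled["pre_population"].to_numpy()
    y = pooled["resp_single"].to_numpy()
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > min_per_bin:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(y[sel].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    if centers.size < 4:
        raise FitNotIdentifiableError(
            f"only {centers.size} bins retained; need >= 4")
    p0 = [means.min(), means.max(), float(np.median(centers)),
          max(np.ptp(centers) / 10, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(_logistic4, centers, means, p0=p0,
                                     maxfev=20000)
    except RuntimeError as e:
        raise FitNotIdentifiableError(f"logistic fit failed: {e}") from None
    params = dict(zip(["floor", "ceiling", "midpoint", "slope"], popt))
    return centers, means, params
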