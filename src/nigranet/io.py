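"""Shared data containers and file I/O.

Two containers travel between every module:

* :class:`Trace` — a uniformly sampled physical signal (membrane voltage in
  mV or clamp current in pA) with its sampling interval, optional holding
  potential, and the stimulus times needed to align event analyses.
* :class:`SpikeSession` — per-unit, per-trial spike times plus the
  conditioned-stimulus (CS) time, the substrate of the population-feedback
  pipeline.

Traces are stored in an HDF5 container (one group per trace, attributes
``dt_ms``, ``units``, ``v_hold_mV``, ``stim_times_ms``); sessions as a CSV
(``unit_id, trial_id, spike_time_s``) with a JSON sidecar carrying the trial
structure and an echo of the generator spec.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class Trace:
    """Uniformly sampled signal.

    Parameters
    ----------
    data : array of sample values in ``units`` (mV or pA).
    dt : sampling interval, ms.
    units : "mV" or "pA".
    v_hold : holding potential for voltage-clamp traces, mV (None otherwise).
    stim_times : stimulus onset times, ms from trace start.
    meta : free-form metadata (e.g. generator ground truth).
    """

    data: np.ndarray
    dt: float
    units: str = "mV"
    v_hold: float | None = None
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Trace duration in ms."""
        return self.n * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n) * self.dt


@dataclass
class SpikeSession:
    """Spike times (seconds, relative to trial start) keyed by (unit, trial).

    ``spikes[unit][trial]`` is a sorted float array. ``cs_time`` is the
    conditioned-stimulus onset within each trial.
    """

    spikes: dict
    cs_time: float
    trial_duration: float
    meta: dict = field(default_factory=dict)

    @property
    def unit_ids(self) -> list:
        return sorted(self.spikes)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def n_trials(self) -> int:
        return max(len(v) for v in self.spikes.values())

    def counts_in_window(self, t0: float, t1: float) -> np.ndarray:
        """Spike counts per (unit, trial) in [t0, t1); shape (n_units, n_trials)."""
        units = self.unit_ids
        out = np.zeros((len(units), self.n_trials))
        for i, u in enumerate(units):
            for j in range(self.n_trials):
                s = self.spikes[u][j]
                out[i, j] = np.count_nonzero((s >= t0) & (s < t1))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for u in self.unit_ids:
            for j, s in enumerate(self.spikes[u]):
                for t in s:
                    rows.append((u, j, t))
        return pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"])


def save_session(session: SpikeSession, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    session.to_dataframe().to_csv(csv_path, index=False)
    sidecar = sidecar_path or csv_path.with_suffix(".json")
    payload = {
        "cs_time_s": session.cs_time,
        "trial_duration_s": session.trial_duration,
        "n_units": session.n_units,
        "n_trials": session.n_trials,
        "meta": _jsonable(session.meta),
    }
    Path(sidecar).write_text(json.dumps(payload, indent=2))


def load_session(csv_path, sidecar_path=None) -> SpikeSession:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(Path(sidecar_path or csv_path.with_suffix(".json")).read_text())
    n_trials = int(sidecar["n_trials"])
    spikes = {}
    for u, g in df.groupby("unit_id"):
        trials = [np.sort(g.loc[g.trial_id == j, "spike_time_s"].to_numpy())
                  for j in range(n_trials)]
        spikes[u] = trials
    # units with zero spikes overall are absent from the CSV; that is allowed
    return SpikeSession(
        spikes=spikes,
        cs_time=float(sidecar["cs_time_s"]),
        trial_duration=float(sidecar["trial_duration_s"]),
        meta=sidecar.get("meta", {}),
    )


def save_traces(path, traces: dict) -> None:
    """Write a dict name -> Trace to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for name, tr in traces.items():
            g = f.create_group(name)
            g.create_dataset("data", data=tr.data)
            g.attrs["dt_ms"] = tr.dt
            g.attrs["units"] = tr.units
            g.attrs["v_hold_mV"] = np.nan if tr.v_hold is None else tr.v_hold
            g.attrs["stim_times_ms"] = tr.stim_times


def load_traces(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            vh = float(g.attrs["v_hold_mV"])
            out[name] = Trace(
                data=g["data"][...],
                dt=float(g.attrs["dt_ms"]),
                units=str(g.attrs["units"]),
                v_hold=None if np.isnan(vh) else vh,
                stim_times=np.asarray(g.attrs["stim_times_ms"], dtype=float),
            )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
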