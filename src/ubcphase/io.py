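"""Plain-text readers/writers for traces, spike trains and tuning tables."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .epsc_fitting import CurrentTrace
from .phase_metrics import TuningCurve

__all__ = [
    "write_trace", "read_trace", "write_spikes", "read_spikes",
    "write_tuning_csv", "read_tuning_csv", "write_json",
]


def write_trace(path, trace: CurrentTrace, stim_path=None) -> None:
    """Columnar text trace (time_ms, current_pA) + optional sidecar stim file."""
    df = pd.DataFrame({"time_ms": trace.times, "current_pA": trace.current})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if stim_path is not None:
        np.savetxt(stim_path, trace.stim_times, fmt="%.6g")


def read_trace(path, stim_path=None) -> CurrentTrace:
    df = pd.read_csv(path, sep="\t")
    stim = np.loadtxt(stim_path, ndmin=1) if stim_path else np.empty(0)
    return CurrentTrace(df["time_ms"].to_numpy(),
                        df["current_pA"].to_numpy(), stim)


def write_spikes(path, spike_times_ms) -> None:
    """One spike time (ms) per line."""
    np.savetxt(path, np.asarray(spike_times_ms, dtype=float), fmt="%.6g")


def read_spikes(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_tuning_csv(path, curves, cell_ids=None) -> None:
    """Tuning summary CSV: cell_id, rmin, rmax, phi_deg, k."""
    ids = cell_ids if cell_ids is not None else range(len(curves))
    pd.DataFrame({
        "cell_id": list(ids),
        "rmin": [c.rmin for c in curves],
        "rmax": [c.rmax for c in curves],
        "phi_deg": [c.phi for c in curves],
        "k": [c.k for c in curves],
    }).to_csv(path, index=False, float_format="%.6g")


def read_tuning_csv(path):
    df = pd.read_csv(path)
    return [TuningCurve(rmin=r.rmin, rmax=r.rmax, phi=r.phi_deg, k=r.k)
            for r in df.itertuples()]


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
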