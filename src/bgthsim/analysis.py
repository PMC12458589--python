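"""Spike statistics, regime comparison, phase trajectories, and result IO.

Regional voltage traces have no intrinsic spike definition, so one is
imposed: a spike is a local maximum above a threshold (default -30 mV)
separated from the previously accepted spike by at least a refractory
interval (default 2 ms).  All summary statistics — spike counts and
rates, mean spike-peak voltage, inter-spike-interval statistics — derive
from that definition, and healthy/Parkinsonian/DBS regimes are compared
by their counts at matched durations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .engine import SimResult
from .errors import ComparisonError, FixtureError, FormatError, ParameterError
from .regions import REGIONS

#: default regional spike definition (config-exposed)
DEFAULT_V_TH = -30.0
DEFAULT_MIN_ISI = 2.0


@dataclass
class SpikeSummary:
    """Spike statistics of one regional voltage trace.

    ISI fields are None when fewer than two spikes were detected; peak
    statistics are None when no spike was detected.
    """

    region: str
    n_spikes: int
    mean_peak_voltage: float | None = None
    peak_voltage_sd: float | None = None
    mean_isi: float | None = None
    isi_cv: float | None = None


@dataclass
class PhaseTrajectory:
    """Paired voltage samples of two regions over a common time window."""

    x_region: str
    y_region: str
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray


def detect_spikes_trace(v: np.ndarray, dt: float, V_th: float = DEFAULT_V_TH,
                        min_isi: float = DEFAULT_MIN_ISI):
    """Detect spikes on a regularly sampled voltage trace.

    A spike is a strict local maximum above ``V_th``; candidates are
    accepted left to right, skipping any maximum closer than ``min_isi``
    to the previously accepted spike.  Returns ``(times, peaks)`` where
    ``times`` are in ms relative to the first sample.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ParameterError("trace must have at least 2 samples")
    idx, _ = find_peaks(v, height=V_th)
    times, peaks = [], []
    last = -np.inf
    for i in idx:
        t = i * dt
        if t - last >= min_isi:
            times.append(t)
            peaks.append(v[i])
            last = t
    return np.asarray(times), np.asarray(peaks)


def summarize_trace(v: np.ndarray, dt: float, region: str = "",
                    V_th: float = DEFAULT_V_TH,
                    min_isi: float = DEFAULT_MIN_ISI) -> SpikeSummary:
    """Spike summary of an arbitrary trace (helper for summarize_region)."""
    times, peaks = detect_spikes_trace(v, dt, V_th=V_th, min_isi=min_isi)
    n = len(times)
    if n == 0:
        return SpikeSummary(region=region, n_spikes=0)
    mean_peak = float(np.mean(peaks))
    sd_peak = float(np.std(peaks)) if n > 1 else 0.0
    mean_isi = isi_cv = None
    if n >= 2:
        isi = np.diff(times)
        mean_isi = float(np.mean(isi))
        isi_cv = float(np.std(isi) / np.mean(isi)) if np.mean(isi) > 0 else None
    return SpikeSummary(region=region, n_spikes=n, mean_peak_voltage=mean_peak,
                        peak_voltage_sd=sd_peak, mean_isi=mean_isi, isi_cv=isi_cv)


def summarize_region(result: SimResult, region: str,
                     V_th: float = DEFAULT_V_TH,
                     min_isi: float = DEFAULT_MIN_ISI) -> SpikeSummary:
    """Spike summary of one region's recorded voltage trace."""
    v = result.region_trace(region)  # raises on unknown region
    dt_rec = float(result.time[1] - result.time[0])
    return summarize_trace(v, dt_rec, region=region, V_th=V_th, min_isi=min_isi)


def compare_regimes(results: dict, region: str,
                    V_th: float = DEFAULT_V_TH,
                    min_isi: float = DEFAULT_MIN_ISI) -> pd.DataFrame:
    """Spike-count table for one region across labelled runs.

    ``results`` maps label -> SimResult; all runs must share the same
    duration.  Returns a DataFrame with columns (label, n_spikes,
    rate_per_s) preserving the input order.
    """
    if len(results) < 2:
        raise ComparisonError("need at least two results to compare")
    durations = {label: float(r.time[-1]) for label, r in results.items()}
    if len(set(durations.values())) > 1:
        raise ComparisonError(f"mismatched durations: {durations}")
    duration_ms = next(iter(durations.values()))
    rows = []
    for label, r in results.items():
        s = summarize_region(r, region, V_th=V_th, min_isi=min_isi)
        rows.append((label, s.n_spikes, s.n_spikes / duration_ms * 1000.0))
    return pd.DataFrame(rows, columns=["label", "n_spikes", "rate_per_s"])


def phase_trajectory(result: SimResult, x_region: str, y_region: str,
                     window: tuple = None) -> PhaseTrajectory:
    """Voltage-vs-voltage trajectory of two regions over a time window.

    ``window = (t0, t1)`` in ms; defaults to the full recording.  The
    samples are paired and time ordered.
    """
    x = result.region_trace(x_region)
    y = result.region_trace(y_region)
    t = result.time
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    if t0 > t1 or t0 < t[0] or t1 > t[-1]:
        raise ParameterError(
            f"window {window} outside recorded range ({t[0]}, {t[-1]})"
        )
    if t0 == t1:  # zero-length window selects nothing
        mask = np.zeros_like(t, dtype=bool)
    else:
        mask = (t >= t0) & (t <= t1)
    return PhaseTrajectory(x_region=x_region, y_region=y_region,
                           time=t[mask], x=x[mask], y=y[mask])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRACE_FILE = "voltages.csv"
_RASTER_FILE = "rasters.csv"
_CURRENT_FILE = "avg_currents.csv"
_META_FILE = "meta.json"
_TRACE_COLS = ("time_ms", "v_stn", "v_gpi", "v_gpe", "v_th")


def write_result(result: SimResult, out_dir) -> Path:
    """Write a result directory: voltage/current traces and rasters as
    CSV, metadata as JSON.  Round-trips losslessly at stored precision."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = pd.DataFrame(
        {col: arr for col, arr in zip(_TRACE_COLS,
                                      [result.time, *result.v_regions])}
    )
    traces.to_csv(out / _TRACE_FILE, index=False, float_format="%.6f")
    raster_rows = []
    for region in REGIONS:
        arr = result.spikes.get(region)
        if arr is not None and len(arr):
            for nid, t in arr:
                raster_rows.append((region, int(nid), t))
    pd.DataFrame(raster_rows, columns=["region", "neuron_id", "time_ms"]).to_csv(
        out / _RASTER_FILE, index=False, float_format="%.6f"
    )
    cur = {"time_ms": result.time}
    for region in REGIONS:
        key = region.lower()
        cur[f"i_e_{key}"] = result.avg_currents[region][0]
        cur[f"i_i_{key}"] = result.avg_currents[region][1]
    pd.DataFrame(cur).to_csv(out / _CURRENT_FILE, index=False, float_format="%.6f")
    (out / _META_FILE).write_text(json.dumps(result.meta, indent=2, default=str))
    return out


def read_result(in_dir) -> SimResult:
    """Read a result directory written by :func:`write_result`."""
    src = Path(in_dir)
    for fname in (_TRACE_FILE, _RASTER_FILE, _CURRENT_FILE, _META_FILE):
        if not (src / fname).exists():
            raise FormatError(f"missing result file {fname!r} in {src}")
    traces = pd.read_csv(src / _TRACE_FILE)
    for col in _TRACE_COLS:
        if col not in traces.columns:
            raise FormatError(f"voltage trace missing column {col!r}")
    time = traces["time_ms"].to_numpy()
    v = np.vstack([traces[c].to_numpy() for c in _TRACE_COLS[1:]])
    rasters = pd.read_csv(src / _RASTER_FILE)
    spikes = {region: np.empty((0, 2)) for region in REGIONS}
    for region, grp in rasters.groupby("region"):
        spikes[str(region)] = grp[["neuron_id", "time_ms"]].to_numpy(dtype=float)
    cur_df = pd.read_csv(src / _CURRENT_FILE)
    avg = {
        region: np.vstack([
            cur_df[f"i_e_{region.lower()}"].to_numpy(),
            cur_df[f"i_i_{region.lower()}"].to_numpy(),
        ])
        for region in REGIONS
    }
    meta = json.loads((src / _META_FILE).read_text())
    return SimResult(time=time, v_regions=v, spikes=spikes,
                     avg_currents=avg, meta=meta)


# ---------------------------------------------------------------------------
# synthetic fixture traces
# ---------------------------------------------------------------------------


def make_fixture_trace(peaks, duration: float, dt: float = 0.1,
                       baseline: float = -65.0, pulse_width: float = 1.0,
                       noise_level: float = 0.0, seed: int | None = None):
    """Synthetic voltage trace with spike-shaped bumps at known places.

    ``peaks`` is a sequence of ``(time_ms, height_mV)`` pairs; each bump
    is a triangular pulse of base width ``2 * pulse_width`` rising from
    ``baseline`` to ``height``.  Seeded Gaussian jitter of standard
    deviation ``noise_level`` is added throughout.  Raises
    :class:`FixtureError` when bumps overlap or leave the duration.
    """
    peaks = sorted(peaks)
    for t, _ in peaks:
        if not 0 <= t <= duration:
            raise FixtureError(f"peak at {t} ms outside duration {duration} ms")
    for (t0, _), (t1, _) in zip(peaks, peaks[1:]):
        if t1 - t0 < 2 * pulse_width:
            raise FixtureError(
                f"peaks at {t0} and {t1} ms overlap (pulse width {pulse_width} ms)"
            )
    t = np.arange(0.0, duration + dt / 2, dt)
    v = np.full_like(t, baseline)
    for tp, height in peaks:
        tri = np.clip(1.0 - np.abs(t - tp) / pulse_width, 0.0, None)
        v += (height - baseline) * tri
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_level, size=t.shape)
    return t, v
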