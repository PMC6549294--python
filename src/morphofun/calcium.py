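"""Functional profiling from calcium time-lapse recordings.

Extracts per-neuron GCaMP fluorescence traces using a nuclear-reporter
reference stack for soma segmentation, normalises them to dF/F0, detects
calcium bursts with a robust (MAD-based) threshold crossing detector, and
computes the functional descriptor class: percentage of active neurons,
per-neuron burst frequency and amplitude, network (synchronous) burst
frequency, and the burst correlation — the mean of the off-diagonal pairwise
Pearson correlation matrix of the normalised traces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .morpho import max_project, segment_nuclei

__all__ = [
    "CalciumRecording",
    "TraceMatrix",
    "BurstTrain",
    "CalciumConfig",
    "segment_somata",
    "extract_traces",
    "detect_bursts",
    "functional_descriptors",
    "profile_recording",
]


@dataclass
class CalciumRecording:
    """One time-lapse recording: activity frames plus nuclear reference stack."""

    frames: np.ndarray  # (n_frames, H, W)
    reference_stack: np.ndarray  # (n_z, H, W)
    frame_rate: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.reference_stack = np.asarray(self.reference_stack)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if self.frames.shape[0] < 2:
            raise ValueError("recording needs at least 2 frames")
        if self.reference_stack.shape[-2:] != self.frames.shape[-2:]:
            raise ValueError("reference stack not co-registered with frames")


@dataclass
class TraceMatrix:
    """Normalised (dF/F0) per-neuron fluorescence traces."""

    values: np.ndarray  # (n_neurons, n_frames)
    frame_rate: float
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.values.shape[1] < 2:
            raise ValueError("traces need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces must be finite")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.values.shape[1] / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.frame_rate


@dataclass
class BurstTrain:
    """Detected bursts per neuron plus field-level network bursts."""

    onsets: dict[int, np.ndarray]  # neuron id -> onset times (s), increasing
    amplitudes: dict[int, np.ndarray]  # neuron id -> peak dF/F0 per burst
    network_burst_times: np.ndarray  # s

    @property
    def active_ids(self) -> list[int]:
        return [i for i, on in self.onsets.items() if len(on) > 0]


@dataclass
class CalciumConfig:
    """Tunable parameters of the functional pipeline."""

    soma_threshold: float = 55.0
    min_soma_area_px: int = 30
    soma_split_min_distance: int = 8
    f0_percentile: float = 10.0
    k_mad: float = 3.0
    min_interval_s: float = 2.0
    network_bin_s: float = 1.0
    network_participation: float = 0.5


def segment_somata(
    reference_stack: np.ndarray,
    threshold: float = 55.0,
    min_area_px: int = 30,
    split_min_distance: int = 8,
) -> np.ndarray:
    """Label somata on the max projection of the nuclear-reporter stack.

    Reuses the nucleus segmentation machinery (threshold + watershed split).
    """
    proj = max_project(np.asarray(reference_stack))
    return segment_nuclei(
        proj, threshold, min_area_px=min_area_px, split_min_distance=split_min_distance
    )


def extract_traces(
    movie: np.ndarray,
    soma_labels: np.ndarray,
    frame_rate: float = 2.0,
    f0_percentile: float = 10.0,
) -> TraceMatrix:
    """Mean-intensity trace per soma, normalised to dF/F0.

    The raw trace of a soma is the mean activity-channel intensity over its
    label per frame; F0 is a robust baseline, the ``f0_percentile``-th
    percentile of the raw trace (insensitive to bursts inflating the mean).
    """
    movie = np.asarray(movie, dtype=float)
    labels = np.asarray(soma_labels)
    if movie.shape[1:] != labels.shape:
        raise ValueError("movie frames not co-registered with soma labels")
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        raise ValueError("no somata in label mask")
    sizes = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    if np.any(sizes == 0):
        raise ValueError("soma label with zero pixels")
    raw = np.stack([ndi.mean(frame, labels, ids) for frame in movie], axis=1)
    f0 = np.percentile(raw, f0_percentile, axis=1, keepdims=True)
    f0 = np.where(np.abs(f0) < 1e-12, 1e-12, f0)
    values = (raw - f0) / f0
    return TraceMatrix(values=values, frame_rate=frame_rate, neuron_ids=ids)


def detect_bursts(
    traces: TraceMatrix,
    k_mad: float = 3.0,
    min_interval_s: float = 2.0,
    network_bin_s: float = 1.0,
    network_participation: float = 0.5,
) -> BurstTrain:
    """Robust threshold-crossing burst detection.

    Per neuron, burst onsets are upward crossings of
    ``median + k_mad * 1.4826 * MAD`` of the trace, merged when closer than
    ``min_interval_s``; the burst amplitude is the trace maximum between an
    onset and the next one. A neuron is active iff it has at least one burst.
    Network bursts are ``network_bin_s``-wide bins in which at least
    ``network_participation`` of the active neurons have a burst onset.
    """
    if not k_mad > 0:
        raise ValueError("k_mad must be positive")
    v = traces.values
    fr = traces.frame_rate
    onsets: dict[int, np.ndarray] = {}
    amplitudes: dict[int, np.ndarray] = {}
    for i, nid in enumerate(traces.neuron_ids):
        x = v[i]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        theta = med + k_mad * 1.4826 * mad
        above = x > theta
        rising = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        # merge onsets closer than min_interval_s
        merged: list[int] = []
        for idx in rising:
            if not merged or (idx - merged[-1]) / fr >= min_interval_s:
                merged.append(int(idx))
        on_times = np.asarray(merged, dtype=float) / fr
        amps = np.empty(len(merged))
        for j, idx in enumerate(merged):
            stop = merged[j + 1] if j + 1 < len(merged) else len(x)
            amps[j] = x[idx:stop].max()
        onsets[int(nid)] = on_times
        amplitudes[int(nid)] = amps

    active = [i for i, on in onsets.items() if len(on) > 0]
    if active:
        n_bins = int(np.ceil(v.shape[1] / fr / network_bin_s))
        participation = np.zeros(n_bins, dtype=int)
        for nid in active:
            bins = np.unique((onsets[nid] / network_bin_s).astype(int))
            bins = bins[bins < n_bins]
            participation[bins] += 1
        hit = participation >= max(network_participation * len(active), 1)
        # consecutive hit bins form one network burst
        starts = np.flatnonzero(hit & ~np.r_[False, hit[:-1]])
        network_times = (starts + 0.5) * network_bin_s
    else:
        network_times = np.asarray([])
    return BurstTrain(onsets=onsets, amplitudes=amplitudes, network_burst_times=network_times)


def burst_correlation(traces: TraceMatrix) -> float:
    """Mean off-diagonal pairwise Pearson correlation of the traces.

    Pairs involving a constant trace contribute 0. Returns NaN with fewer
    than two neurons.
    """
    v = traces.values
    n = v.shape[0]
    if n < 2:
        return float("nan")
    sd = v.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(v)
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        if sd[i] == 0 or sd[j] == 0:
            vals.append(0.0)
        else:
            vals.append(float(c[i, j]))
    return float(np.mean(vals))


def functional_descriptors(
    traces: TraceMatrix,
    bursts: BurstTrain,
) -> dict[str, float]:
    """Functional descriptor class for one recording.

    Percent active neurons, mean per-neuron burst frequency (Hz) and peak
    amplitude (dF/F0) over active neurons, network burst frequency (Hz), and
    the burst correlation. With fewer than two neurons the correlation is
    emitted as NaN (missing).
    """
    n = traces.n_neurons
    dur = traces.duration_s
    active = bursts.active_ids
    out: dict[str, float] = {}
    out["percent_active"] = 100.0 * len(active) / n if n else np.nan
    if active:
        rates = [len(bursts.onsets[i]) / dur for i in active]
        amps = np.concatenate([bursts.amplitudes[i] for i in active])
        out["burst_rate_hz"] = float(np.mean(rates))
        out["burst_amplitude"] = float(amps.mean())
    else:
        out["burst_rate_hz"] = 0.0
        out["burst_amplitude"] = np.nan
    out["network_burst_rate_hz"] = len(bursts.network_burst_times) / dur
    out["burst_correlation"] = burst_correlation(traces)
    return out


def profile_recording(
    recording: CalciumRecording,
    config: CalciumConfig | None = None,
) -> dict[str, float]:
    """Full functional pipeline for one recording: somata -> traces -> bursts."""
    cfg = config or CalciumConfig()
    labels = segment_somata(
        recording.reference_stack, cfg.soma_threshold,
        min_area_px=cfg.min_soma_area_px, split_min_distance=cfg.soma_split_min_distance,
    )
    row = dict(recording.metadata)
    if labels.max() == 0:
        row.update(
            n_neurons=0.0, percent_active=np.nan, burst_rate_hz=np.nan,
            burst_amplitude=np.nan, network_burst_rate_hz=np.nan, burst_correlation=np.nan,
        )
        return row
    traces = extract_traces(
        recording.frames, labels, recording.frame_rate, cfg.f0_percentile
    )
    bursts = detect_bursts(
        traces, cfg.k_mad, cfg.min_interval_s, cfg.network_bin_s, cfg.network_participation
    )
    row["n_neurons"] = float(traces.n_neurons)
    row.update(functional_descriptors(traces, bursts))
    return row
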