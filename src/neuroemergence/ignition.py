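"""Intrinsic-driven ignition and the spatiotemporal hierarchy of brain activity.

A region triggers a "driver event" whenever its narrowband (0.04-0.07 Hz)
z-scored signal crosses z = 1 from below.  The breadth of the ignition that
event elicits is the number of regions that themselves show an event inside a
short window after it (the largest connected component of the binary
co-event matrix, which links every pair of co-eventful regions and is
therefore a clique).  Averaging each region's ignition breadth over its
events gives a regional profile; the standard deviation of that profile
across regions is the spatiotemporal hierarchy: large when some regions
ignite globally and others not at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .datatypes import RegionalTimeseries


@dataclass
class EventRaster:
    """Binary driver-event raster (regions x timepoints)."""

    events: np.ndarray
    tr: float
    band: tuple[float, float]
    z_threshold: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=bool)
        if self.events.ndim != 2:
            raise ValueError("event raster must be 2-D")

    @property
    def n_regions(self) -> int:
        return self.events.shape[0]


@dataclass
class IgnitionProfile:
    """Per-region mean ignition breadth and event counts (NaN where eventless)."""

    mean_idi: np.ndarray
    n_events: np.ndarray


def bandpass(
    data: np.ndarray, tr: float, band: tuple[float, float], order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along time (rows are regions)."""
    low, high = band
    nyquist = 0.5 / tr
    if not 0 < low < high < nyquist:
        raise ValueError(f"band {band} must lie strictly inside (0, {nyquist:.3f}) Hz")
    b, a = butter(order, [low, high], btype="band", fs=1.0 / tr)
    return filtfilt(b, a, data, axis=-1)


def detect_events(
    ts: RegionalTimeseries,
    band: tuple[float, float] = (0.04, 0.07),
    z_threshold: float = 1.0,
) -> EventRaster:
    """Detect upward threshold crossings of the narrowband z-scored signal.

    An event occurs at (i, t) when z_i(t) > threshold and z_i(t-1) <= threshold;
    no event is possible at t = 0.  Constant regions yield no events.
    """
    if ts.n_timepoints <= 20:
        raise ValueError("need more than 20 timepoints for event detection")
    filtered = bandpass(ts.data, ts.tr, band)
    sd = filtered.std(axis=1, keepdims=True)
    # constant regions leave only filter roundoff; they carry no events
    raw_scale = ts.data.std(axis=1, keepdims=True)
    degenerate = (raw_scale == 0) | (sd <= 1e-8 * np.maximum(raw_scale, 1e-300))
    sd[degenerate | (sd == 0)] = np.inf
    z = (filtered - filtered.mean(axis=1, keepdims=True)) / sd
    above = z > z_threshold
    crossing = above[:, 1:] & ~above[:, :-1]
    events = np.concatenate([np.zeros((ts.n_regions, 1), dtype=bool), crossing], axis=1)
    return EventRaster(events=events, tr=ts.tr, band=band, z_threshold=z_threshold)


def intrinsic_driven_ignition(raster: EventRaster, window: int = 4) -> IgnitionProfile:
    """Mean ignition breadth per driver region.

    For each driver event at (i, t) the participating set is every region with
    at least one event in [t, t + window - 1]; the co-event matrix links all
    participating pairs, so its largest connected component is the
    participating-set size (and always contains the driver, hence >= 1).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ev = raster.events
    n, T = ev.shape
    mean_idi = np.full(n, np.nan)
    n_events = ev.sum(axis=1).astype(int)
    # any-event-in-window, computed once for all (region, t)
    padded = np.zeros((n, T + window - 1), dtype=bool)
    padded[:, :T] = ev
    windows = np.zeros((n, T), dtype=bool)
    for w in range(window):
        windows |= padded[:, w : w + T]
    participating = windows.sum(axis=0)  # regions with an event in [t, t+window-1]
    for i in range(n):
        times = np.flatnonzero(ev[i])
        if len(times):
            mean_idi[i] = participating[times].mean()
    return IgnitionProfile(mean_idi=mean_idi, n_events=n_events)


def spatiotemporal_hierarchy(profile: IgnitionProfile, include_eventless: bool = False) -> float:
    """Across-region sample standard deviation of the mean ignition breadth.

    Regions without events are excluded by default; with
    ``include_eventless=True`` they enter as breadth 0.
    """
    vals = profile.mean_idi.copy()
    if include_eventless:
        vals = np.where(np.isnan(vals), 0.0, vals)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 eventful regions for a hierarchy score")
    return float(np.std(vals, ddof=1))


def hierarchy_from_timeseries(
    ts: RegionalTimeseries,
    band: tuple[float, float] = (0.04, 0.07),
    z_threshold: float = 1.0,
    window: int = 4,
) -> tuple[float, IgnitionProfile]:
    """Convenience wrapper: events -> ignition profile -> hierarchy score."""
    raster = detect_events(ts, band=band, z_threshold=z_threshold)
    profile = intrinsic_driven_ignition(raster, window=window)
    return spatiotemporal_hierarchy(profile), profile
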