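"""Network-burst detection and burst-ratio statistics.

A network burst is a window of quasi-synchronous collective firing: the
number of distinct units spiking within a 200 ms window exceeding 20% of
the population.  The window slides at 1 ms resolution; a maximal run of
qualifying window positions collapses to a single event whose onset is the
first qualifying position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import BurstConfig
from .dynamics import SpikeRaster

__all__ = ["BurstEvent", "detect_bursts", "burst_ratio",
           "summarize_ratios", "roi_grid_raster"]


@dataclass
class BurstEvent:
    onset_ms: float
    n_participating: int
    fraction: float


def _participation_counts(raster: SpikeRaster, window_ms: float,
                          n_units: int, stride_ms: float = 1.0) -> np.ndarray:
    """Distinct-unit participation for every window start position.

    Window at position t covers [t, t + window). Computed per unit with an
    interval difference array (a unit counts once however often it fires).
    """
    w = int(round(window_ms / stride_ms))
    T = int(np.ceil(raster.duration_ms / stride_ms))
    n_pos = max(T - w + 1, 1)
    counts = np.zeros(n_pos + 1, dtype=np.int64)
    if raster.n_spikes == 0:
        return counts[:n_pos]
    bins = np.minimum((raster.times / stride_ms).astype(np.int64), T - 1)
    # windows covering a spike at bin s start in [s - w + 1, s]
    for u in range(n_units):
        s = np.unique(bins[raster.units == u])
        if s.size == 0:
            continue
        lo = np.maximum(s - w + 1, 0)
        hi = np.minimum(s, n_pos - 1)
        ok = lo <= hi
        # merge overlapping coverage intervals, then mark via diff array
        diff = np.zeros(n_pos + 1, dtype=np.int64)
        np.add.at(diff, lo[ok], 1)
        np.add.at(diff, hi[ok] + 1, -1)
        counts[:n_pos] += (np.cumsum(diff[:n_pos]) > 0)
    return counts[:n_pos]


def detect_bursts(raster: SpikeRaster, config: BurstConfig | None = None,
                  n_units: int | None = None) -> list:
    """Detect network bursts in a raster.

    ``n_units`` is the participation denominator (defaults to the raster's
    unit count; pass the alive-unit count for lesioned networks).
    """
    config = config if config is not None else BurstConfig()
    if n_units is None:
        n_units = raster.n_units
    if n_units <= 0:
        raise ValueError("burst detection requires at least one unit")
    part = _participation_counts(raster, config.window, raster.n_units)
    thresh = config.participation_threshold * n_units
    above = part > thresh
    if not above.any():
        return []
    edges = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    events = []
    for s, e in zip(starts, ends):
        peak = int(part[s:e].max())
        events.append(BurstEvent(onset_ms=float(s), n_participating=peak,
                                 fraction=peak / n_units))
    return events


def burst_ratio(test_raster: SpikeRaster, reference_raster: SpikeRaster,
                config: BurstConfig | None = None,
                n_units_test: int | None = None,
                n_units_reference: int | None = None) -> float:
    """Burst-count ratio test/reference (rate-normalized if the epochs have
    different durations).  NaN with a warning when the reference has no
    bursts."""
    n_test = len(detect_bursts(test_raster, config, n_units_test))
    n_ref = len(detect_bursts(reference_raster, config, n_units_reference))
    if n_ref == 0:
        warnings.warn("reference epoch contains no bursts; ratio undefined")
        return float("nan")
    ratio = n_test / n_ref
    if test_raster.duration_ms != reference_raster.duration_ms:
        ratio *= reference_raster.duration_ms / test_raster.duration_ms
    return float(ratio)


def summarize_ratios(ratios) -> dict:
    """Mean and normal-approximation 95% CI over replicates; undefined
    (NaN) replicates are excluded."""
    r = np.asarray([x for x in ratios if np.isfinite(x)], dtype=float)
    if r.size == 0:
        return {"mean": float("nan"), "ci95": (float("nan"), float("nan")),
                "n": 0}
    mean = float(r.mean())
    if r.size > 1:
        half = 1.96 * float(r.std(ddof=1)) / np.sqrt(r.size)
    else:
        half = float("nan")
    return {"mean": mean, "ci95": (mean - half, mean + half),
            "n": int(r.size), "sd": float(r.std(ddof=1)) if r.size > 1
            else float("nan")}


def roi_grid_raster(raster: SpikeRaster, positions: np.ndarray,
                    roi_size_mm: float = 0.150) -> SpikeRaster:
    """Pool unit spikes onto a square ROI grid (like imaging regions of
    interest), for apples-to-apples comparison with in-vitro processing."""
    xy = np.asarray(positions)
    gx = np.floor(xy[:, 0] / roi_size_mm).astype(np.int64)
    gy = np.floor(xy[:, 1] / roi_size_mm).astype(np.int64)
    gx -= gx.min() if len(gx) else 0
    gy -= gy.min() if len(gy) else 0
    roi_of_unit = gx * (gy.max() + 1 if len(gy) else 1) + gy
    _, roi_idx = np.unique(roi_of_unit, return_inverse=True)
    return SpikeRaster(roi_idx[raster.units], raster.times.copy(),
                       int(roi_idx.max()) + 1 if len(roi_idx) else 0,
                       raster.duration_ms, raster.dt)
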