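"""Social-behaviour statistics from paired trajectories.

A focal animal and a neighbour (a real conspecific or a projected dot)
are tracked at 30 fps in a shallow dish.  The statistics here quantify
the two classical components of shoaling:

* **Attraction** — how much closer the pair stays than chance.  The real
  mean inter-animal distance per 5-min chunk (IADr) is compared against
  a time-shift null (IADs, the mean over 10 cyclic shifts of the
  neighbour trajectory), giving attraction = (IADs - IADr) / IADs.
  Shifting destroys the temporal coupling while preserving each
  animal's spatial occupancy, so independent swimmers score ~0 and a
  perfect follower scores 1.

* **Repulsion** — the short-range density deficit around the focal
  animal.  Neighbour positions are histogrammed in the focal animal's
  egocentric (heading-up) frame; the smoothed map is scanned radially
  and the area of the central void below the peak of the averaged scan,
  normalized by the scan length, is the repulsion score.

Bout detection (speed-peak based) and the looming escape fraction
(post/pre displacement ratio > 2) complete the assay read-outs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .stimuli import PositionSeries

__all__ = [
    "Track",
    "AttractionResult",
    "NeighborMap",
    "RepulsionResult",
    "BoutEvents",
    "chunked_iad",
    "shifted_iad",
    "attraction_score",
    "attraction",
    "neighbor_density_map",
    "repulsion_score",
    "detect_bouts",
    "escape_fraction",
]


class Track(PositionSeries):
    """Uniformly sampled animal or stimulus trajectory (mm, s, optional heading)."""


def _check_aligned(a: Track, b: Track) -> float:
    if len(a) != len(b) or not np.allclose(a.t_s, b.t_s, rtol=0, atol=1e-9):
        raise ValueError("tracks are not time-aligned on the same grid")
    return a.dt_s


@dataclass
class AttractionResult:
    iadr_mm: np.ndarray          # per-chunk real mean distance
    iads_mm: np.ndarray          # per-chunk time-shift-null mean distance
    per_chunk: np.ndarray        # per-chunk attraction values
    attraction: float            # per-animal value: mean over chunks


def chunked_iad(focal: Track, neighbor: Track, chunk_s: float = 300.0) -> np.ndarray:
    """Mean inter-animal (or animal-dot) distance per non-overlapping chunk (IADr).

    The trailing partial chunk is dropped.
    """
    dt = _check_aligned(focal, neighbor)
    n_per = int(round(chunk_s / dt))
    if n_per < 1:
        raise ValueError("chunk shorter than one sample")
    n_chunks = len(focal) // n_per
    if n_chunks == 0:
        raise ValueError("track shorter than one chunk")
    d = np.hypot(focal.x_mm - neighbor.x_mm, focal.y_mm - neighbor.y_mm)
    d = d[: n_chunks * n_per].reshape(n_chunks, n_per)
    return d.mean(axis=1)


def shifted_iad(focal: Track, neighbor: Track, chunk_s: float = 300.0,
                n_shifts: int = 10) -> np.ndarray:
    """Time-shift-null mean distance per chunk (IADs).

    Within each chunk the neighbour trajectory is cyclically shifted by
    k * chunk / (n_shifts + 1) for k = 1..n_shifts and the mean distance is
    recomputed; IADs is the mean over shifts.  Evenly spaced shifts give a
    minimum offset of ~27 s for 5-min chunks, well beyond the correlation
    time of individual swim bouts.
    """
    dt = _check_aligned(focal, neighbor)
    n_per = int(round(chunk_s / dt))
    n_chunks = len(focal) // n_per
    if n_chunks == 0:
        raise ValueError("track shorter than one chunk")
    if n_per < n_shifts + 1:
        raise ValueError("chunk too short for the requested number of shifts")
    fx = focal.x_mm[: n_chunks * n_per].reshape(n_chunks, n_per)
    fy = focal.y_mm[: n_chunks * n_per].reshape(n_chunks, n_per)
    nx = neighbor.x_mm[: n_chunks * n_per].reshape(n_chunks, n_per)
    ny = neighbor.y_mm[: n_chunks * n_per].reshape(n_chunks, n_per)
    out = np.zeros(n_chunks)
    for k in range(1, n_shifts + 1):
        s = int(round(k * n_per / (n_shifts + 1)))
        sx = np.roll(nx, s, axis=1)
        sy = np.roll(ny, s, axis=1)
        out += np.hypot(fx - sx, fy - sy).mean(axis=1)
    return out / n_shifts


def attraction_score(iadr_mm, iads_mm):
    """Attraction = (IADs - IADr) / IADs, elementwise; undefined at IADs = 0."""
    iadr = np.asarray(iadr_mm, dtype=float)
    iads = np.asarray(iads_mm, dtype=float)
    if np.any(iads <= 0):
        raise ValueError("IADs must be > 0 (permanently coincident tracks have no null)")
    out = (iads - iadr) / iads
    return float(out) if out.ndim == 0 else out


def attraction(focal: Track, neighbor: Track, chunk_s: float = 300.0,
               n_shifts: int = 10) -> AttractionResult:
    """Full attraction computation: chunked IADr, shift-null IADs, per-animal score."""
    iadr = chunked_iad(focal, neighbor, chunk_s)
    iads = shifted_iad(focal, neighbor, chunk_s, n_shifts)
    per_chunk = attraction_score(iadr, iads)
    return AttractionResult(iadr, iads, per_chunk, float(np.mean(per_chunk)))


# ---------------------------------------------------------------------------
# egocentric neighbour maps


@dataclass
class NeighborMap:
    """2-D histogram of neighbour positions, focal animal at centre heading up (+y)."""

    counts: np.ndarray           # [ix, iy]; x = rightward, y = forward
    extent_mm: float
    bin_mm: float
    n_samples: int               # samples retained in the map
    n_clipped: int               # samples outside the extent
    n_skipped: int               # samples with undefined heading
    normalized: bool = False

    @property
    def edges_mm(self) -> np.ndarray:
        half = self.extent_mm / 2.0
        return np.arange(-half, half + self.bin_mm / 2.0, self.bin_mm)

    def normalize(self) -> "NeighborMap":
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty map")
        return NeighborMap(self.counts / total, self.extent_mm, self.bin_mm,
                           self.n_samples, self.n_clipped, self.n_skipped, True)


def _heading_from_displacement(track: Track, min_step_mm: float):
    dx = np.diff(track.x_mm)
    dy = np.diff(track.y_mm)
    step = np.hypot(dx, dy)
    ok = step >= min_step_mm
    return np.arctan2(dy, dx), ok


def neighbor_density_map(focal: Track, neighbor: Track, extent_mm: float = 60.0,
                         bin_mm: float = 1.0, min_step_mm: float = 0.1) -> NeighborMap:
    """Histogram neighbour positions in the focal animal's heading-up frame.

    Heading is taken from ``focal.heading_rad`` when present, otherwise from
    frame-to-frame displacement; displacement samples below ``min_step_mm``
    have no defined heading and are skipped.  Samples landing outside the
    map extent are discarded but tallied in ``n_clipped``.
    """
    _check_aligned(focal, neighbor)
    if focal.heading_rad is not None:
        h = np.asarray(focal.heading_rad, dtype=float)
        ok = np.isfinite(h)
        rel_x = neighbor.x_mm - focal.x_mm
        rel_y = neighbor.y_mm - focal.y_mm
    else:
        h, ok = _heading_from_displacement(focal, min_step_mm)
        rel_x = (neighbor.x_mm - focal.x_mm)[:-1]
        rel_y = (neighbor.y_mm - focal.y_mm)[:-1]
    n_skipped = int((~ok).sum())
    h, rel_x, rel_y = h[ok], rel_x[ok], rel_y[ok]
    # forward axis = heading -> +y; rightward axis -> +x
    y_ego = rel_x * np.cos(h) + rel_y * np.sin(h)
    x_ego = rel_x * np.sin(h) - rel_y * np.cos(h)
    half = extent_mm / 2.0
    edges = np.arange(-half, half + bin_mm / 2.0, bin_mm)
    inside = (np.abs(x_ego) < half) & (np.abs(y_ego) < half)
    counts, _, _ = np.histogram2d(x_ego[inside], y_ego[inside], bins=[edges, edges])
    return NeighborMap(counts, extent_mm, bin_mm,
                       n_samples=int(inside.sum()), n_clipped=int((~inside).sum()),
                       n_skipped=n_skipped)


@dataclass
class RepulsionResult:
    smoothed_map: np.ndarray
    radii_mm: np.ndarray
    scans: np.ndarray            # (n_scans, n_radii) individual radial scans
    mean_scan: np.ndarray
    r_peak_mm: float
    score: float


def repulsion_score(nmap: NeighborMap, sigma_mm: float = 3.0, n_scans: int = 24,
                    scan_len_mm: float = 29.0, scan_width_mm: float = 5.0,
                    n_width_rays: int = 5) -> RepulsionResult:
    """Central density deficit of a neighbour map ("reduction in attraction at the centre").

    The map is Gaussian-smoothed (sigma 3 mm), scanned along ``n_scans``
    equally spaced rays from the centre out to ``scan_len_mm``; each scan
    averages ``n_width_rays`` parallel rays spanning ``scan_width_mm``.
    With r_peak the radius of maximum density on the averaged scan, the
    score is the area between the peak level and the scan at r < r_peak,
    divided by the full scan length.  Zero when the density peaks at the
    centre; positive when a short-range void surrounds the animal.
    """
    if nmap.counts.sum() == 0:
        raise ValueError("empty neighbour map has no density")
    if nmap.extent_mm < 2 * scan_len_mm:
        raise ValueError("map extent too small for the requested scan length")
    bin_mm = nmap.bin_mm
    smoothed = ndimage.gaussian_filter(nmap.counts.astype(float), sigma=sigma_mm / bin_mm)
    centre_px = (np.array(smoothed.shape) - 1) / 2.0
    r = np.arange(0.0, scan_len_mm + bin_mm / 4.0, bin_mm / 2.0)
    offsets = np.linspace(-scan_width_mm / 2.0, scan_width_mm / 2.0, n_width_rays)
    angles = 2.0 * math.pi * np.arange(n_scans) / n_scans
    scans = np.zeros((n_scans, len(r)))
    for i, th in enumerate(angles):
        ux, uy = math.cos(th), math.sin(th)
        acc = np.zeros(len(r))
        for off in offsets:
            # offset perpendicular to the ray
            px = centre_px[0] + (r * ux - off * uy) / bin_mm
            py = centre_px[1] + (r * uy + off * ux) / bin_mm
            acc += ndimage.map_coordinates(smoothed, [px, py], order=1, mode="nearest")
        scans[i] = acc / n_width_rays
    mean_scan = scans.mean(axis=0)
    i_peak = int(np.argmax(mean_scan))
    r_peak = float(r[i_peak])
    if i_peak == 0:
        score = 0.0
    else:
        deficit = mean_scan[i_peak] - mean_scan[: i_peak + 1]
        score = float(np.trapezoid(deficit, r[: i_peak + 1]) / scan_len_mm)
    return RepulsionResult(smoothed, r, scans, mean_scan, r_peak, score)


# ---------------------------------------------------------------------------
# bouts and escapes


@dataclass
class BoutEvents:
    peak_times_s: np.ndarray
    start_times_s: np.ndarray
    durations_s: np.ndarray
    threshold_mm_s: float

    @property
    def n_bouts(self) -> int:
        return len(self.peak_times_s)

    def rate_hz(self, duration_s: float) -> float:
        return self.n_bouts / duration_s


def detect_bouts(track: Track, threshold_mm_s: Optional[float] = None) -> BoutEvents:
    """Detect swim bouts as supra-threshold peaks in frame-to-frame speed.

    The default threshold is noise-adaptive: median + 3 * MAD of the speed
    series.  Each contiguous supra-threshold span yields one bout whose
    duration is the span length and whose time is the speed peak within it.
    """
    dt = track.dt_s
    if not (dt <= 0.1):
        raise ValueError("bout detection requires sampling at 10 Hz or faster")
    speed = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm)) / dt
    if threshold_mm_s is None:
        med = float(np.median(speed))
        mad = float(np.median(np.abs(speed - med)))
        # tiny absolute floor so a perfectly steady glide (MAD = 0 up to
        # floating-point jitter) yields no bouts
        threshold_mm_s = med + 3.0 * mad + 1e-6
    above = speed > threshold_mm_s
    if not above.any():
        return BoutEvents(np.array([]), np.array([]), np.array([]), threshold_mm_s)
    # contiguous spans of supra-threshold speed
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])
    t_mid = track.t_s[:-1] + dt / 2.0  # speed samples live between frames
    peaks, t_start, durs = [], [], []
    for s, e in zip(starts, ends):
        i = s + int(np.argmax(speed[s:e]))
        peaks.append(t_mid[i])
        t_start.append(t_mid[s])
        durs.append((e - s) * dt)
    return BoutEvents(np.array(peaks), np.array(t_start), np.array(durs), threshold_mm_s)


def escape_fraction(track: Track, loom_times_s: Sequence[float], pre_s: float = 1.3,
                    post_s: float = 1.0, ratio: float = 2.0) -> tuple[float, list[bool]]:
    """Fraction of looming trials with an escape response.

    A trial counts as an escape when the path length travelled in the
    ``post_s`` window immediately after the loom exceeds ``ratio`` times
    the path length in the ``pre_s`` window before it.  Trials whose
    windows are truncated by the recording edges are excluded.
    """
    dt = track.dt_s
    step = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    t0, t1 = track.t_s[0], track.t_s[-1]
    outcomes: list[bool] = []
    for tl in loom_times_s:
        if tl - pre_s < t0 or tl + post_s > t1:
            continue  # truncated window: trial excluded
        i = np.searchsorted(track.t_s, tl)
        n_pre = int(round(pre_s / dt))
        n_post = int(round(post_s / dt))
        pre_path = step[max(i - n_pre, 0): i].sum()
        post_path = step[i: i + n_post].sum()
        outcomes.append(post_path > ratio * pre_path)
    if not outcomes:
        raise ValueError("no looming trial has complete pre/post windows")
    return float(np.mean(outcomes)), outcomes
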