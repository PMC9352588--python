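"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one input class of the analysis modules so the
whole pipeline can be exercised end to end with planted parameters:

* :func:`gen_dyad` — bout-structured dyadic swimming in a 100 mm dish,
  with a tunable attraction gain and short-range exclusion radius.  The
  follower is a minimal kinematic model (discrete bouts, noisy heading,
  range-error steering), a test harness rather than a behavioural claim.
* :func:`gen_traces` — calcium traces of frequency-tuned and untuned
  neurons: log-Gaussian frequency tuning, single-exponential calcium
  kernel (tau = 7 s, matching nuclear GCaMP6s kinetics), 5 volumes/s
  acquisition mean-downsampled fivefold to 1 volume/s.
* :func:`gen_cell_points` — spatially clustered 3-D cell coordinates in
  two hemispheres.
* :func:`gen_cfos_volumes` — two-channel volumes with exponential depth
  attenuation and per-cluster condition factors chosen to realize target
  Cohen's d at the given group size.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import Track
from .cfos import VolumePair
from .anatomy import CellPoints
from .tuning import TraceSet, make_schedule

__all__ = [
    "FollowerParams",
    "NeuronSimParams",
    "gen_dyad",
    "gen_traces",
    "gen_cell_points",
    "gen_cfos_volumes",
]


@dataclass
class FollowerParams:
    """Kinematic parameters of the synthetic shoaling dyad.

    The attraction gain is the fraction of the bearing error toward the
    partner corrected at each bout when beyond the preferred distance
    (steering away instead when inside the exclusion radius); juvenile
    zebrafish swim at ~1.25 bouts/s and ~5 mm/s average speed.
    """

    attraction_gain: float = 0.8
    preferred_distance_mm: float = 12.0
    exclusion_radius_mm: float = 6.0
    bout_freq_hz: float = 1.25
    bout_speed_mm_s: float = 5.0
    heading_noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.exclusion_radius_mm < self.preferred_distance_mm):
            raise ValueError("exclusion radius must be smaller than the preferred distance")
        if self.bout_freq_hz <= 0 or self.bout_speed_mm_s <= 0:
            raise ValueError("bout rate and speed must be positive")


def _wrap(a):
    return (a + math.pi) % (2 * math.pi) - math.pi


def _simulate_agents(kind: str, params: FollowerParams, duration_s: float,
                     dish_radius_mm: float, rng: np.random.Generator):
    """Event-driven bout simulation; returns per-agent bout event lists."""
    f = params.bout_freq_hz
    L = params.bout_speed_mm_s / f          # displacement per bout => mean speed = bout speed
    margin = 2.0
    r0 = dish_radius_mm * 0.5
    pos = [rng.uniform(-r0, r0, 2), rng.uniform(-r0, r0, 2)]
    head = list(rng.uniform(-math.pi, math.pi, 2))
    next_t = [float(rng.uniform(0, 1.0 / f)), float(rng.uniform(0, 1.0 / f))]
    events: list[list[tuple]] = [[], []]
    while min(next_t) < duration_s:
        i = 0 if next_t[0] <= next_t[1] else 1
        t = next_t[i]
        h = head[i] + rng.normal(0.0, params.heading_noise_sd)
        if kind == "follower" and i == 1:
            rel = pos[0] - pos[1]
            dist = float(np.hypot(*rel))
            bearing = math.atan2(rel[1], rel[0])
            if dist > params.preferred_distance_mm:
                h += params.attraction_gain * _wrap(bearing - h)
            elif dist < params.exclusion_radius_mm:
                h += params.attraction_gain * _wrap(bearing + math.pi - h)
        new = pos[i] + L * np.array([math.cos(h), math.sin(h)])
        if np.hypot(*new) > dish_radius_mm - margin:
            # turn back toward the dish centre (reflective boundary behaviour)
            h = math.atan2(-pos[i][1], -pos[i][0]) + rng.normal(0.0, 0.3)
            new = pos[i] + L * np.array([math.cos(h), math.sin(h)])
            rad = np.hypot(*new)
            if rad > dish_radius_mm - margin:
                new *= (dish_radius_mm - margin) / rad
        events[i].append((t, pos[i].copy(), new.copy()))
        pos[i] = new
        head[i] = h
        # jittered inter-bout interval, bounded below the bout execution time
        next_t[i] = t + max(0.3, rng.normal(1.0 / f, 0.1 / f))
    return events


def _render_track(events, duration_s: float, fps: float, bout_dur_s: float) -> Track:
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    times, xs, ys = [0.0], [events[0][1][0]], [events[0][1][1]]
    for (tb, p0, p1) in events:
        if tb > times[-1]:
            times.extend([tb, tb + bout_dur_s])
            xs.extend([p0[0], p1[0]])
            ys.extend([p0[1], p1[1]])
    x = np.interp(t, times, xs)
    y = np.interp(t, times, ys)
    return Track(t_s=t, x_mm=x, y_mm=y)


def gen_dyad(kind: str = "follower", params: Optional[FollowerParams] = None,
             duration_s: float = 1200.0, fps: float = 30.0,
             dish_radius_mm: float = 50.0, bout_dur_s: float = 0.2
             ) -> tuple[Track, Track]:
    """Simulate a dyad of bout-structured swimmers; returns (partner, focal).

    ``kind='follower'`` couples the second animal to the first through the
    range-error steering rule; ``kind='independent'`` leaves both uncoupled.
    Tracks are rendered at ``fps`` with each bout executed over
    ``bout_dur_s``.  Deterministic under ``params.seed``.
    """
    if kind not in ("follower", "independent"):
        raise ValueError("kind must be 'follower' or 'independent'")
    params = params or FollowerParams()
    rng = np.random.default_rng(params.seed)
    events = _simulate_agents(kind, params, duration_s, dish_radius_mm, rng)
    a = _render_track(events[0], duration_s, fps, bout_dur_s)
    b = _render_track(events[1], duration_s, fps, bout_dur_s)
    return a, b


# ---------------------------------------------------------------------------
# calcium traces


@dataclass
class NeuronSimParams:
    """Population parameters for synthetic frequency-tuned calcium traces."""

    n_neurons: int = 1000
    selective_fraction: float = 0.15
    responder_fraction: float = 0.5      # of non-selective neurons: flat responders
    tuning_center_hz: float = 1.2
    tuning_width_oct: float = 1.0        # log2-frequency Gaussian width
    response_amplitude: float = 1.0      # plateau dF/F of a fully driven neuron
    kernel_tau_s: float = 7.0
    acquisition_hz: float = 5.0
    downsample: int = 5
    noise_sd: float = 0.25               # dF/F noise SD as a fraction of amplitude
    baseline_f: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_tau_s <= 0 or self.acquisition_hz <= 0:
            raise ValueError("kernel tau and acquisition rate must be positive")
        if not (0 <= self.selective_fraction <= 1):
            raise ValueError("selective_fraction must be in [0, 1]")


def gen_traces(params: Optional[NeuronSimParams] = None,
               schedule: Optional[pd.DataFrame] = None
               ) -> tuple[TraceSet, pd.DataFrame]:
    """Synthesize a trace population with ground-truth class labels.

    Selective neurons carry log-Gaussian frequency tuning centred at
    ``tuning_center_hz``; flat responders respond equally to every stimulus;
    silent neurons never respond.  Stimulus drive is filtered through a
    single-exponential calcium kernel (instantaneous rise, tau decay),
    Gaussian noise is added at the acquisition rate, and the traces are
    mean-downsampled to 1 volume/s.  Returns (TraceSet, truth table with
    columns cls/amplitude/center_hz).
    """
    params = params or NeuronSimParams()
    schedule = schedule if schedule is not None else make_schedule(seed=params.seed)
    freqs = schedule["freq_hz"].to_numpy() if "freq_hz" in schedule.columns else None
    if freqs is None:
        raise ValueError("schedule must carry a freq_hz column")
    needed = {0.75, 1.5, 3.0, 6.0, 60.0}
    if not needed.issubset(set(np.round(freqs, 6))):
        raise ValueError("schedule must cover all five standard frequencies")
    rng = np.random.default_rng(params.seed)
    n = params.n_neurons
    n_sel = int(round(params.selective_fraction * n))
    n_flat = int(round(params.responder_fraction * (n - n_sel)))
    cls = np.array(["selective"] * n_sel + ["flat"] * n_flat
                   + ["silent"] * (n - n_sel - n_flat))
    rng.shuffle(cls)
    amp = params.response_amplitude * rng.uniform(0.7, 1.3, n)
    amp[cls == "silent"] = 0.0

    def weight(f_hz: np.ndarray) -> np.ndarray:
        z = (np.log2(f_hz) - np.log2(params.tuning_center_hz)) / params.tuning_width_oct
        return np.exp(-0.5 * z**2)

    rate = params.acquisition_hz
    t_end = float((schedule["onset_s"] + schedule["duration_s"]).max()) + 20.0
    n_t = int(round(t_end * rate))
    drive = np.zeros((n, n_t))
    w_sel = weight(freqs)                                  # per presentation
    for j, row in schedule.reset_index(drop=True).iterrows():
        i0 = int(round(row["onset_s"] * rate))
        i1 = int(round((row["onset_s"] + row["duration_s"]) * rate))
        w = np.where(cls == "selective", w_sel[j], 1.0)
        drive[:, i0:i1] = (amp * w)[:, None]
    # single-exponential calcium kernel: c[t] = a*c[t-1] + (1-a)*drive[t]
    a = math.exp(-1.0 / (rate * params.kernel_tau_s))
    c = np.zeros_like(drive)
    for k in range(1, n_t):
        c[:, k] = a * c[:, k - 1] + (1 - a) * drive[:, k]
    f0 = rng.uniform(0.5, 1.5, n)[:, None] * params.baseline_f
    noise = rng.normal(0.0, params.noise_sd * params.response_amplitude, (n, n_t))
    f = f0 * (1.0 + c + noise)
    traces = TraceSet(np.clip(f, 0.0, None), rate).downsample(params.downsample)
    truth = pd.DataFrame({"cls": cls, "amplitude": amp,
                          "center_hz": params.tuning_center_hz})
    return traces, truth


# ---------------------------------------------------------------------------
# cell coordinates


def gen_cell_points(centers_um: Sequence[Sequence[float]],
                    counts: Sequence[int], spread_um: float = 15.0,
                    seed: int = 0) -> CellPoints:
    """Gaussian point clouds around the given 3-D centres (µm)."""
    if len(centers_um) != len(counts):
        raise ValueError("centers and counts must have equal length")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, (c, k) in enumerate(zip(centers_um, counts)):
        c = np.asarray(c, dtype=float)
        if k > 0:
            pts.append(c + rng.normal(0.0, spread_um, (k, 3)))
            labels.extend([f"cluster{i}"] * k)
    xyz = np.vstack(pts) if pts else np.empty((0, 3))
    return CellPoints(xyz, np.array(labels) if labels else None)


# ---------------------------------------------------------------------------
# two-channel volumes


def _standardized(rng: np.random.Generator, n: int) -> np.ndarray:
    """Gaussian deviates standardized to sample mean 0, sample SD 1."""
    e = rng.normal(0.0, 1.0, n)
    return (e - e.mean()) / e.std(ddof=1)


def gen_cfos_volumes(masks: Mapping[str, np.ndarray],
                     effects: Mapping[str, float] | Mapping[str, Mapping[str, float]],
                     n_per_condition: int = 8,
                     conditions: Sequence[str] = ("no-stimulus", "continuous",
                                                  "bout-like", "conspecific"),
                     spacing_um: float = 10.0, atten_lambda_um: float = 150.0,
                     between_sd: float = 0.15, voxel_noise_sd: float = 0.02,
                     base_intensity: float = 100.0, seed: int = 0
                     ) -> list[VolumePair]:
    """Two-channel volumes with planted per-cluster effect sizes.

    The reference channel is a smooth base field times an exponential depth
    attenuation exp(-z/lambda) and a per-animal global gain; the activity
    channel multiplies the reference by a cluster/condition factor
    1 + between_sd * (d + eps), with the per-animal deviates eps
    standardized within each group so the planted Cohen's d is realized
    in-sample at the given group size.  ``effects`` maps cluster name to a
    single d (applied to every non-baseline condition) or to a
    {condition: d} mapping; the first condition is the baseline (d = 0).
    """
    names = list(masks)
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("all cluster masks must share one grid")
    shape = shapes.pop()
    stacked = np.stack([np.asarray(masks[nm], dtype=bool) for nm in names])
    if np.any(stacked.sum(axis=0) > 1):
        raise ValueError("cluster masks must be disjoint")
    rng = np.random.default_rng(seed)
    baseline = conditions[0]

    def d_of(cluster: str, cond: str) -> float:
        if cond == baseline:
            return 0.0
        e = effects.get(cluster, 0.0)
        return float(e.get(cond, 0.0)) if isinstance(e, Mapping) else float(e)

    ix, iy, iz = np.indices(shape)
    base = base_intensity * (1.0 + 0.2 * np.sin(2 * math.pi * ix / shape[0])
                             * np.cos(2 * math.pi * iy / shape[1]))
    atten = np.exp(-(iz * spacing_um) / atten_lambda_um)
    smooth_ref = base * atten

    # per-group standardized between-animal deviates, per cluster
    eps = {(nm, cond): _standardized(rng, n_per_condition)
           for nm in names for cond in conditions}
    pairs: list[VolumePair] = []
    for cond in conditions:
        for i in range(n_per_condition):
            gain = float(np.exp(rng.normal(0.0, 0.1)))
            factor = np.ones(shape)
            for nm in names:
                f = 1.0 + between_sd * (d_of(nm, cond) + eps[(nm, cond)][i])
                factor[np.asarray(masks[nm], dtype=bool)] = f
            ref = smooth_ref * gain * (1.0 + rng.normal(0.0, voxel_noise_sd, shape))
            act = smooth_ref * gain * factor * (1.0 + rng.normal(0.0, voxel_noise_sd, shape))
            pairs.append(VolumePair(np.clip(act, 0.0, None), np.clip(ref, 0.0, None),
                                    animal_id=f"{cond}-{i}", condition=cond))
    return pairs
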