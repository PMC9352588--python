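"""From ROI fluorescence traces to bout-preference classification.

Volumetric two-photon recordings yield one fluorescence trace per
segmented neuron (ROI), sampled at 1 volume/s after fivefold temporal
downsampling.  Stimuli (dots at bout frequencies 0.75-60 Hz) are
presented for 22.6 s each, separated by >= 20 s breaks.

The pipeline: epoch each trace around stimulus onsets and convert to
dF/F against a 5 s pre-onset baseline; average across presentations of
the same stimulus and then over the stimulus window to get one mean
dF/F per ROI and stimulus; optionally keep only strongly responsive
ROIs (per-stimulus percentile filter); and contrast bout-like
(0.75-3 Hz) against continuous (6-60 Hz) categories with the bout
preference index

    BPI = (mean dF/F bout - mean dF/F continuous)
          / (mean dF/F bout + mean dF/F continuous)

Neurons with BPI > 0.5 (a threefold stronger bout response) are bout
preference neurons (BPNs).  Tuning peaks along a stimulus variable are
located with a second-degree interpolating spline; frequency axes are
interpolated in log2 space since the supports span 0.75-60 Hz.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline

__all__ = [
    "TraceSet",
    "make_schedule",
    "EpochedDFF",
    "epoch_dff",
    "mean_responses",
    "responsive_filter",
    "bout_preference_index",
    "classify_bpns",
    "tuning_peak",
]


@dataclass
class TraceSet:
    """ROI x time fluorescence matrix at a stated sampling rate."""

    traces: np.ndarray           # (n_roi, n_t), raw fluorescence
    rate_hz: float
    coords_um: Optional[np.ndarray] = None   # (n_roi, 3) anatomical coordinates

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D ROI x time matrix")
        if np.any(self.traces < 0):
            raise ValueError("raw fluorescence must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def n_roi(self) -> int:
        return self.traces.shape[0]

    def downsample(self, factor: int = 5) -> "TraceSet":
        """Mean-downsample in time (e.g. 5 volumes/s -> 1 volume/s)."""
        n = (self.traces.shape[1] // factor) * factor
        tr = self.traces[:, :n].reshape(self.n_roi, -1, factor).mean(axis=2)
        return TraceSet(tr, self.rate_hz / factor, self.coords_um)


def make_schedule(freqs_hz: Sequence[float] = (0.75, 1.5, 3.0, 6.0, 60.0),
                  n_reps: int = 4, duration_s: float = 22.6, gap_s: float = 20.0,
                  lead_in_s: float = 30.0, seed: Optional[int] = None) -> pd.DataFrame:
    """Build a stimulus schedule: onset_s, duration_s, label, freq_hz.

    Presentations are separated by ``gap_s`` (>= the 5 s baseline window);
    order is shuffled per repetition block when a seed is given, mirroring
    the random draw of frequency at each stimulus instance.
    """
    if gap_s < 5.0:
        raise ValueError("gap must leave at least a 5 s baseline before each onset")
    rng = np.random.default_rng(seed) if seed is not None else None
    rows = []
    t = lead_in_s
    for _ in range(n_reps):
        order = list(freqs_hz)
        if rng is not None:
            order = [order[i] for i in rng.permutation(len(order))]
        for f in order:
            rows.append({"onset_s": round(t, 3), "duration_s": duration_s,
                         "label": f"dot_{f:g}Hz", "freq_hz": float(f)})
            t += duration_s + gap_s
    return pd.DataFrame(rows)


def _validate_schedule(schedule: pd.DataFrame) -> None:
    for col in ("onset_s", "duration_s", "label"):
        if col not in schedule.columns:
            raise ValueError(f"schedule missing required column {col!r}")
    s = schedule.sort_values("onset_s")
    ends = (s["onset_s"] + s["duration_s"]).to_numpy()[:-1]
    if np.any(s["onset_s"].to_numpy()[1:] < ends):
        raise ValueError("stimulus presentations overlap")


@dataclass
class EpochedDFF:
    """Per-presentation dF/F epochs: (n_pres, n_roi, n_t) with validity mask."""

    dff: np.ndarray              # (n_pres, n_roi, n_t)
    labels: list
    valid: np.ndarray            # (n_pres, n_roi) False where the baseline was unusable
    rate_hz: float


def epoch_dff(traces: TraceSet, schedule: pd.DataFrame, baseline_s: float = 5.0,
              f0_floor_frac: float = 0.01) -> EpochedDFF:
    """Epoch traces around stimulus onsets and convert to dF/F.

    F0 is the mean fluorescence over the ``baseline_s`` window before each
    onset.  ROI-presentations whose F0 falls below ``f0_floor_frac`` of the
    ROI's median fluorescence are flagged invalid instead of producing
    unbounded dF/F.
    """
    _validate_schedule(schedule)
    rate = traces.rate_hz
    n_base = int(round(baseline_s * rate))
    n_win = int(round(float(schedule["duration_s"].min()) * rate))
    floors = f0_floor_frac * np.median(traces.traces, axis=1)
    epochs, valid = [], []
    for _, row in schedule.iterrows():
        i_on = int(round(row["onset_s"] * rate))
        if i_on - n_base < 0 or i_on + n_win > traces.traces.shape[1]:
            raise ValueError(
                f"presentation at {row['onset_s']} s does not fit in the recording")
        f0 = traces.traces[:, i_on - n_base:i_on].mean(axis=1)
        ok = f0 > floors
        f0_safe = np.where(ok, f0, 1.0)
        win = traces.traces[:, i_on:i_on + n_win]
        epochs.append((win - f0_safe[:, None]) / f0_safe[:, None])
        valid.append(ok)
    return EpochedDFF(np.stack(epochs), list(schedule["label"]), np.stack(valid), rate)


def mean_responses(epoched: EpochedDFF) -> pd.DataFrame:
    """One mean dF/F per ROI and stimulus.

    Averages across presentations of each stimulus first (per time point,
    over valid ROI-presentations), then over the stimulus window.
    """
    labels = pd.unique(pd.Series(epoched.labels))
    n_roi = epoched.dff.shape[1]
    out = {}
    for lab in labels:
        idx = [i for i, l in enumerate(epoched.labels) if l == lab]
        d = epoched.dff[idx]                       # (n_pres_lab, n_roi, n_t)
        v = epoched.valid[idx].astype(float)       # (n_pres_lab, n_roi)
        w = v[:, :, None]
        denom = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            per_time = np.where(denom > 0, (d * w).sum(axis=0) / denom, np.nan)
        out[lab] = per_time.mean(axis=1)
    return pd.DataFrame(out, index=pd.RangeIndex(n_roi, name="roi"))


def responsive_filter(table: pd.DataFrame, percentile: float = 95.0) -> pd.Index:
    """ROIs whose mean dF/F to *any* stimulus strictly exceeds that stimulus's percentile.

    The percentile is computed per stimulus across ROIs (95 for volumetric
    juvenile data, 90 for the ablation dataset, 50 for single-plane larvae).
    """
    if percentile <= 0:
        return table.index
    cutoffs = np.nanpercentile(table.to_numpy(), percentile, axis=0)
    keep = (table.to_numpy() > cutoffs).any(axis=1)
    return table.index[keep]


def _freq_of_column(col, freq_map) -> Optional[float]:
    if freq_map is not None and col in freq_map:
        return float(freq_map[col])
    if isinstance(col, (int, float)):
        return float(col)
    m = re.search(r"(\d+(?:\.\d+)?)\s*Hz", str(col))
    return float(m.group(1)) if m else None


def bout_preference_index(table: pd.DataFrame, bout_hz: tuple = (0.75, 3.0),
                          cont_hz: tuple = (6.0, 60.0),
                          freq_map: Optional[dict] = None) -> pd.DataFrame:
    """Bout preference index per ROI from a ROI x stimulus response table.

    Stimuli are split by frequency into bout-like (0.75-3 Hz) and continuous
    (6-60 Hz) categories regardless of size or direction; BPI is the
    normalized difference of the category means.  Columns whose frequency
    cannot be determined (pass ``freq_map`` to override parsing from the
    column name) are ignored.  Returns columns: ``bout_mean``, ``cont_mean``,
    ``bpi``, ``is_bpn`` (BPI > 0.5), ``quality`` ('ok', 'undefined' for a
    zero denominator, 'out_of_range' when negative responses push BPI
    outside [-1, 1]).
    """
    bout_cols, cont_cols = [], []
    for col in table.columns:
        f = _freq_of_column(col, freq_map)
        if f is None:
            continue
        if bout_hz[0] <= f <= bout_hz[1]:
            bout_cols.append(col)
        elif cont_hz[0] <= f <= cont_hz[1]:
            cont_cols.append(col)
    if not bout_cols or not cont_cols:
        raise ValueError("need at least one bout-like and one continuous stimulus column")
    b = table[bout_cols].mean(axis=1)
    c = table[cont_cols].mean(axis=1)
    denom = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        bpi = (b - c) / denom
    quality = pd.Series("ok", index=table.index)
    quality[denom == 0] = "undefined"
    bpi[denom == 0] = np.nan
    out_of_range = (np.abs(bpi) > 1.0) & quality.eq("ok")
    quality[out_of_range] = "out_of_range"
    # the quality flag is informational: negative responses may push BPI
    # outside [-1, 1], but BPN status remains BPI > 0.5
    return pd.DataFrame({
        "bout_mean": b, "cont_mean": c, "bpi": bpi,
        "is_bpn": (bpi > 0.5) & quality.ne("undefined"),
        "quality": quality,
    })


def classify_bpns(table: pd.DataFrame, bpi_threshold: float = 0.5,
                  min_total_dff: float = 0.1, **kwargs) -> pd.DataFrame:
    """BPN classification with a response floor.

    An ROI is a BPN when BPI > ``bpi_threshold`` *and* its total category
    response (bout_mean + cont_mean) exceeds ``min_total_dff``; ROIs below
    the floor have no measurable response, so a BPI computed from their
    noise is meaningless (quality code 'below_floor').
    """
    res = bout_preference_index(table, **kwargs)
    below = (res["bout_mean"] + res["cont_mean"]) < min_total_dff
    res.loc[below & ~res["quality"].eq("undefined"), "quality"] = "below_floor"
    res["is_bpn"] = ((res["bpi"] > bpi_threshold)
                     & ~res["quality"].isin(["undefined", "below_floor"]))
    return res


def tuning_peak(x_values, responses, axis: str = "linear",
                n_grid: int = 4001) -> float:
    """Location of the response maximum along a stimulus variable.

    Interpolates the (x, response) support points with a second-degree
    spline and returns the argmax of the interpolant over the support
    interval (boundaries allowed).  With ``axis='log2'`` the spline is fit
    in log2(x) — appropriate for frequency grids spanning 0.75-60 Hz —
    and the peak is returned on the original scale.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and responses must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 support points for a degree-2 spline")
    if len(np.unique(x)) != len(x):
        raise ValueError("duplicate x values are not allowed")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if axis == "log2":
        if np.any(x <= 0):
            raise ValueError("log2 axis requires positive x values")
        tx = np.log2(x)
    elif axis == "linear":
        tx = x
    else:
        raise ValueError("axis must be 'linear' or 'log2'")
    spline = InterpolatedUnivariateSpline(tx, y, k=2)
    grid = np.linspace(tx[0], tx[-1], n_grid)
    peak_tx = grid[int(np.argmax(spline(grid)))]
    return float(2.0 ** peak_tx) if axis == "log2" else float(peak_tx)
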