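"""Behavioral scoring: activity, freezing, fear-conditioning summaries
and open-field locomotion metrics.

Activity is the fraction of pixels changed between consecutive video
frames (or is taken directly from a tracking-software export).
Freezing — the absence of all movement except breathing — is scored as
maximal runs of sub-threshold activity lasting at least a minimum bout
duration.  Cued fear conditioning on day 2 is summarized over two
60 s bins straddling the tone onset at 150 s: 90–150 s (pre-tone) and
150–210 s (tone).  Open-field videos are scored for clockwise /
counterclockwise rotations (full ±360° turns of the center→nose
vector), distance traveled, and cumulative time in the central
0.4 m² zone, over the 300–900 s analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorTrace",
    "FreezeBout",
    "FCResult",
    "OpenFieldResult",
    "compute_activity",
    "detect_freezing",
    "fc_summary",
    "open_field",
]

#: default freezing-detection parameters (config-exposed; tracking
#: software thresholds are typically tuned per rig)
DEFAULT_THETA = 0.01
DEFAULT_MIN_DURATION_S = 1.0


@dataclass
class BehaviorTrace:
    """Per-frame tracking trace with protocol annotations.

    ``data`` columns: frame, time_s, activity, and optionally
    cx, cy, nx, ny (center and nose points, metres).
    ``annotations``: e.g. {"tone_on_s": 150.0, "tone_off_s": 300.0}.
    """

    data: pd.DataFrame
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.data["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        act = self.data["activity"].to_numpy(dtype=float)
        if np.any((act < 0) | (act > 1)):
            raise ValueError("activity must lie in [0, 1]")

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    @property
    def activity(self) -> np.ndarray:
        return self.data["activity"].to_numpy(dtype=float)


@dataclass(frozen=True)
class FreezeBout:
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FCResult:
    pre_mean_activity: float
    post_mean_activity: float
    pre_freezing_s: float
    post_freezing_s: float
    pre_bin: tuple = (90.0, 150.0)
    post_bin: tuple = (150.0, 210.0)


@dataclass(frozen=True)
class OpenFieldResult:
    cw_rotations: int | None       # None when the nose track is missing
    ccw_rotations: int | None
    distance_cm: float
    center_duration_s: float
    window_s: tuple = (300.0, 900.0)


def compute_activity(frames, pixel_delta_threshold: float) -> np.ndarray:
    """Fraction of pixels changed frame-to-frame.

    ``frames`` is a (T, H, W) array; activity[0] = 0 by convention.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need >= 2 frames of constant shape")
    diff = np.abs(np.diff(frames.astype(float), axis=0))
    changed = (diff > pixel_delta_threshold).mean(axis=(1, 2))
    return np.concatenate([[0.0], changed])


def detect_freezing(activity, time_s, theta: float = DEFAULT_THETA,
                    min_duration_s: float = DEFAULT_MIN_DURATION_S,
                    bins=None):
    """Freezing bouts: maximal sub-threshold runs of at least ``min_duration_s``.

    A frame at time t covers [t, t + dt); a run's duration is from its
    first frame to just after its last.  Returns (bouts, per-bin
    cumulative freezing dict) — bins are (start, end) tuples and bouts
    crossing a boundary contribute their overlap to each bin.
    """
    activity = np.asarray(activity, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if activity.size == 0 or activity.shape != time_s.shape:
        raise ValueError("activity and time must be non-empty and aligned")
    if theta <= 0 or min_duration_s <= 0:
        raise ValueError("theta and min_duration must be positive")

    dt = float(np.median(np.diff(time_s))) if time_s.size > 1 else 0.0
    sub = activity < theta
    bouts = []
    i = 0
    n = sub.size
    while i < n:
        if sub[i]:
            j = i
            while j + 1 < n and sub[j + 1]:
                j += 1
            start = time_s[i]
            end = time_s[j] + dt
            if end - start >= min_duration_s:
                bouts.append(FreezeBout(start_s=float(start), end_s=float(end)))
            i = j + 1
        else:
            i += 1

    per_bin = {}
    if bins is not None:
        for b in bins:
            lo, hi = float(b[0]), float(b[1])
            per_bin[(lo, hi)] = float(
                sum(max(0.0, min(hi, bt.end_s) - max(lo, bt.start_s)) for bt in bouts)
            )
    return bouts, per_bin


def fc_summary(trace: BehaviorTrace, theta: float = DEFAULT_THETA,
               min_duration_s: float = DEFAULT_MIN_DURATION_S) -> FCResult:
    """Day-2 fear-conditioning summary over the pre-tone and tone bins.

    Bin edges are anchored at the annotated tone onset (150 s in the
    standard protocol): pre = [onset−60, onset), post = [onset, onset+60).
    """
    if "tone_on_s" not in trace.annotations:
        raise ValueError("trace lacks a tone_on_s protocol annotation")
    onset = float(trace.annotations["tone_on_s"])
    pre = (onset - 60.0, onset)
    post = (onset, onset + 60.0)
    t = trace.time_s
    if t[0] > pre[0] or t[-1] < post[1] - 1.0:
        raise ValueError("trace does not cover the 90–210 s analysis span")

    act = trace.activity
    pre_m = float(act[(t >= pre[0]) & (t < pre[1])].mean())
    post_m = float(act[(t >= post[0]) & (t < post[1])].mean())
    _, per_bin = detect_freezing(act, t, theta=theta, min_duration_s=min_duration_s,
                                 bins=[pre, post])
    return FCResult(
        pre_mean_activity=pre_m, post_mean_activity=post_m,
        pre_freezing_s=min(per_bin[pre], 60.0),
        post_freezing_s=min(per_bin[post], 60.0),
        pre_bin=pre, post_bin=post,
    )


def _count_rotations(angles: np.ndarray):
    """Full-turn counting with reset-on-reversal semantics.

    Signed angle increments of the center→nose vector are accumulated;
    every time the accumulator passes ±2π one CW/CCW rotation is counted
    and the accumulator is reset.  A direction reversal discards the
    partial rotation accumulated so far.
    """
    d = np.diff(angles)
    # unwrap single-step jumps across ±π
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    cw = ccw = 0
    acc = 0.0
    full = 2.0 * np.pi - 1e-6  # tolerate float error at an exact full turn
    for step in d:
        if step == 0.0:
            continue
        if acc != 0.0 and np.sign(step) != np.sign(acc):
            acc = 0.0
        acc += step
        if acc >= full:
            ccw += 1
            acc -= 2.0 * np.pi
        elif acc <= -full:
            cw += 1
            acc += 2.0 * np.pi
    return cw, ccw


def open_field(trace: BehaviorTrace, arena_side_m: float = 1.581,
               center_area_m2: float = 0.4, window_s=(300.0, 900.0)) -> OpenFieldResult:
    """Rotations, distance traveled and center-zone time.

    The arena is a square of side ``arena_side_m`` (2.5 m² by default);
    the center zone is the concentric square of area ``center_area_m2``.
    Rotations need the nose track; distance and center time only need
    the center-point track.
    """
    df = trace.data
    t = trace.time_s
    sel = (t >= window_s[0]) & (t <= window_s[1])
    if not sel.any():
        raise ValueError("trace does not cover the analysis window")
    if not {"cx", "cy"}.issubset(df.columns):
        raise ValueError("center-point track (cx, cy) required")

    cx = df["cx"].to_numpy(dtype=float)[sel]
    cy = df["cy"].to_numpy(dtype=float)[sel]
    tw = t[sel]

    steps = np.hypot(np.diff(cx), np.diff(cy))
    distance_cm = float(steps.sum() * 100.0)

    half = np.sqrt(center_area_m2) / 2.0
    c0 = arena_side_m / 2.0
    inside = (np.abs(cx - c0) <= half) & (np.abs(cy - c0) <= half)
    # each frame covers the interval up to the next frame; the last frame
    # contributes nothing, so a full-window stay scores exactly the window
    dt = np.diff(tw, append=tw[-1])
    center_duration_s = float(dt[inside].sum())

    if {"nx", "ny"}.issubset(df.columns) and not df["nx"].isna().all():
        nx = df["nx"].to_numpy(dtype=float)[sel]
        ny = df["ny"].to_numpy(dtype=float)[sel]
        angles = np.arctan2(ny - cy, nx - cx)
        cw, ccw = _count_rotations(angles)
    else:
        cw = ccw = None
    return OpenFieldResult(
        cw_rotations=cw, ccw_rotations=ccw, distance_cm=distance_cm,
        center_duration_s=center_duration_s, window_s=tuple(window_s),
    )
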