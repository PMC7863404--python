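"""ABR and DPOAE feature extraction.

ABR: averaged scalp-potential traces are recorded per stimulus
frequency over an ascending intensity grid (10–90 dB SPL in 5 dB
steps).  A response is "detected" when the peak-to-peak amplitude in a
post-onset response window exceeds ``k`` times the baseline standard
deviation (k = 4 by default) — an objective stand-in for the visual
"reproducible waveform" judgment.  The threshold is the lowest
intensity detected at which every higher intensity is also detected
(monotone enforcement suppresses isolated false positives).  If nothing
is detected the threshold is censored and encoded as grid max + step
with an explicit flag.

P1 is the first local maximum after stimulus onset within a search
window; N1 the first local minimum after P1; P1 latency is measured
from onset, and the P1−N1 amplitude is their voltage difference.

DPOAE: for primaries f1 < f2 at ratio f2/f1, the cubic distortion
product sits at 2·f1 − f2.  Its amplitude is read at the nearest
spectral bin; the noise floor is the mean of flanking bins (skipping
guard bins and primary-tone bins); the emission is "detected" when the
DP amplitude exceeds the noise floor by a criterion (default 6 dB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ABRTrace",
    "ABRSeries",
    "ABRFeatures",
    "ThresholdResult",
    "DPOAESpectrum",
    "DPResult",
    "detect_response",
    "abr_threshold",
    "abr_features",
    "dp_extract",
    "dpoae_threshold",
]


@dataclass(frozen=True)
class ABRTrace:
    """One averaged ABR trace: uniform time grid (ms), voltage (µV)."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    frequency: float | str          # kHz, or "click"
    intensity_db: float
    onset_ms: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        v = np.asarray(self.voltage_uv, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 4:
            raise ValueError("time and voltage must be equal-length 1-D arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        if not (t[0] <= self.onset_ms <= t[-1]):
            raise ValueError("stimulus onset outside the record")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "voltage_uv", v)


@dataclass
class ABRSeries:
    """Traces over a uniform intensity grid for one stimulus frequency."""

    frequency: float | str
    traces: dict = field(default_factory=dict)   # intensity -> ABRTrace

    @property
    def intensities(self) -> np.ndarray:
        return np.array(sorted(self.traces), dtype=float)

    def validate_grid(self):
        grid = self.intensities
        if grid.size < 2:
            raise ValueError("need at least two intensities")
        step = np.diff(grid)
        if not np.allclose(step, step[0]):
            raise ValueError("intensity grid must be uniform (missing intensities?)")
        return grid, float(step[0])


@dataclass(frozen=True)
class ABRFeatures:
    detected: bool
    p1_latency_ms: float | None = None
    p1_amplitude_uv: float | None = None
    n1_amplitude_uv: float | None = None
    p1n1_delta_uv: float | None = None


@dataclass(frozen=True)
class ThresholdResult:
    threshold_db: float
    censored: bool


def _window_slice(t: np.ndarray, window) -> np.ndarray:
    """Half-open window [lo, hi), so adjacent windows are disjoint."""
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must have positive length")
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("window outside the record")
    sel = (t >= lo) & (t < hi)
    if hi >= t[-1] - 1e-12:  # window reaching the record end includes it
        sel |= np.isclose(t, hi)
    return sel


def detect_response(trace: ABRTrace, baseline_window, response_window, k: float = 4.0) -> bool:
    """Peak-to-peak in the response window > k × SD of the baseline."""
    t = trace.time_ms
    bi = _window_slice(t, baseline_window)
    ri = _window_slice(t, response_window)
    if np.any(bi & ri):
        raise ValueError("baseline and response windows must be disjoint")
    base_sd = float(np.std(trace.voltage_uv[bi]))
    ptp = float(np.ptp(trace.voltage_uv[ri]))
    return ptp > k * base_sd


#: default response window relative to stimulus onset (ms), matched to
#: the P1/N1 complex so baseline noise peaks elsewhere cannot trigger
RESPONSE_WINDOW_MS = (0.5, 3.0)


def abr_threshold(series: ABRSeries, baseline_window=None, response_window=None,
                  k: float = 4.0) -> ThresholdResult:
    """Lowest intensity detected with all higher intensities also detected.

    Default windows: baseline is the whole pre-stimulus segment,
    response is onset + 0.5 to onset + 3 ms (the P1/N1 region).  A
    series with no such intensity is censored and encoded as grid max
    + step.
    """
    grid, step = series.validate_grid()
    r0, r1 = RESPONSE_WINDOW_MS
    detected = []
    for inten in grid:
        tr = series.traces[inten]
        bw = baseline_window or (tr.time_ms[0], tr.onset_ms)
        rw = response_window or (tr.onset_ms + r0,
                                 min(tr.onset_ms + r1, tr.time_ms[-1]))
        detected.append(detect_response(tr, bw, rw, k=k))
    detected = np.asarray(detected)
    # monotone enforcement: threshold = lowest I with detection at I and
    # every intensity above it
    ok = np.flip(np.cumprod(np.flip(detected.astype(int)))).astype(bool)
    if not ok.any():
        return ThresholdResult(threshold_db=float(grid[-1] + step), censored=True)
    return ThresholdResult(threshold_db=float(grid[ok][0]), censored=False)


def abr_features(trace: ABRTrace, search_window=None) -> ABRFeatures:
    """P1 (first local max after onset), N1 (first local min after P1)."""
    t = trace.time_ms
    v = trace.voltage_uv
    if search_window is None:
        search_window = (trace.onset_ms, min(trace.onset_ms + 6.0, t[-1]))
    sl = _window_slice(t, search_window) & (t > trace.onset_ms)
    idx = np.flatnonzero(sl)
    if idx.size < 3:
        return ABRFeatures(detected=False)

    def first_local_max(indices):
        for i in indices:
            if 0 < i < t.size - 1 and v[i] > v[i - 1] and v[i] >= v[i + 1]:
                return i
        return None

    def first_local_min(indices):
        for i in indices:
            if 0 < i < t.size - 1 and v[i] < v[i - 1] and v[i] <= v[i + 1]:
                return i
        return None

    ip1 = first_local_max(idx)
    if ip1 is None:
        return ABRFeatures(detected=False)
    in1 = first_local_min(np.arange(ip1 + 1, t.size - 1))
    if in1 is None:
        return ABRFeatures(detected=False)
    return ABRFeatures(
        detected=True,
        p1_latency_ms=float(t[ip1] - trace.onset_ms),
        p1_amplitude_uv=float(v[ip1]),
        n1_amplitude_uv=float(v[in1]),
        p1n1_delta_uv=float(v[ip1] - v[in1]),
    )


@dataclass(frozen=True)
class DPOAESpectrum:
    """Averaged ear-canal spectrum for one primary-pair presentation."""

    frequency_hz: np.ndarray
    amplitude_db: np.ndarray
    f1_hz: float
    f2_hz: float
    level_db: float

    def __post_init__(self):
        f = np.asarray(self.frequency_hz, dtype=float)
        a = np.asarray(self.amplitude_db, dtype=float)
        if f.shape != a.shape or f.ndim != 1:
            raise ValueError("frequency and amplitude must match")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency bins must be ascending")
        if self.f1_hz >= self.f2_hz:
            raise ValueError("f1 must be below f2")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "amplitude_db", a)

    @property
    def dp_frequency_hz(self) -> float:
        return 2.0 * self.f1_hz - self.f2_hz


@dataclass(frozen=True)
class DPResult:
    dp_frequency_hz: float
    dp_amplitude_db: float
    noise_floor_db: float
    detected: bool
    level_db: float


def dp_extract(spectrum: DPOAESpectrum, noise_bins: int = 5, guard_bins: int = 2,
               criterion_db: float = 6.0) -> DPResult:
    """Read the 2f1−f2 amplitude and the flanking noise floor."""
    f = spectrum.frequency_hz
    a = spectrum.amplitude_db
    fdp = spectrum.dp_frequency_hz
    if fdp < f[0] or fdp > f[-1]:
        raise ValueError("distortion-product frequency outside the spectrum")
    idp = int(np.argmin(np.abs(f - fdp)))
    i1 = int(np.argmin(np.abs(f - spectrum.f1_hz)))
    i2 = int(np.argmin(np.abs(f - spectrum.f2_hz)))
    if idp in (i1, i2):
        raise ValueError("DP bin collides with a primary-tone bin")

    excluded = set()
    for ic in (i1, i2):
        excluded.update(range(ic - guard_bins, ic + guard_bins + 1))

    noise_idx = []
    for direction in (-1, +1):
        j = idp + direction * (guard_bins + 1)
        while 0 <= j < f.size and len([x for x in noise_idx if (x - idp) * direction > 0]) < noise_bins:
            if j not in excluded:
                noise_idx.append(j)
            j += direction
    if not noise_idx:
        raise ValueError("no noise bins available around the DP bin")
    noise = float(np.mean(a[noise_idx]))
    dp = float(a[idp])
    return DPResult(
        dp_frequency_hz=float(f[idp]), dp_amplitude_db=dp, noise_floor_db=noise,
        detected=dp >= noise + criterion_db, level_db=spectrum.level_db,
    )


def dpoae_threshold(results) -> ThresholdResult:
    """Lowest stimulus level detected with all higher levels detected."""
    results = sorted(results, key=lambda r: r.level_db)
    if not results:
        raise ValueError("empty level list")
    levels = np.array([r.level_db for r in results])
    if levels.size >= 2:
        step = float(np.diff(levels)[0])
    else:
        step = 5.0
    detected = np.array([r.detected for r in results])
    ok = np.flip(np.cumprod(np.flip(detected.astype(int)))).astype(bool)
    if not ok.any():
        return ThresholdResult(threshold_db=float(levels[-1] + step), censored=True)
    return ThresholdResult(threshold_db=float(levels[ok][0]), censored=False)
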