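"""Synthetic raw-data generators with known ground truth.

Every downstream stage (segmentation, morphometry, cochleograms,
ABR/DPOAE feature extraction, behavior scoring) is exercised against
data from these generators, which emulate the study's raw inputs:

* ``gen_cochlea_stack`` — a 4-channel confocal-like stack (DAPI,
  MYO7A, GFP, FLAG) of one IHC row and three OHC rows of ellipsoidal
  cells along a cochlear axis, with genotype-dependent apical
  mispositioning of OHC nuclei, a position-dependent OHC survival
  gradient, per-cell GFP transduction intensities, and a FLAG shell at
  the nuclear envelope of transduced cells.
* ``gen_abr_series`` — averaged ABR traces over the 10–90 dB SPL grid
  with a programmed true threshold, intensity-dependent P1/N1 latency
  and amplitude, and band-limited noise whose averaged SD scales as
  1/√n_sweeps.
* ``gen_dpoae_levels`` — ear-canal spectra with primaries f1 = f2/1.2
  and f2, and a 2f1−f2 distortion product emerging from the noise floor
  above a programmed threshold.
* ``gen_behavior_trace`` — day-2 fear-conditioning activity traces with
  programmed freeze bouts (tone-locked for a hearing phenotype,
  tone-independent for a deaf one) plus center/nose tracking.

All generators draw from a single seeded ``numpy.random.Generator`` per
call; identical seed and parameters give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .audiology import ABRSeries, ABRTrace, DPOAESpectrum
from .behavior import BehaviorTrace, FreezeBout
from .cochleomap import CochleaPolyline
from .imaging import ImageStack

__all__ = [
    "CochleaSimParams",
    "ABRSimParams",
    "FCProtocol",
    "study_params",
    "gen_cochlea_stack",
    "gen_abr_series",
    "gen_dpoae_levels",
    "gen_behavior_trace",
]


# ---------------------------------------------------------------------------
# cochlear stacks

@dataclass(frozen=True)
class CochleaSimParams:
    """Parameters of the synthetic organ-of-Corti stack.

    ``nucleus_offset_effect_um`` is the mean apical shift of OHC nuclei
    (reduction of the nucleus-to-cuticular-plate arc distance) produced
    by the knockout; ``survival_base``/``survival_slope`` set the
    per-position OHC survival probability
    p(s) = clip(base + slope·s/L, 0, 1) — the default knockout gradient
    loses more cells toward the base, matching high-frequency-first
    hearing loss.
    """

    n_cells_per_row: int = 20
    row_spacing_um: float = 8.0
    cell_spacing_um: float = 10.0
    axis_length_um: float | None = None
    genotype: str = "WT"                    # WT | KO | KO_treated
    nucleus_offset_effect_um: float = 0.0
    offset_jitter_um: float = 0.3
    survival_base: float = 1.0
    survival_slope: float = 0.0
    transduced_fraction: float = 0.0
    gfp_mu_on: float = 60.0
    gfp_sigma_on: float = 10.0
    gfp_mu_off: float = 8.0
    gfp_sigma_off: float = 3.0
    noise_sd: float = 5.0
    voxel_size_um: tuple = (0.4, 0.4, 0.5)  # (dx, dy, dz)
    seed: int = 0
    # cell geometry
    cell_length_um: float = 15.0            # apical-to-basal chord
    cell_radius_um: float = 3.0
    nucleus_radius_um: float = 2.2
    bow_um: float = 1.0                     # sagitta of the cell's arc
    wt_nucleus_distance_um: float = 10.0    # WT arc distance from apical

    def __post_init__(self):
        if self.n_cells_per_row < 1:
            raise ValueError("need at least one cell per row")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel size must be strictly positive")
        for p in (self.transduced_fraction, self.survival_base):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.genotype not in ("WT", "KO", "KO_treated"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.gfp_mu_on <= self.gfp_mu_off:
            raise ValueError("gfp_mu_on must exceed gfp_mu_off")
        if self.nucleus_offset_effect_um >= self.wt_nucleus_distance_um:
            raise ValueError("nuclear shift exceeds the available cell length")
        if self.axis_length_um is not None and (
            self.axis_length_um < self.n_cells_per_row * self.cell_spacing_um
        ):
            raise ValueError("axis too short for the requested cells")

    @property
    def axis_length(self) -> float:
        return self.axis_length_um or self.n_cells_per_row * self.cell_spacing_um


def study_params(genotype: str, seed: int = 0, **overrides) -> CochleaSimParams:
    """Study-condition presets per genotype.

    WT: no nuclear shift, full survival, no transduction.
    KO: 3 µm apical OHC nuclear shift and a base-ward survival gradient.
    KO_treated: transduced cells (90%) keep WT nuclear position and
    survive; untransduced cells behave as KO.
    """
    presets = {
        "WT": dict(nucleus_offset_effect_um=0.0, survival_base=1.0,
                   survival_slope=0.0, transduced_fraction=0.0),
        "KO": dict(nucleus_offset_effect_um=3.0, survival_base=0.8,
                   survival_slope=-0.6, transduced_fraction=0.0),
        "KO_treated": dict(nucleus_offset_effect_um=3.0, survival_base=0.98,
                           survival_slope=0.0, transduced_fraction=0.9),
    }
    if genotype not in presets:
        raise ValueError(f"unknown genotype {genotype!r}")
    kw = dict(presets[genotype])
    kw.update(overrides)
    return CochleaSimParams(genotype=genotype, seed=seed, **kw)


def _cell_arc(apical: np.ndarray, chord: float, sagitta: float):
    """Circular cell arc in the (y, z) plane below the apical point.

    Returns (center, radius, angle_at_A, total_arc_angle); the arc bows
    toward +y and runs from the apical point down to the basal point at
    apical − (0, 0, chord).
    """
    R = (sagitta**2 + (chord / 2.0) ** 2) / (2.0 * sagitta)
    mid = apical + np.array([0.0, 0.0, -chord / 2.0])
    center = mid + np.array([0.0, sagitta - R, 0.0])
    angle_a = np.arctan2(chord / 2.0, R - sagitta)
    return center, R, angle_a, 2.0 * angle_a


def _arc_point(center, R, angle_a, arc_dist):
    """Point at arc length ``arc_dist`` from the apical end."""
    ang = angle_a - arc_dist / R
    return center + R * np.array([0.0, np.cos(ang), np.sin(ang)])


def _add_ball(img, stack_vs, center_um, radius_um, amplitude, edge_um=0.6,
              rim=0.0, rim_sigma_um=0.3):
    """Add a soft-edged ball (optionally with a bright rim) to ``img``."""
    dx, dy, dz = stack_vs
    nz, ny, nx = img.shape
    cx, cy, cz = center_um
    r = radius_um + edge_um + 3 * rim_sigma_um
    z0, z1 = max(int((cz - r) / dz), 0), min(int((cz + r) / dz) + 2, nz)
    y0, y1 = max(int((cy - r) / dy), 0), min(int((cy + r) / dy) + 2, ny)
    x0, x1 = max(int((cx - r) / dx), 0), min(int((cx + r) / dx) + 2, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = np.arange(z0, z1) * dz - cz
    yy = np.arange(y0, y1) * dy - cy
    xx = np.arange(x0, x1) * dx - cx
    dist = np.sqrt(zz[:, None, None] ** 2 + yy[None, :, None] ** 2
                   + xx[None, None, :] ** 2)
    body = amplitude * np.clip((radius_um - dist) / edge_um + 0.5, 0.0, 1.0)
    if rim > 0:
        body = body + rim * np.exp(-((dist - radius_um) ** 2) / (2 * rim_sigma_um**2))
    img[z0:z1, y0:y1, x0:x1] += body


def _add_capsule(img, stack_vs, axis_points_um, radius_um, amplitude, edge_um=0.6):
    """Add a soft-edged tube along a sampled medial axis."""
    dx, dy, dz = stack_vs
    nz, ny, nx = img.shape
    pts = np.asarray(axis_points_um)
    r = radius_um + edge_um
    lo = pts.min(axis=0) - r
    hi = pts.max(axis=0) + r
    x0, y0, z0 = (max(int(lo[0] / dx), 0), max(int(lo[1] / dy), 0),
                  max(int(lo[2] / dz), 0))
    x1, y1, z1 = (min(int(hi[0] / dx) + 2, nx), min(int(hi[1] / dy) + 2, ny),
                  min(int(hi[2] / dz) + 2, nz))
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = np.arange(z0, z1) * dz
    yy = np.arange(y0, y1) * dy
    xx = np.arange(x0, x1) * dx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    vox = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    d2 = ((vox[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d2.min(axis=1)).reshape(Z.shape)
    img[z0:z1, y0:y1, x0:x1] += amplitude * np.clip(
        (radius_um - dist) / edge_um + 0.5, 0.0, 1.0
    )


def gen_cochlea_stack(params: CochleaSimParams):
    """Render a 4-channel stack and its ground truth.

    Returns ``(ImageStack, GroundTruth DataFrame, CochleaPolyline)``.
    The polyline runs along the pillar-cell region between the IHC row
    and OHC row 1; truth ``position_um`` is arc length along it from
    the apex.  Truth arc distances are exact by construction (nuclei
    are placed on the cell's arc).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dx, dy, dz = p.voxel_size_um
    margin_xy = p.cell_radius_um + 2.0
    margin_z = 4.0
    L = p.axis_length

    # row lateral offsets from the stack edge; pillar region between
    # the IHC row (index 0) and the first OHC row
    row_y = margin_xy + np.array([0.0, 1.5, 2.5, 3.5]) * p.row_spacing_um
    pillar_y = margin_xy + 0.75 * p.row_spacing_um
    z_basal = margin_z
    z_apical = margin_z + p.cell_length_um

    size_x = L + 2 * margin_xy
    size_y = row_y[-1] + margin_xy
    size_z = z_apical + margin_z
    shape = (int(np.ceil(size_z / dz)) + 1, int(np.ceil(size_y / dy)) + 1,
             int(np.ceil(size_x / dx)) + 1)

    channels = {name: np.zeros(shape, dtype=np.float32)
                for name in ("DAPI", "MYO7A", "GFP", "FLAG")}

    records = []
    cell_id = 0
    for row in range(4):
        ctype = "IHC" if row == 0 else "OHC"
        for i in range(p.n_cells_per_row):
            pos = (i + 0.5) * p.cell_spacing_um
            if pos > L:
                break
            x = margin_xy + pos
            apical = np.array([x, row_y[row], z_apical])
            center, R, ang_a, ang_tot = _cell_arc(apical, p.cell_length_um, p.bow_um)
            arc_len = R * ang_tot
            basal = _arc_point(center, R, ang_a, arc_len)

            # survival: IHC always survive; OHC follow the gradient
            if ctype == "IHC":
                alive = True
            else:
                prob = np.clip(p.survival_base + p.survival_slope * pos / L, 0, 1)
                alive = bool(rng.random() < prob)

            transduced = bool(alive and rng.random() < p.transduced_fraction)

            # nuclear arc distance from the apical landmark
            d = p.wt_nucleus_distance_um
            if ctype == "OHC" and p.genotype in ("KO", "KO_treated"):
                if not (p.genotype == "KO_treated" and transduced):
                    d = d - p.nucleus_offset_effect_um
            if p.offset_jitter_um > 0:
                d = d + rng.normal(0.0, p.offset_jitter_um)
            d = float(np.clip(d, p.nucleus_radius_um,
                              arc_len - p.nucleus_radius_um))
            nucleus = _arc_point(center, R, ang_a, d)

            gfp_val = float(max(
                rng.normal(p.gfp_mu_on, p.gfp_sigma_on) if transduced
                else rng.normal(p.gfp_mu_off, p.gfp_sigma_off), 0.0))

            if alive:
                # myosin body: tube along the arc, tips at A and B
                s = np.arange(p.cell_radius_um, arc_len - p.cell_radius_um + 1e-9, 0.3)
                axis_pts = np.array([_arc_point(center, R, ang_a, si) for si in s])
                _add_capsule(channels["MYO7A"], p.voxel_size_um, axis_pts,
                             p.cell_radius_um, 100.0)
                # nucleus: DAPI ball with a bright envelope rim
                _add_ball(channels["DAPI"], p.voxel_size_um, nucleus,
                          p.nucleus_radius_um, 60.0, rim=40.0)
                _add_ball(channels["GFP"], p.voxel_size_um, nucleus,
                          p.nucleus_radius_um, gfp_val)
                if transduced:
                    _add_ball(channels["FLAG"], p.voxel_size_um, nucleus,
                              p.nucleus_radius_um, 0.0, rim=80.0)

            records.append({
                "cell_id": cell_id, "type": ctype, "row": row,
                "alive": alive, "transduced": transduced,
                "position_um": pos,
                "arc_distance_um": d, "arc_length_um": float(arc_len),
                "gfp_value": gfp_val,
                "ax": apical[0], "ay": apical[1], "az": apical[2],
                "nx": nucleus[0], "ny": nucleus[1], "nz": nucleus[2],
                "bx": basal[0], "by": basal[1], "bz": basal[2],
            })
            cell_id += 1

    if p.noise_sd > 0:
        for name in ("DAPI", "MYO7A", "GFP", "FLAG"):
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, p.noise_sd,
                                            shape).astype(np.float32),
                0.0, None)

    stack = ImageStack(channels=channels, voxel_size=p.voxel_size_um)
    truth = pd.DataFrame(records)
    polyline = CochleaPolyline(np.array([[margin_xy, pillar_y],
                                         [margin_xy + L, pillar_y]]))
    return stack, truth, polyline


# ---------------------------------------------------------------------------
# ABR

@dataclass(frozen=True)
class ABRSimParams:
    """ABR simulation: intensity-dependent P1/N1 complex over noise.

    At intensity I ≥ ``true_threshold``, the averaged trace carries a
    stimulus-locked P1/N1 complex with peak-to-peak amplitude
    ``base_amplitude + amplitude_growth·(I − threshold)`` µV and P1
    latency ``p1_latency − latency_shift_per_db·(I − threshold)`` ms
    after onset.  Noise is band-limited (smoothed white noise, as after
    the recording band-pass) with averaged SD ``noise_sd/√n_sweeps``.
    """

    true_threshold_db: float = 35.0
    frequencies: tuple = ("click", 6.0, 12.0, 18.0, 24.0, 30.0, 35.0)
    intensities_db: tuple = tuple(range(10, 95, 5))
    n_sweeps: int = 512
    p1_latency_ms: float = 1.5
    latency_shift_per_db: float = 0.01
    amplitude_growth_uv_per_db: float = 0.05
    base_amplitude_uv: float = 1.0
    noise_sd_uv: float = 2.0
    sampling_rate_khz: float = 16.0
    duration_ms: float = 16.0
    onset_ms: float = 8.0
    noise_smooth_samples: float = 8.0
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.intensities_db, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("intensity grid must be ascending")
        if not np.allclose(np.diff(grid), np.diff(grid)[0]):
            raise ValueError("intensity grid must have a uniform step")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.sampling_rate_khz < 8.0:
            raise ValueError("sampling rate too low for ms-scale peaks")


def _p1n1_shape(t_ms: np.ndarray, lat_ms: float) -> np.ndarray:
    """Unit-peak-to-peak P1/N1 complex with P1 at ``lat_ms``."""
    w = (np.exp(-((t_ms - lat_ms) ** 2) / (2 * 0.25**2))
         - 0.8 * np.exp(-((t_ms - lat_ms - 0.8) ** 2) / (2 * 0.35**2)))
    ptp = np.ptp(w)
    return w / ptp if ptp > 0 else w


def _bandlimited_noise(rng, n, sd, smooth):
    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, 1.0, n)
    if smooth > 0:
        raw = ndi.gaussian_filter1d(raw, smooth, mode="wrap")
        raw = raw / raw.std() if raw.std() > 0 else raw
    return sd * raw


def gen_abr_series(params: ABRSimParams):
    """Simulate averaged ABR series per stimulus frequency.

    Returns ``(series, truth)``: ``series`` maps frequency → ABRSeries,
    ``truth`` maps frequency → dict(threshold_db, censored).  A true
    threshold above the grid emits a warning and flags the truth as
    censored.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    grid = np.asarray(p.intensities_db, dtype=float)
    n = int(round(p.duration_ms * p.sampling_rate_khz)) + 1
    t = np.arange(n) / p.sampling_rate_khz
    avg_sd = p.noise_sd_uv / np.sqrt(p.n_sweeps)

    censored = bool(p.true_threshold_db > grid[-1])
    if censored:
        warnings.warn("true threshold above the intensity grid; truth censored")

    series, truth = {}, {}
    for freq in p.frequencies:
        traces = {}
        for inten in grid:
            v = _bandlimited_noise(rng, n, avg_sd, p.noise_smooth_samples)
            if inten >= p.true_threshold_db:
                above = inten - p.true_threshold_db
                lat = max(p.p1_latency_ms - p.latency_shift_per_db * above, 0.5)
                amp = p.base_amplitude_uv + p.amplitude_growth_uv_per_db * above
                v = v + amp * _p1n1_shape(t - p.onset_ms, lat)
            traces[float(inten)] = ABRTrace(
                time_ms=t, voltage_uv=v, frequency=freq,
                intensity_db=float(inten), onset_ms=p.onset_ms)
        series[freq] = ABRSeries(frequency=freq, traces=traces)
        truth[freq] = {"threshold_db": float(p.true_threshold_db),
                       "censored": censored}
    return series, truth


# ---------------------------------------------------------------------------
# DPOAE

def gen_dpoae_levels(f2_khz: float, ratio: float = 1.2, levels=None,
                     dp_gain_db_per_db: float = 1.0,
                     true_threshold_db: float = 40.0,
                     noise_floor_db: float = -10.0,
                     noise_sd_db: float = 3.0,
                     snr_at_threshold_db: float = 15.0,
                     bin_hz: float = 50.0,
                     seed: int = 0):
    """Simulate DPOAE spectra over ascending stimulus levels.

    Each spectrum has primaries at f1 = f2/ratio and f2 (at
    level − 10 dB) and, for level ≥ ``true_threshold_db``, a 2f1−f2
    component at ``noise_floor + snr_at_threshold +
    dp_gain·(level − threshold)`` dB SPL, power-summed with the
    per-bin noise floor.
    """
    if ratio <= 1.0:
        raise ValueError("ratio must exceed 1 (f1 < f2)")
    if levels is None:
        levels = list(range(20, 85, 5))
    levels = [float(v) for v in levels]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be ascending")

    rng = np.random.default_rng(seed)
    f1 = f2_khz / ratio * 1000.0
    f2 = f2_khz * 1000.0
    fdp = 2.0 * f1 - f2
    if fdp <= 0:
        raise ValueError("2f1-f2 is non-positive for this ratio")
    freqs = np.arange(max(fdp - 2000.0, bin_hz), f2 + 2000.0, bin_hz)

    spectra = []
    for level in levels:
        amp = rng.normal(noise_floor_db, noise_sd_db, freqs.size)
        power = 10.0 ** (amp / 10.0)

        def inject(f_hz, a_db):
            i = int(np.argmin(np.abs(freqs - f_hz)))
            power[i] += 10.0 ** (a_db / 10.0)

        inject(f1, level - 10.0)
        inject(f2, level - 10.0)
        if level >= true_threshold_db:
            dp_amp = (noise_floor_db + snr_at_threshold_db
                      + dp_gain_db_per_db * (level - true_threshold_db))
            inject(fdp, dp_amp)
        spectra.append(DPOAESpectrum(
            frequency_hz=freqs.copy(), amplitude_db=10.0 * np.log10(power),
            f1_hz=f1, f2_hz=f2, level_db=level))
    return spectra


# ---------------------------------------------------------------------------
# behavior

@dataclass(frozen=True)
class FCProtocol:
    """Cued fear-conditioning protocol.

    Day 1: baseline, then tone (6 kHz, 20 s) followed by a 2 s 0.7 mA
    shock, an inter-trial interval, and a second tone+shock.  Day 2:
    150 s baseline, then the same tone for 150 s with no shock.
    """

    day1_baseline_s: float = 90.0
    tone_s: float = 20.0
    tone_khz: float = 6.0
    shock_s: float = 2.0
    shock_ma: float = 0.7
    inter_trial_s: float = 60.0
    day2_baseline_s: float = 150.0
    day2_tone_s: float = 150.0
    frame_rate_hz: float = 25.0

    def __post_init__(self):
        for v in (self.day1_baseline_s, self.tone_s, self.shock_s,
                  self.inter_trial_s, self.day2_baseline_s, self.day2_tone_s):
            if v <= 0:
                raise ValueError("all protocol durations must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def day1_events(self):
        """(name, start_s, end_s) protocol intervals, in order."""
        t0 = self.day1_baseline_s
        ev = [("tone1", t0, t0 + self.tone_s),
              ("shock1", t0 + self.tone_s, t0 + self.tone_s + self.shock_s)]
        t1 = ev[-1][2] + self.inter_trial_s
        ev += [("tone2", t1, t1 + self.tone_s),
               ("shock2", t1 + self.tone_s, t1 + self.tone_s + self.shock_s)]
        return ev


def _merge_touching(bouts, tol=1e-9):
    merged = []
    for b in sorted(bouts, key=lambda b: b.start_s):
        if merged and b.start_s - merged[-1].end_s <= tol:
            merged[-1] = FreezeBout(merged[-1].start_s, max(merged[-1].end_s, b.end_s))
        else:
            merged.append(b)
    return merged


def gen_behavior_trace(protocol: FCProtocol, phenotype: str = "hearing",
                       freeze_latency_s: float = 0.0,
                       freeze_fraction: float = 0.8,
                       arena_side_m: float = 0.3,
                       seed: int = 0):
    """Simulate a day-2 fear-conditioning trace.

    ``hearing``: freeze bouts totaling ``freeze_fraction`` of the tone
    duration, starting ``freeze_latency_s`` after tone onset.
    ``deaf``: the same total freezing placed uniformly through the
    session, independent of tone timing.  Returns
    ``(BehaviorTrace, truth bout list)``; truth bouts match the
    rendered activity channel exactly on the frame grid.
    """
    if not (0.0 <= freeze_fraction <= 1.0):
        raise ValueError("freeze_fraction must lie in [0, 1]")
    if phenotype not in ("hearing", "deaf"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    p = protocol
    rng = np.random.default_rng(seed)
    onset = p.day2_baseline_s
    total = p.day2_baseline_s + p.day2_tone_s
    fr = p.frame_rate_hz
    n = int(round(total * fr))
    t = np.arange(n) / fr

    target = freeze_fraction * p.day2_tone_s
    bouts = []
    if target > 0:
        if phenotype == "hearing":
            pos = onset + freeze_latency_s
            acc = 0.0
            while acc < target - 1e-9 and pos < total - 1e-9:
                d = min(rng.uniform(3.0, 10.0), target - acc, total - pos)
                bouts.append(FreezeBout(pos, pos + d))
                acc += d
                gap = (rng.uniform(1.0, 4.0) * (1.0 - freeze_fraction)
                       / max(freeze_fraction, 1e-9))
                pos += d + gap
        else:
            acc = 0.0
            attempts = 0
            while acc < target - 1e-9 and attempts < 10_000:
                attempts += 1
                d = min(rng.uniform(3.0, 10.0), target - acc)
                start = rng.uniform(5.0, total - d - 1.0)
                cand = FreezeBout(start, start + d)
                if all(cand.end_s <= b.start_s - 1.0 or cand.start_s >= b.end_s + 1.0
                       for b in bouts):
                    bouts.append(cand)
                    acc += d
        bouts = _merge_touching(bouts)
        # snap bout edges to the frame grid so truth matches the
        # rendered activity channel exactly
        snapped = []
        for b in bouts:
            s = np.round(b.start_s * fr) / fr
            e = np.round(b.end_s * fr) / fr
            if e > s:
                snapped.append(FreezeBout(float(s), float(e)))
        bouts = _merge_touching(snapped)

    frozen = np.zeros(n, dtype=bool)
    for b in bouts:
        frozen |= (t >= b.start_s - 1e-9) & (t < b.end_s - 1e-9)

    activity = rng.uniform(0.1, 0.3, n)
    activity[frozen] = rng.uniform(0.0, 0.004, int(frozen.sum()))

    # center/nose tracks: random walk, paused while frozen, with a
    # slowly rotating nose vector
    steps = rng.normal(0.0, 0.004, (n, 2))
    steps[frozen] = 0.0
    center = np.clip(arena_side_m / 2.0 + np.cumsum(steps, axis=0),
                     0.02, arena_side_m - 0.02)
    dpsi = rng.normal(0.0, 0.1, n)
    dpsi[frozen] = 0.0
    psi = np.cumsum(dpsi)
    nose = center + 0.03 * np.stack([np.cos(psi), np.sin(psi)], axis=1)

    data = pd.DataFrame({
        "frame": np.arange(n), "time_s": t, "activity": activity,
        "cx": center[:, 0], "cy": center[:, 1],
        "nx": nose[:, 0], "ny": nose[:, 1],
    })
    trace = BehaviorTrace(data=data, annotations={
        "tone_on_s": onset, "tone_off_s": total,
        "tone_khz": p.tone_khz, "phenotype": phenotype,
    })
    return trace, bouts
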