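"""Hair-cell imaging: nucleus segmentation, IHC/OHC classification,
GFP transduction quantification, and nuclear-envelope line profiles.

Nuclei are segmented from the DAPI channel by automatic (Otsu)
thresholding followed by a distance-transform watershed that splits
touching nuclei.  Cells are typed IHC or OHC by the signed lateral
offset of their nucleus from the pillar-cell polyline (IHC on the
negative side, the three OHC rows on the positive side), and apical /
basal landmarks are read from the extent of the cell's myosin-VIIa
blob along the depth axis.

Transduction is scored against an un-injected control specimen: a cell
is GFP-positive when its mean nuclear GFP intensity exceeds the control
mean by more than two control standard deviations (per cell type), and
intensities are reported normalized to the control mean,
(I − µ_c) / µ_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .cochleomap import CochleaPolyline

__all__ = [
    "ImageStack",
    "NucleusSegment",
    "CellDetection",
    "RowGeometry",
    "ControlStats",
    "segment_nuclei",
    "classify_cells",
    "control_stats",
    "gfp_quantify",
    "envelope_profile",
    "save_stack",
    "load_stack",
]


@dataclass
class ImageStack:
    """Multi-channel 3D stack; arrays are (z, y, x), voxel_size is (dx, dy, dz) µm.

    Voxel (iz, iy, ix) is centered at physical position
    (ix·dx, iy·dy, iz·dz) µm (0-based indices at voxel centers).
    """

    channels: dict
    voxel_size: tuple

    def __post_init__(self):
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all channels must share one shape, got {shapes}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (dx, dy, dz)")
        for ch, a in self.channels.items():
            if np.any(a < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")
        self.voxel_size = vs

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in stack ({sorted(self.channels)})")
        return self.channels[name]

    def index_to_um(self, zyx) -> np.ndarray:
        """Voxel index (z, y, x) -> physical (x, y, z) in µm."""
        dx, dy, dz = self.voxel_size
        zyx = np.asarray(zyx, dtype=float)
        return np.stack(
            [zyx[..., 2] * dx, zyx[..., 1] * dy, zyx[..., 0] * dz], axis=-1
        )

    def um_to_index(self, xyz) -> np.ndarray:
        """Physical (x, y, z) µm -> fractional voxel index (z, y, x)."""
        dx, dy, dz = self.voxel_size
        xyz = np.asarray(xyz, dtype=float)
        return np.stack(
            [xyz[..., 2] / dz, xyz[..., 1] / dy, xyz[..., 0] / dx], axis=-1
        )


@dataclass
class NucleusSegment:
    label: int
    coords: np.ndarray            # (n, 3) voxel indices (z, y, x)
    centroid_um: np.ndarray       # (x, y, z) µm
    volume_um3: float


@dataclass
class CellDetection:
    cell_id: int
    type: str                     # "IHC" | "OHC"
    row: int                      # 0 for IHC, 1-3 for OHC
    segment: NucleusSegment
    apical_um: np.ndarray
    basal_um: np.ndarray
    position_um: float            # arc length from apex along the polyline
    flags: tuple = ()

    @property
    def centroid_um(self) -> np.ndarray:
        return self.segment.centroid_um


@dataclass
class RowGeometry:
    """Row model: pillar polyline plus expected row spacing.

    The polyline runs apex-first along the pillar-cell region, between
    the single IHC row (negative lateral offset) and the three OHC rows
    (positive offsets, one ``row_spacing`` apart).  ``apical_high_z``
    states which end of the depth axis is the cuticular-plate side.
    """

    polyline: CochleaPolyline
    row_spacing_um: float = 8.0
    #: known signed row offsets from the polyline (µm); when None the
    #: row centers are estimated by 1-D gap clustering of the data
    row_offsets_um: tuple | None = None
    myosin_channel: str = "MYO7A"
    apical_high_z: bool = True
    lateral_radius_um: float = 4.5


@dataclass
class ControlStats:
    """Per-cell-type control intensity statistics (µ_c, σ_c)."""

    mean: dict
    sd: dict

    def __post_init__(self):
        for t, mu in self.mean.items():
            if mu <= 0:
                raise ValueError(f"control mean for {t} must be positive")
            if self.sd[t] < 0:
                raise ValueError("control SD must be non-negative")

    def cutoff(self, cell_type: str) -> float:
        return self.mean[cell_type] + 2.0 * self.sd[cell_type]


def _ellipsoid_footprint(radius_um: float, voxel_size) -> np.ndarray:
    dx, dy, dz = voxel_size
    rz, ry, rx = (max(1, int(np.ceil(radius_um / d))) for d in (dz, dy, dx))
    zz, yy, xx = np.ogrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def segment_nuclei(stack: ImageStack, channel: str = "DAPI",
                   min_volume_um3: float = 8.0,
                   min_distance_um: float = 3.0) -> list:
    """Otsu threshold + distance-transform watershed nucleus segmentation.

    Touching nuclei are split at watershed lines of the Euclidean
    distance transform; regions smaller than ``min_volume_um3`` are
    discarded.  A constant channel yields zero segments.  Labels are
    re-assigned in (z, y, x) centroid order, so output is deterministic.
    """
    if min_volume_um3 < 0:
        raise ValueError("min_volume must be non-negative")
    img = stack.channel(channel)
    if img.max() == img.min():
        return []
    dx, dy, dz = stack.voxel_size
    binary = img > threshold_otsu(img)
    if not binary.any():
        return []

    edt = ndi.distance_transform_edt(binary, sampling=(dz, dy, dx))
    # smooth the distance map so plateau tops yield a single marker
    edt_s = ndi.gaussian_filter(edt, sigma=1.0)
    fp = _ellipsoid_footprint(min_distance_um, stack.voxel_size)
    peaks = peak_local_max(edt_s, footprint=fp, labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-edt, markers, mask=binary)

    voxel_vol = dx * dy * dz
    segments = []
    for lab in range(1, int(labels.max()) + 1):
        coords = np.argwhere(labels == lab)
        if coords.shape[0] == 0:
            continue
        vol = coords.shape[0] * voxel_vol
        if vol < min_volume_um3:
            continue
        centroid = stack.index_to_um(coords.mean(axis=0))
        segments.append(NucleusSegment(label=lab, coords=coords,
                                       centroid_um=centroid, volume_um3=float(vol)))
    segments.sort(key=lambda s: tuple(np.round(s.centroid_um[::-1], 6)))
    for new_lab, seg in enumerate(segments, start=1):
        seg.label = new_lab
    return segments


def _signed_offset(polyline: CochleaPolyline, p_xy: np.ndarray):
    """(arc position, signed lateral offset) of a 2D point; positive on
    the left of the apex-to-base travel direction."""
    s, dist, _ = polyline.project(p_xy)
    pts = polyline.points[:, :2]
    cum = polyline.cumlength
    i = int(np.searchsorted(cum, min(s, cum[-1] - 1e-9), side="right") - 1)
    i = min(max(i, 0), len(pts) - 2)
    d = pts[i + 1] - pts[i]
    t = (s - cum[i]) / np.linalg.norm(d)
    foot = pts[i] + np.clip(t, 0, 1) * d
    v = p_xy - foot
    sign = np.sign(d[0] * v[1] - d[1] * v[0])
    return s, float(dist * (sign if sign != 0 else 1.0))


def _cluster_offsets(offsets: np.ndarray, gap: float) -> list:
    """1-D clustering: split sorted offsets at gaps larger than ``gap``.
    Returns cluster centers, sorted ascending."""
    srt = np.sort(offsets)
    groups = [[srt[0]]]
    for v in srt[1:]:
        if v - groups[-1][-1] > gap:
            groups.append([v])
        else:
            groups[-1].append(v)
    return [float(np.mean(g)) for g in groups]


def classify_cells(segments, stack: ImageStack, geometry: RowGeometry) -> list:
    """Assign IHC/OHC type and row, extract landmarks and axial positions.

    Rows are recovered by clustering the signed lateral offsets of the
    nucleus centroids from the pillar polyline; the negative-offset
    cluster is the IHC row, positive clusters are OHC rows 1–3 ordered
    by increasing offset.  A nucleus equidistant between two row centers
    goes to the lower row index and is flagged ``ambiguous``.  Apical /
    basal landmarks are the centroids of the top and bottom depth slabs
    of the cell's myosin column; cells with no myosin signal are flagged
    ``no_myosin`` (landmarks fall back to the nucleus depth extent),
    never silently dropped.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments: cannot fit row model")
    poly = geometry.polyline

    pos_off = [_signed_offset(poly, np.asarray(s.centroid_um[:2])) for s in segments]
    offsets = np.array([o for _, o in pos_off])
    if geometry.row_offsets_um is not None:
        centers = sorted(float(c) for c in geometry.row_offsets_um)
    else:
        centers = _cluster_offsets(offsets, gap=0.5 * geometry.row_spacing_um)
    neg = [c for c in centers if c < 0]
    posc = sorted(c for c in centers if c >= 0)
    # row index per cluster center: IHC rows -> 0, OHC rows -> 1..k
    row_of_center = {}
    for c in neg:
        row_of_center[c] = (0, "IHC")
    for i, c in enumerate(posc, start=1):
        row_of_center[c] = (i, "OHC")

    if geometry.myosin_channel in stack.channels:
        myo = stack.channel(geometry.myosin_channel)
        myo_thr = threshold_otsu(myo) if myo.max() > myo.min() else np.inf
        myo_coords = np.argwhere(myo > myo_thr)
    else:
        myo_coords = np.empty((0, 3), dtype=int)
    myo_xy = stack.index_to_um(myo_coords)[:, :2] if myo_coords.size else np.empty((0, 2))

    detections = []
    for cid, (seg, (s_pos, off)) in enumerate(zip(segments, pos_off)):
        flags = []
        dists = np.abs(np.array(centers) - off)
        order = np.argsort(dists, kind="stable")
        best = centers[order[0]]
        if len(centers) > 1 and abs(dists[order[0]] - dists[order[1]]) < 1e-9:
            # exact tie between two row centers: lower row index wins
            cands = [centers[order[0]], centers[order[1]]]
            best = min(cands, key=lambda c: row_of_center[c][0])
            flags.append("ambiguous")
        if dists[order[0]] > geometry.row_spacing_um:
            flags.append("unassignable")
        row, ctype = row_of_center[best]

        # myosin column around the cell's lateral position
        cx, cy = seg.centroid_um[:2]
        if myo_coords.size:
            near = np.hypot(myo_xy[:, 0] - cx, myo_xy[:, 1] - cy) <= geometry.lateral_radius_um
            col = myo_coords[near]
        else:
            col = np.empty((0, 3), dtype=int)

        if col.shape[0] == 0:
            flags.append("no_myosin")
            nuc_um = stack.index_to_um(seg.coords)
            hi = nuc_um[np.argmax(nuc_um[:, 2])]
            lo = nuc_um[np.argmin(nuc_um[:, 2])]
            apical, basal = (hi, lo) if geometry.apical_high_z else (lo, hi)
        else:
            z = col[:, 0]
            top = stack.index_to_um(col[z == z.max()]).mean(axis=0)
            bot = stack.index_to_um(col[z == z.min()]).mean(axis=0)
            apical, basal = (top, bot) if geometry.apical_high_z else (bot, top)

        detections.append(CellDetection(
            cell_id=cid, type=ctype, row=row, segment=seg,
            apical_um=np.asarray(apical), basal_um=np.asarray(basal),
            position_um=float(s_pos), flags=tuple(flags),
        ))
    return detections


def _mean_over_segment(seg: NucleusSegment, channel_img: np.ndarray) -> float:
    z, y, x = seg.coords.T
    return float(channel_img[z, y, x].mean())


def control_stats(detections, stack: ImageStack, channel: str = "GFP") -> ControlStats:
    """Per-type mean/SD of nuclear intensities in a control specimen."""
    img = stack.channel(channel)
    by_type = {}
    for det in detections:
        by_type.setdefault(det.type, []).append(_mean_over_segment(det.segment, img))
    mean = {t: float(np.mean(v)) for t, v in by_type.items()}
    sd = {t: float(np.std(v, ddof=0)) for t, v in by_type.items()}
    return ControlStats(mean=mean, sd=sd)


def gfp_quantify(detections, stack: ImageStack, control: ControlStats,
                 channel: str = "GFP", pooled: bool = False):
    """Per-cell GFP intensity, control-normalized intensity and positivity.

    positive ⇔ I > µ_c + 2σ_c (per matching cell type, or pooled when
    ``pooled=True``); normalized = (I − µ_c)/µ_c.  Returns a DataFrame
    and a per-type transduction-rate dict.
    """
    img = stack.channel(channel)
    if pooled:
        mu = float(np.mean(list(control.mean.values())))
        sdv = float(np.mean(list(control.sd.values())))
        get_mu = lambda t: mu
        get_cut = lambda t: mu + 2.0 * sdv
    else:
        get_mu = lambda t: control.mean[t]
        get_cut = lambda t: control.cutoff(t)

    rows = []
    for det in detections:
        mu_c = get_mu(det.type)
        inten = _mean_over_segment(det.segment, img)
        rows.append({
            "cell_id": det.cell_id,
            "type": det.type,
            "row": det.row,
            "position_um": det.position_um,
            "intensity": inten,
            "normalized": (inten - mu_c) / mu_c,
            "positive": bool(inten > get_cut(det.type)),
        })
    table = pd.DataFrame(rows)
    rates = {}
    if len(table):
        for t, grp in table.groupby("type"):
            rates[t] = float(grp["positive"].mean())
    return table, rates


def envelope_profile(detection: CellDetection, stack: ImageStack,
                     channels=("FLAG", "DAPI"), half_width_um: float = 3.0,
                     direction=(0.0, 1.0, 0.0), step_um: float = 0.2,
                     search_um: float = 8.0) -> pd.DataFrame:
    """FLAG/DAPI line profile across the nuclear envelope.

    A radial line is cast from the nucleus centroid along ``direction``;
    the profile is centered at the position of maximal DAPI on that line
    (the nuclear periphery) and sampled on ±``half_width_um`` around it.
    Each channel is normalized to its own maximum along the profile.
    """
    if half_width_um <= 0:
        raise ValueError("half_width must be positive")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    c = np.asarray(detection.centroid_um, dtype=float)

    dapi_name = [ch for ch in channels if ch.upper() == "DAPI"]
    if not dapi_name:
        raise ValueError("a DAPI channel is required to center the profile")
    dapi_name = dapi_name[0]

    def sample(channel: str, positions_um: np.ndarray) -> np.ndarray:
        pts = c[None, :] + positions_um[:, None] * d[None, :]
        idx = stack.um_to_index(pts)  # (n, 3) fractional (z, y, x)
        return ndi.map_coordinates(stack.channel(channel).astype(float),
                                   idx.T, order=1, mode="nearest")

    t_search = np.arange(0.0, search_um + step_um / 2, step_um)
    dapi_line = sample(dapi_name, t_search)
    center_t = float(t_search[int(np.argmax(dapi_line))])

    positions = np.arange(-half_width_um, half_width_um + step_um / 2, step_um)
    out = {"position_um": positions}
    for ch in channels:
        prof = sample(ch, center_t + positions)
        m = prof.max()
        if m <= 0:
            raise ValueError(f"channel {ch!r} is zero along the profile line")
        out[f"{ch}_norm"] = prof / m
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# TIFF I/O

def save_stack(stack: ImageStack, path) -> None:
    """Write an OME-TIFF with channel names and voxel size in metadata."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    dx, dy, dz = stack.voxel_size
    tifffile.imwrite(
        path, data.astype(np.float32), ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": dx, "PhysicalSizeY": dy, "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm", "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def load_stack(path) -> ImageStack:
    """Read an OME-TIFF written by :func:`save_stack`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tifffile.xml2dict(tf.ome_metadata)
    image = meta["OME"]["Image"]
    if isinstance(image, list):
        image = image[0]
    pixels = image["Pixels"]
    chans = pixels["Channel"]
    if isinstance(chans, dict):
        chans = [chans]
    names = [c.get("Name", f"ch{i}") for i, c in enumerate(chans)]
    vs = (float(pixels.get("PhysicalSizeX", 1.0)),
          float(pixels.get("PhysicalSizeY", 1.0)),
          float(pixels.get("PhysicalSizeZ", 1.0)))
    if data.ndim == 3:
        data = data[None]
    channels = {n: data[i] for i, n in enumerate(names)}
    return ImageStack(channels=channels, voxel_size=vs)
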