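"""Mechanotyping features from binary mask trajectories.

The core shape descriptor is the aspect ratio AR: the extent of the
fitted ellipse along the channel axis over the perpendicular extent.
AR = 1 for an undeformed (spherical) cell, AR > 1 for a cell stretched
along the flow, AR < 1 for compression.  Relative deformability rD is
AR minus the minimum AR the same cell attains in the channel cavity, so
min(rD over cavity) = 0 by construction.

Each trajectory is partitioned into four phases: deformation entering
the first constriction (R1), relaxation into the cavity (R2), second
deformation (R3), and relaxation past the second constriction (R4).
The scalar feature set is {rD1, rD2, R2 slope, R3 slope, radius};
slopes are OLS fits of AR against axial position in µm⁻¹.  An extended
set adds normalized central moments and the seven Hu invariants of the
masks at the first peak, cavity baseline, and second peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import convex_hull_image

from .channel import ChannelGeometry
from .data import Detection
from .tracking import Trajectory

BASE_FEATURE_NAMES = ["rD1", "rD2", "R2_slope", "R3_slope", "radius"]

_MOMENT_NAMES = ["eta20", "eta11", "eta02"] + [f"hu{i}" for i in range(1, 8)]
EXTENDED_FEATURE_NAMES = BASE_FEATURE_NAMES + [
    f"{region}_{name}" for region in ("R1", "R2", "R3")
    for name in _MOMENT_NAMES
]


@dataclass(frozen=True)
class EllipseFit:
    """Moment-based ellipse fit of a single mask."""

    centroid: tuple[float, float]   # (x, y) µm within the patch frame
    a: float                        # semi-axis along the channel axis, µm
    b: float                        # perpendicular semi-axis, µm
    major: float                    # principal semi-axes, µm
    minor: float
    orientation: float              # radians, major axis vs channel axis
    ar: float                       # channel-axis / perpendicular extent

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    _, n = ndimage.label(mask)
    if n > 1:
        raise ValueError(f"mask has {n} connected components")
    return mask


def fit_ellipse(mask: np.ndarray, pixel_size: float = 1.0) -> EllipseFit:
    """Fit an ellipse to a mask via its first and second moments.

    The principal axes come from the eigen-decomposition of the second
    central moment matrix (semi-axis = 2·sqrt(eigenvalue), exact for a
    solid ellipse).  AR uses the axis-aligned convention: the projected
    extent along the channel axis (columns) over the perpendicular
    extent (rows), i.e. sqrt(mu20/mu02), so compression is AR < 1.
    """
    mask = _check_mask(mask)
    rows, cols = np.nonzero(mask)
    n = rows.size
    cr, cc = rows.mean(), cols.mean()
    dr, dc = rows - cr, cols - cc
    mu20 = (dc * dc).mean()   # variance along channel axis (x ~ columns)
    mu02 = (dr * dr).mean()
    mu11 = (dc * dr).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order
    minor_ax = 2.0 * math.sqrt(max(evals[0], 1e-12)) * pixel_size
    major_ax = 2.0 * math.sqrt(max(evals[1], 1e-12)) * pixel_size
    vx, vy = evecs[0, 1], evecs[1, 1]
    orientation = math.atan2(vy, vx)
    a = 2.0 * math.sqrt(mu20) * pixel_size
    b = 2.0 * math.sqrt(mu02) * pixel_size
    return EllipseFit(
        centroid=((cc + 0.5) * pixel_size, (cr + 0.5) * pixel_size),
        a=a, b=b, major=major_ax, minor=minor_ax,
        orientation=orientation, ar=a / b)


def convex_hull_ratio(mask: np.ndarray) -> float:
    """Convex hull area over mask area; 1 for convex shapes."""
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        raise ValueError("empty mask")
    if area == 1:
        return 1.0
    # hull of pixel centers (no half-pixel offset): a digitized convex
    # shape then scores ~1.0 instead of inheriting an O(1/r) bias
    hull = convex_hull_image(mask, offset_coordinates=False)
    return float(hull.sum() / area)


def mask_perimeter(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Contour perimeter of the mask in µm."""
    return float(measure.perimeter(np.asarray(mask, dtype=bool), neighborhood=4)
                 * pixel_size)


def shape_moments(mask: np.ndarray) -> dict[str, float]:
    """Normalized central moments (order 2) and Hu's seven invariants."""
    mask = _check_mask(mask)
    m = measure.moments_central(mask.astype(float))
    norm = measure.moments_normalized(m)
    hu = measure.moments_hu(norm)
    out = {"eta20": float(norm[2, 0]), "eta11": float(norm[1, 1]),
           "eta02": float(norm[0, 2])}
    for i, v in enumerate(hu, start=1):
        out[f"hu{i}"] = float(v)
    return out


@dataclass
class ShapeSeries:
    """Per-frame shape descriptors of one trajectory, ordered by x."""

    x: np.ndarray                  # µm, strictly increasing
    ar: np.ndarray
    area: np.ndarray               # µm²
    perimeter: np.ndarray          # µm
    detections: list[Detection]
    cell_id: int
    phenotype: str | None = None
    ar_min_cavity: float | None = None
    partition: "RegionPartition | None" = None

    @property
    def rd(self) -> np.ndarray:
        if self.ar_min_cavity is None:
            raise ValueError("partition the series before computing rD")
        return self.ar - self.ar_min_cavity

    @property
    def radius(self) -> float:
        """Mean equivalent radius (µm) from per-frame areas."""
        return float(np.sqrt(self.area / math.pi).mean())


def shape_series(traj: Trajectory, pixel_size: float) -> ShapeSeries:
    """Fit ellipses along a trajectory and assemble the AR series."""
    xs, ars, areas, perims = [], [], [], []
    for det in traj.detections:
        fit = fit_ellipse(det.mask, pixel_size)
        xs.append(det.centroid[0])
        ars.append(fit.ar)
        areas.append(det.area)
        perims.append(mask_perimeter(det.mask, pixel_size))
    order = np.argsort(xs)
    return ShapeSeries(
        x=np.asarray(xs)[order], ar=np.asarray(ars)[order],
        area=np.asarray(areas)[order], perimeter=np.asarray(perims)[order],
        detections=[traj.detections[i] for i in order],
        cell_id=traj.cell_id, phenotype=traj.phenotype)


@dataclass(frozen=True)
class RegionPartition:
    """Index ranges of the four trajectory phases.

    R1 = start..peak1, R2 = peak1..baseline, R3 = baseline..peak2,
    R4 = peak2..end (all inclusive of their endpoints).
    """

    peak1: int
    baseline: int
    peak2: int
    n: int
    degenerate: tuple[str, ...] = ()

    def indices(self, region: str) -> tuple[int, int]:
        spans = {"R1": (0, self.peak1), "R2": (self.peak1, self.baseline),
                 "R3": (self.baseline, self.peak2),
                 "R4": (self.peak2, self.n - 1)}
        return spans[region]


def partition_regions(series: ShapeSeries, geometry: ChannelGeometry
                      ) -> RegionPartition:
    """Locate the two deformation peaks and the cavity baseline.

    peak1 is the AR maximum before the cavity, the baseline is the AR
    minimum inside the cavity, and peak2 is the AR maximum downstream of
    the baseline.  Degenerate phases (length <= 1) are flagged rather
    than raised, so callers can propagate missing values.
    """
    lo, hi = geometry.alignment_window
    cav_lo, cav_hi = geometry.cavity_span
    x = series.x
    pre = np.nonzero((x >= lo) & (x < cav_lo))[0]
    cav = np.nonzero((x >= cav_lo) & (x < cav_hi))[0]
    if pre.size == 0 or cav.size == 0:
        raise ValueError("series does not cover the pre-cavity and cavity "
                         "regions")
    peak1 = int(pre[np.argmax(series.ar[pre])])
    baseline = int(cav[np.argmin(series.ar[cav])])
    post = np.nonzero((x >= x[baseline]) & (x <= hi))[0]
    peak2 = int(post[np.argmax(series.ar[post])])
    degenerate = tuple(
        name for name, (i, j) in (
            ("R1", (0, peak1)), ("R2", (peak1, baseline)),
            ("R3", (baseline, peak2)), ("R4", (peak2, x.size - 1)))
        if j - i <= 1)
    part = RegionPartition(peak1=peak1, baseline=baseline, peak2=peak2,
                           n=x.size, degenerate=degenerate)
    series.partition = part
    series.ar_min_cavity = float(series.ar[baseline])
    return part


def relative_deformability(series: ShapeSeries
                           ) -> tuple[np.ndarray, float, float]:
    """rD series plus its maxima in the two deformation phases.

    rD(x) = AR(x) − min(AR over cavity); rD1 = max rD in R1,
    rD2 = max rD in R3.
    """
    if series.partition is None:
        raise ValueError("call partition_regions first")
    rd = series.rd
    p = series.partition
    rd1 = float(rd[0:p.peak1 + 1].max())
    rd2 = float(rd[p.baseline:p.peak2 + 1].max())
    return rd, rd1, rd2


def fit_slope(series: ShapeSeries, start_idx: int, end_idx: int) -> float:
    """OLS slope of AR against x (µm⁻¹) over [start_idx, end_idx]."""
    if end_idx - start_idx < 1:
        raise ValueError("need at least 2 points for a slope")
    x = series.x[start_idx:end_idx + 1]
    y = series.ar[start_idx:end_idx + 1]
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    return float(np.dot(dx, y - ym) / np.dot(dx, dx))


@dataclass
class FeatureVector:
    """Derived mechanotyping scalars for one trajectory."""

    cell_id: int
    phenotype: str | None
    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names])


def derive_feature_vector(series: ShapeSeries, geometry: ChannelGeometry,
                          extended: bool = False) -> FeatureVector:
    """Compute {rD1, rD2, R2_slope, R3_slope, radius} (+ moments).

    The extended set adds normalized central moments and Hu invariants
    of the masks at peak1 (R1), the cavity baseline (R2), and peak2
    (R3): 30 additional values.  Degenerate phases yield NaN slopes and
    a flag instead of an error.
    """
    if series.partition is None:
        partition_regions(series, geometry)
    p = series.partition
    _, rd1, rd2 = relative_deformability(series)
    flags = [f"degenerate_{r}" for r in p.degenerate]
    values: dict[str, float] = {"rD1": rd1, "rD2": rd2,
                                "radius": series.radius}
    values["R2_slope"] = (fit_slope(series, p.peak1, p.baseline)
                          if "R2" not in p.degenerate else float("nan"))
    values["R3_slope"] = (fit_slope(series, p.baseline, p.peak2)
                          if "R3" not in p.degenerate else float("nan"))
    if extended:
        for region, idx in (("R1", p.peak1), ("R2", p.baseline),
                            ("R3", p.peak2)):
            mom = shape_moments(series.detections[idx].mask)
            for name, v in mom.items():
                values[f"{region}_{name}"] = v
    return FeatureVector(cell_id=series.cell_id, phenotype=series.phenotype,
                         values=values, flags=flags)


@dataclass
class FilterReport:
    kept: list[ShapeSeries]
    discarded: list[tuple[ShapeSeries, str]]
    counts: dict[str, int]


def apply_filters(series_list: list[ShapeSeries],
                  hull_threshold: float = 1.1,
                  radius_sd_threshold: float = 3.0) -> FilterReport:
    """Reject segmentation failures and size outliers.

    A trajectory is discarded if any frame's convex-hull/mask area ratio
    exceeds ``hull_threshold`` (strict inequality), or if its mean
    radius deviates from the population mean by at least
    ``radius_sd_threshold`` population standard deviations.  The radius
    rule is defined on the full input population, so filtering is done
    after pooling; the kept set is order-independent.
    """
    hull_ok: list[ShapeSeries] = []
    discarded: list[tuple[ShapeSeries, str]] = []
    for s in series_list:
        ratios = [convex_hull_ratio(d.mask) for d in s.detections]
        if max(ratios, default=1.0) > hull_threshold:
            discarded.append((s, "hull ratio"))
        else:
            hull_ok.append(s)

    if hull_ok:
        radii = np.array([s.radius for s in hull_ok])
        mean, sd = radii.mean(), radii.std()
        kept = []
        for s, r in zip(hull_ok, radii):
            if sd > 0 and abs(r - mean) >= radius_sd_threshold * sd:
                discarded.append((s, "radius outlier"))
            else:
                kept.append(s)
    else:
        kept = []

    counts: dict[str, int] = {"kept": len(kept)}
    for _, reason in discarded:
        counts[reason] = counts.get(reason, 0) + 1
    return FilterReport(kept=kept, discarded=discarded, counts=counts)


SEQUENCE_CHANNELS = ["ar", "perimeter", "rd", "area"]
SEQUENCE_LENGTH = 50


def prepare_sequences(series_list: list[ShapeSeries],
                      geometry: ChannelGeometry
                      ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Model-ready padded sequences of (AR, perimeter, rD, area).

    Frames are clipped to the alignment window, post-padded with zeros
    to length 50; a boolean validity mask marks real steps.  Sequences
    longer than 50 frames are rejected with an explicit error.
    Returns (sequences [n, 50, 4], valid [n, 50], cell_ids).
    """
    lo, hi = geometry.alignment_window
    out = np.zeros((len(series_list), SEQUENCE_LENGTH,
                    len(SEQUENCE_CHANNELS)))
    valid = np.zeros((len(series_list), SEQUENCE_LENGTH), dtype=bool)
    cell_ids = []
    for i, s in enumerate(series_list):
        if s.partition is None:
            partition_regions(s, geometry)
        keep = (s.x >= lo) & (s.x <= hi)
        n = int(keep.sum())
        if n > SEQUENCE_LENGTH:
            raise ValueError(
                f"trajectory {s.cell_id} has {n} frames in the alignment "
                f"window; the sequence contract allows {SEQUENCE_LENGTH}")
        stacked = np.stack([s.ar[keep], s.perimeter[keep],
                            s.rd[keep], s.area[keep]], axis=1)
        out[i, :n] = stacked
        valid[i, :n] = True
        cell_ids.append(s.cell_id)
    return out, valid, cell_ids


MASK_CROP = 96


def prepare_mask_sequences(series_list: list[ShapeSeries],
                           geometry: ChannelGeometry,
                           crop: int = MASK_CROP
                           ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Two-channel centered mask-image sequences, padded to length 50.

    Channel 1 is the binary mask centered in a crop×crop window;
    channel 2 is the rasterized fitted ellipse of that mask.  Padded
    steps are all-zero in both channels.  Returns
    (tensor [n, 50, crop, crop, 2] uint8, valid [n, 50], cell_ids).
    """
    lo, hi = geometry.alignment_window
    n_traj = len(series_list)
    out = np.zeros((n_traj, SEQUENCE_LENGTH, crop, crop, 2), dtype=np.uint8)
    valid = np.zeros((n_traj, SEQUENCE_LENGTH), dtype=bool)
    cell_ids = []
    half = crop // 2
    yy, xx = np.mgrid[:crop, :crop]
    for i, s in enumerate(series_list):
        keep = np.nonzero((s.x >= lo) & (s.x <= hi))[0]
        if keep.size > SEQUENCE_LENGTH:
            raise ValueError(
                f"trajectory {s.cell_id} has {keep.size} frames in the "
                f"alignment window; the sequence contract allows "
                f"{SEQUENCE_LENGTH}")
        for t, j in enumerate(keep):
            mask = np.asarray(s.detections[j].mask, dtype=bool)
            h, w = mask.shape
            if h > crop or w > crop:
                raise ValueError(
                    f"mask of trajectory {s.cell_id} ({h}x{w}) exceeds "
                    f"the {crop}x{crop} crop")
            rows, cols = np.nonzero(mask)
            cr, cc = rows.mean(), cols.mean()
            r0 = half - int(round(cr))
            c0 = half - int(round(cc))
            centered = np.zeros((crop, crop), dtype=bool)
            centered[r0:r0 + h, c0:c0 + w] = mask
            fit = fit_ellipse(mask, 1.0)
            # rasterize the fitted ellipse in its principal frame
            ct, st_ = math.cos(fit.orientation), math.sin(fit.orientation)
            dx = xx - half
            dy = yy - half
            u = dx * ct + dy * st_
            v = -dx * st_ + dy * ct
            ellipse = ((u / max(fit.major, 0.5)) ** 2
                       + (v / max(fit.minor, 0.5)) ** 2) <= 1.0
            out[i, t, :, :, 0] = centered
            out[i, t, :, :, 1] = ellipse
            valid[i, t] = True
        cell_ids.append(s.cell_id)
    return out, valid, cell_ids


def extract_features(trajectories: list[Trajectory],
                     geometry: ChannelGeometry, pixel_size: float,
                     extended: bool = False,
                     hull_threshold: float = 1.1,
                     radius_sd_threshold: float = 3.0
                     ) -> tuple[list[FeatureVector], FilterReport]:
    """Trajectories → filtered feature vectors (pipeline convenience)."""
    series_list = [shape_series(t, pixel_size) for t in trajectories]
    report = apply_filters(series_list, hull_threshold, radius_sd_threshold)
    feats = [derive_feature_vector(s, geometry, extended=extended)
             for s in report.kept]
    return feats, report
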