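"""Synthetic generator: cell populations, deformation dynamics, masks.

Cells are modelled as constant-area ellipses advected along the channel
centerline.  The shape anisotropy D = a/b (axis parallel / perpendicular
to the flow) relaxes toward a stress-set equilibrium with a single
relaxation time:

    dx/dt = v(x)
    dD/dt = (D_eq(x) - D) / tau,     D_eq(x) = 1 + k * dv/dx(x)

where ``k`` (the deformation gain, in seconds) maps the local velocity
gradient to the equilibrium anisotropy and ``tau`` sets the response
kinetics.  This first-order viscoelastic response is the simplest model
that produces the experimentally observed trace: a large deformation
peak entering the first constriction, relaxation to a sphere in the
cavity where dv/dx = 0, a second, smaller peak entering the second
constriction, and relaxation at the outlet.  Phenotypes differ in the
joint distribution of (k, tau, radius); k and tau are generator
constructs, not estimates of any measured cell's rheology.

Masks are rendered by rasterizing the ellipse at the acquisition pixel
size, optionally perturbing the boundary with smooth angular noise to
emulate segmentation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .channel import (
    ChannelGeometry,
    DEFAULT_VELOCITY_SCALE,
    centerline_velocity,
    stress_proxy,
)
from .data import Dataset, Detection


@dataclass(frozen=True)
class PhenotypeConfig:
    """Generative parameter distributions for one phenotype.

    ``gain`` (k, seconds) and ``tau`` (ms) are drawn from normal
    distributions truncated at zero; ``radius`` (µm) likewise.
    ``boundary_noise_sd`` is the RMS radial boundary perturbation in
    pixels applied when rendering masks.
    """

    name: str
    gain_mean: float
    gain_sd: float
    tau_mean: float               # ms
    tau_sd: float                 # ms
    radius_mean: float = 6.0      # µm
    radius_sd: float = 0.4        # µm
    boundary_noise_sd: float = 0.5
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_mean < 0:
            raise ValueError("gain_mean must be >= 0")
        if self.tau_mean <= 0:
            raise ValueError("tau_mean must be positive")
        if self.radius_sd >= self.radius_mean / 3:
            raise ValueError("radius_sd must be < radius_mean / 3")


@dataclass(frozen=True)
class CellParams:
    """Sampled generative parameters of a single cell."""

    cell_id: int
    phenotype: str
    radius: float                 # µm
    gain: float                   # s
    tau: float                    # ms
    entry_time: float             # s
    boundary_noise_sd: float = 0.5
    y_offset: float = 0.0         # µm, lateral offset from the channel axis
    start_x: float | None = None  # µm; None = upstream of the window

    def __post_init__(self) -> None:
        vals = (self.radius, self.gain, self.tau, self.entry_time)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("cell parameters must be finite")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and flow settings of the emulated recording."""

    fps: float = 11000.0
    pixel_size: float = 0.26      # µm/pixel
    frame_shape: tuple[int, int] = (140, 880)
    flow_rate: float = 1.0        # µL/min
    velocity_scale: float = DEFAULT_VELOCITY_SCALE
    x_origin: float = -44.2       # µm at pixel column 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.pixel_size <= 0:
            raise ValueError("fps and pixel_size must be positive")


@dataclass(frozen=True)
class TrueState:
    """Ground-truth kinematic state of a cell at one frame time."""

    t: float                      # s
    x: float                      # µm
    d_true: float                 # equilibrium-relative anisotropy a/b
    a: float                      # semi-axis parallel to flow, µm
    b: float                      # semi-axis perpendicular, µm


@dataclass(frozen=True)
class ArtifactsConfig:
    """Controlled defects injected to exercise tracking and filters."""

    impossible_fraction: float = 0.0   # cells first appearing mid-channel
    impossible_start_x: float = 60.0   # µm
    concave_fraction: float = 0.0      # cells with one crescent frame
    concave_bite_scale: float = 0.75   # bite radius as fraction of r


# Default phenotypes mirror the three-population study design: an
# untreated line, an actin-disrupted (more deformable, faster) line, and
# a microtubule-disrupted (less deformable, slower, more variable) line.
# Radii are drawn from the same distribution for all three phenotypes —
# the populations are intentionally size-matched so that classification
# can only exploit mechanics.
def default_phenotypes() -> list[PhenotypeConfig]:
    return [
        PhenotypeConfig(name="HL60", gain_mean=6.0e-5, gain_sd=1.0e-5,
                        tau_mean=0.042, tau_sd=0.008, abundance=1 / 3),
        PhenotypeConfig(name="HL60d", gain_mean=8.5e-5, gain_sd=1.2e-5,
                        tau_mean=0.034, tau_sd=0.007, abundance=1 / 3),
        PhenotypeConfig(name="HL60n", gain_mean=4.0e-5, gain_sd=1.5e-5,
                        tau_mean=0.050, tau_sd=0.010, abundance=1 / 3),
    ]


def _cell_rng(seed: int, cell_id: int, purpose: int = 0) -> np.random.Generator:
    """Per-cell substream: reproducible regardless of sampling order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell_id, purpose)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """Draw from N(mean, sd) truncated to (low, inf) by rejection."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    raise RuntimeError("truncated normal rejection failed; check config")


def sample_population(phenotype_configs: list[PhenotypeConfig],
                      n_per_phenotype: int, seed: int,
                      mean_gap_s: float = 0.010,
                      min_gap_s: float = 1.2e-3) -> list[CellParams]:
    """Sample a seeded population of cells, interleaved by entry time.

    Per-cell parameters are drawn from each cell's own substream keyed
    by ``cell_id``, so the same seed always yields the same population.
    Entry times are spaced by exponential gaps (mean ``mean_gap_s``)
    after a shuffle that interleaves phenotypes; gaps are floored at
    ``min_gap_s`` because consecutive cells are excluded-volume objects
    that cannot ride closer than about one cell diameter apart.
    """
    if n_per_phenotype < 1:
        raise ValueError("n_per_phenotype must be >= 1")
    order_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0xE17,)))
    assignments: list[PhenotypeConfig] = []
    for cfg in phenotype_configs:
        assignments.extend([cfg] * n_per_phenotype)
    perm = order_rng.permutation(len(assignments))
    gaps = np.maximum(order_rng.exponential(mean_gap_s,
                                            size=len(assignments)),
                      min_gap_s)
    entry_times = np.cumsum(gaps)

    cells = []
    for cell_id, (j, t0) in enumerate(zip(perm, entry_times)):
        cfg = assignments[j]
        rng = _cell_rng(seed, cell_id)
        radius = _truncated_normal(rng, cfg.radius_mean, cfg.radius_sd)
        gain = _truncated_normal(rng, cfg.gain_mean, cfg.gain_sd)
        tau = _truncated_normal(rng, cfg.tau_mean, cfg.tau_sd)
        y_offset = float(rng.normal(0.0, 0.8))
        cells.append(CellParams(
            cell_id=cell_id, phenotype=cfg.name, radius=radius, gain=gain,
            tau=tau, entry_time=float(t0),
            boundary_noise_sd=cfg.boundary_noise_sd, y_offset=y_offset))
    return cells


# floor on the equilibrium anisotropy; keeps extreme gain draws physical
_D_EQ_MIN = 0.25


def simulate_trajectories(cells: list[CellParams],
                          geometry: ChannelGeometry,
                          acquisition: AcquisitionConfig,
                          substeps: int = 10,
                          start_margin: float = 12.0,
                          end_margin: float = 8.0
                          ) -> list[list[TrueState]]:
    """Integrate cell kinematics and sample each cell at frame times.

    Fixed-step RK4 on (x, D), vectorized over cells.  The substep count
    per frame is raised automatically when the shortest tau in the batch
    approaches the frame interval, keeping the relaxation equation
    stable (dt <= tau/2).  Each trajectory covers the alignment window
    with margins on both sides (unless the cell has a forced mid-channel
    ``start_x``).
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if not cells:
        return []
    n = len(cells)
    tau_s = np.array([c.tau for c in cells]) * 1e-3
    gain = np.array([c.gain for c in cells])
    radius = np.array([c.radius for c in cells])
    dt_frame = 1.0 / acquisition.fps
    n_sub = max(substeps, math.ceil(2.0 * dt_frame / tau_s.min()))
    if n_sub > 200_000:
        raise RuntimeError(
            f"stability violation: tau={tau_s.min() * 1e3:.2g} ms needs "
            f"{n_sub} substeps per frame")
    h = dt_frame / n_sub

    lo, hi = geometry.alignment_window
    x0 = np.array([lo - start_margin if c.start_x is None else c.start_x
                   for c in cells])
    x_end = hi + end_margin
    q, vs = acquisition.flow_rate, acquisition.velocity_scale

    def deriv(x, d):
        v = centerline_velocity(geometry, q, x, vs)
        d_eq = np.maximum(1.0 + gain * stress_proxy(geometry, q, x, vs),
                          _D_EQ_MIN)
        return v, (d_eq - d) / tau_s

    def rk4(x, d, h):
        k1v, k1d = deriv(x, d)
        k2v, k2d = deriv(x + 0.5 * h * k1v, d + 0.5 * h * k1d)
        k3v, k3d = deriv(x + 0.5 * h * k2v, d + 0.5 * h * k2d)
        k4v, k4d = deriv(x + h * k3v, d + h * k3d)
        return (x + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v),
                d + h / 6 * (k1d + 2 * k2d + 2 * k3d + k4d))

    # first sampled frame at or after each cell's entry time
    entry = np.array([c.entry_time for c in cells])
    n0 = np.ceil(entry * acquisition.fps - 1e-9).astype(int)
    t_first = n0 / acquisition.fps
    x = x0.copy()
    d = np.ones(n)
    # advance each cell from entry_time to its first frame time
    lead = t_first - entry
    if np.any(lead > 0):
        m = max(1, math.ceil(lead.max() / h))
        hl = lead / m
        for _ in range(m):
            x, d = rk4(x, d, hl)

    states: list[list[TrueState]] = [[] for _ in range(n)]
    active = np.ones(n, dtype=bool)
    for frame in range(100_000):
        sqrt_d = np.sqrt(d)
        t_frame = t_first + frame * dt_frame
        for i in np.nonzero(active)[0]:
            states[i].append(TrueState(
                t=float(t_frame[i]), x=float(x[i]), d_true=float(d[i]),
                a=float(radius[i] * sqrt_d[i]),
                b=float(radius[i] / sqrt_d[i])))
        active &= x < x_end
        if not active.any():
            break
        for _ in range(n_sub):
            x, d = rk4(x, d, h)
    else:
        raise RuntimeError("trajectories did not reach the channel end")
    return states


def simulate_trajectory(cell: CellParams, geometry: ChannelGeometry,
                        acquisition: AcquisitionConfig,
                        substeps: int = 10,
                        start_margin: float = 12.0,
                        end_margin: float = 8.0) -> list[TrueState]:
    """Single-cell convenience wrapper around the batch integrator."""
    return simulate_trajectories([cell], geometry, acquisition, substeps,
                                 start_margin, end_margin)[0]


def quasi_static_anisotropy(cell: CellParams, geometry: ChannelGeometry,
                            acquisition: AcquisitionConfig, x) -> np.ndarray:
    """Closed-form tau→0 limit: D(x) = max(1 + k·dv/dx, floor)."""
    dv = stress_proxy(geometry, acquisition.flow_rate, x,
                      acquisition.velocity_scale)
    return np.maximum(1.0 + cell.gain * np.asarray(dv), _D_EQ_MIN)


_NOISE_MODES = np.arange(2, 9)


def _boundary_noise(rng: np.random.Generator, noise_sd: float,
                    theta: np.ndarray) -> np.ndarray:
    """Smooth angular perturbation with RMS amplitude noise_sd pixels."""
    if noise_sd == 0:
        return np.zeros_like(theta)
    k = _NOISE_MODES.size
    coeffs = rng.normal(0.0, 1.0, size=(2, k))
    field = (coeffs[0] @ np.cos(np.outer(_NOISE_MODES, theta))
             + coeffs[1] @ np.sin(np.outer(_NOISE_MODES, theta)))
    return field * noise_sd / math.sqrt(k)


def render_patch(state: TrueState, acquisition: AcquisitionConfig,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 y_offset: float = 0.0
                 ) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize the ellipse as a boolean patch plus its frame offset.

    Pixels whose centers fall inside the (optionally noise-perturbed)
    ellipse boundary are set.  Raises if the ellipse does not fit inside
    the frame.
    """
    px = acquisition.pixel_size
    ap, bp = state.a / px, state.b / px
    rows, cols = acquisition.frame_shape
    cc = (state.x - acquisition.x_origin) / px
    cr = rows / 2.0 + y_offset / px
    pad = 3.0 + 3.0 * noise_sd
    r_lo = int(math.floor(cr - bp - pad))
    r_hi = int(math.ceil(cr + bp + pad)) + 1
    c_lo = int(math.floor(cc - ap - pad))
    c_hi = int(math.ceil(cc + ap + pad)) + 1
    if r_lo < 0 or c_lo < 0 or r_hi > rows or c_hi > cols:
        raise ValueError(
            f"ellipse at x={state.x:.1f} µm exceeds frame bounds")
    rr = np.arange(r_lo, r_hi) + 0.5
    cc_grid = np.arange(c_lo, c_hi) + 0.5
    dy = (rr - cr)[:, None]
    dx = (cc_grid - cc)[None, :]
    theta = np.arctan2(dy, dx)
    # elliptical boundary radius along each pixel's direction
    rho = (ap * bp) / np.sqrt((bp * np.cos(theta)) ** 2
                              + (ap * np.sin(theta)) ** 2)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        rho = rho + _boundary_noise(rng, noise_sd, theta.ravel()
                                    ).reshape(theta.shape)
    mask = np.hypot(dx, dy) <= rho
    return mask, (r_lo, c_lo)


def render_mask(state: TrueState, acquisition: AcquisitionConfig,
                noise_sd: float = 0.0,
                rng: np.random.Generator | None = None,
                y_offset: float = 0.0) -> np.ndarray:
    """Full-frame binary raster of one cell (convenience wrapper)."""
    patch, (r0, c0) = render_patch(state, acquisition, noise_sd, rng,
                                   y_offset)
    frame = np.zeros(acquisition.frame_shape, dtype=bool)
    frame[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] = patch
    return frame


def crescent_patch(radius_px: float, bite_scale: float = 0.75
                   ) -> np.ndarray:
    """Disc with a circular bite removed: a concave segmentation defect."""
    r = radius_px
    rb = bite_scale * r
    size = int(math.ceil(2 * r)) + 5
    yy, xx = np.mgrid[:size, :size]
    cyx = (size - 1) / 2.0
    disc = (xx - cyx) ** 2 + (yy - cyx) ** 2 <= r ** 2
    bite = (xx - (cyx + r)) ** 2 + (yy - cyx) ** 2 <= rb ** 2
    return disc & ~bite


def _detection_from_patch(frame_index: int, patch: np.ndarray,
                          offset: tuple[int, int],
                          acquisition: AcquisitionConfig,
                          truth: dict | None) -> Detection:
    px = acquisition.pixel_size
    rows_idx, cols_idx = np.nonzero(patch)
    r0, c0 = offset
    cr = rows_idx.mean() + r0
    ccol = cols_idx.mean() + c0
    x_um = acquisition.x_origin + (ccol + 0.5) * px
    y_um = (cr + 0.5 - acquisition.frame_shape[0] / 2.0) * px
    area = patch.sum() * px * px
    return Detection(frame_index=frame_index, mask=patch, offset=offset,
                     centroid=(float(x_um), float(y_um)), area=float(area),
                     truth=truth)


def generate_dataset(population: list[CellParams],
                     geometry: ChannelGeometry,
                     acquisition: AcquisitionConfig,
                     artifacts: ArtifactsConfig | None = None,
                     seed: int | None = None) -> Dataset:
    """Render a full synthetic recording with ground-truth linkage.

    Cells are interleaved by entry time, so frames can contain several
    cells.  Artifact injection adds (a) extra cells that first appear
    mid-channel ("impossible" trajectories, which tracking must reject)
    and (b) single concave crescent frames on a fraction of cells (which
    the hull-ratio filter must reject); counts are deterministic
    ``round(fraction * n)``.
    """
    artifacts = artifacts or ArtifactsConfig()
    seed = acquisition.seed if seed is None else seed
    n = len(population)
    n_impossible = int(round(artifacts.impossible_fraction * n))
    n_concave = int(round(artifacts.concave_fraction * n))

    inj_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0xA2,)))
    population = list(population)
    next_id = max((c.cell_id for c in population), default=-1) + 1
    last_entry = max((c.entry_time for c in population), default=0.0)
    injected_ids = []
    for i in range(n_impossible):
        src = population[int(inj_rng.integers(0, n))]
        cid = next_id + i
        injected_ids.append(cid)
        population.append(CellParams(
            cell_id=cid, phenotype=src.phenotype, radius=src.radius,
            gain=src.gain, tau=src.tau,
            entry_time=float(last_entry + (i + 1) * 0.02),
            boundary_noise_sd=src.boundary_noise_sd,
            y_offset=src.y_offset,
            start_x=artifacts.impossible_start_x))
    concave_ids = set(
        int(i) for i in inj_rng.choice(n, size=n_concave, replace=False)
    ) if n_concave else set()

    detections: list[Detection] = []
    n_frames = 0
    all_states = simulate_trajectories(population, geometry, acquisition)
    for cell, states in zip(population, all_states):
        render_rng = _cell_rng(seed, cell.cell_id, purpose=1)
        concave_frame = None
        if cell.cell_id in concave_ids and len(states) > 4:
            concave_frame = int(render_rng.integers(2, len(states) - 2))
        for j, st in enumerate(states):
            frame_index = int(round(st.t * acquisition.fps))
            if j == concave_frame:
                patch = crescent_patch(cell.radius / acquisition.pixel_size,
                                       artifacts.concave_bite_scale)
                cc = (st.x - acquisition.x_origin) / acquisition.pixel_size
                cr = (acquisition.frame_shape[0] / 2.0
                      + cell.y_offset / acquisition.pixel_size)
                off = (int(round(cr - patch.shape[0] / 2)),
                       int(round(cc - patch.shape[1] / 2)))
                patch = patch.copy()
            else:
                try:
                    patch, off = render_patch(
                        st, acquisition, noise_sd=cell.boundary_noise_sd,
                        rng=render_rng, y_offset=cell.y_offset)
                except ValueError:
                    # cell not fully inside the camera field of view yet
                    continue
            truth = {
                "cell_id": int(cell.cell_id),
                "phenotype": cell.phenotype,
                "x": st.x, "t": st.t, "d_true": st.d_true,
                "a": st.a, "b": st.b,
                "artifact": ("impossible_start" if cell.start_x is not None
                             else ("concave_frame" if j == concave_frame
                                   else None)),
            }
            detections.append(_detection_from_patch(
                frame_index, patch, off, acquisition, truth))
            n_frames = max(n_frames, frame_index + 1)

    detections.sort(key=lambda d: (d.frame_index, d.centroid[0],
                                   d.truth["cell_id"]))
    return Dataset(
        detections=detections,
        frame_shape=acquisition.frame_shape,
        pixel_size=acquisition.pixel_size,
        fps=acquisition.fps,
        n_frames=n_frames,
        cells=population,
        meta={
            "seed": int(seed),
            "x_origin_um": acquisition.x_origin,
            "n_cells": n,
            "n_injected_impossible": n_impossible,
            "injected_cell_ids": injected_ids,
            "concave_cell_ids": sorted(concave_ids),
            "geometry": geometry.to_dict(),
        },
    )
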