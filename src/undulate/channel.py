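"""Parametric model of the undulating microchannel.

The channel is a constriction-cavity-constriction sequence (nominally
25/50/25 µm wide, 50 µm per region, 20 µm tall) fed from a much wider
inlet.  Cells advected along the centerline experience a velocity that
varies inversely with the local cross-section; the axial velocity
gradient dv/dx acts as a proxy for the shear stress that deforms them:
positive entering each constriction (extension along the flow axis),
negative on expansion into the cavity and outlet, and zero at the cavity
midpoint where cells relax back to a sphere.

The full 3-D flow field is deliberately reduced to this 1-D
mass-conservation profile: only the shape of the centerline dv/dx is
needed to drive the deformation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# A logistic step reaches 10%/90% of its amplitude at u = ±ln(9)·s, so the
# 10-90% transition width is 2·ln(9) ≈ 4.394 internal scale units.
_LOGISTIC_10_90 = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry of the undulating channel, all lengths in µm.

    ``x = 0`` is the entrance of the first constriction and increases
    along the flow.  ``transition_scale`` is the 10-90% width of the
    smoothed steps between regions.  ``alignment_window`` is the axial
    span over which trajectories are analysed and aligned.
    """

    region_lengths: tuple[float, float, float] = (50.0, 50.0, 50.0)
    region_widths: tuple[float, float, float] = (25.0, 50.0, 25.0)
    height: float = 20.0
    inlet_effective_width: float = 60.0
    transition_scale: float = 10.0
    alignment_window: tuple[float, float] = (-30.0, 170.0)

    def __post_init__(self) -> None:
        if self.transition_scale <= 0:
            raise ValueError("transition_scale must be positive")
        if any(w <= 0 for w in self.region_widths) or self.height <= 0:
            raise ValueError("widths and height must be positive")

    @property
    def total_length(self) -> float:
        return float(sum(self.region_lengths))

    @property
    def boundaries(self) -> np.ndarray:
        """x positions of the region interfaces: entrance, cavity start,
        cavity end, outlet."""
        return np.concatenate([[0.0], np.cumsum(self.region_lengths)])

    @property
    def cavity_span(self) -> tuple[float, float]:
        b = self.boundaries
        return float(b[1]), float(b[2])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        d = dict(d)
        for key in ("region_lengths", "region_widths", "alignment_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _steps(geometry: ChannelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Step positions and width increments of the piecewise profile."""
    widths = [geometry.inlet_effective_width, *geometry.region_widths,
              geometry.inlet_effective_width]
    positions = geometry.boundaries
    deltas = np.diff(np.asarray(widths, dtype=float))
    return positions, deltas


def width_profile(geometry: ChannelGeometry, x) -> np.ndarray | float:
    """Smooth channel width w(x) in µm.

    Logistic transitions of 10-90% width ``transition_scale`` interpolate
    the stepped inlet→25→50→25→outlet profile; far upstream the width
    asymptotes to ``inlet_effective_width``.
    """
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("x must be finite")
    s = geometry.transition_scale / _LOGISTIC_10_90
    positions, deltas = _steps(geometry)
    w = np.full_like(x_arr, geometry.inlet_effective_width, dtype=float)
    for x0, dw in zip(positions, deltas):
        # numerically safe logistic
        w = w + dw / (1.0 + np.exp(np.clip(-(x_arr - x0) / s, -500, 500)))
    return w if w.ndim else float(w)


def width_gradient(geometry: ChannelGeometry, x) -> np.ndarray | float:
    """Analytic dw/dx of :func:`width_profile` (µm/µm)."""
    x_arr = np.asarray(x, dtype=float)
    s = geometry.transition_scale / _LOGISTIC_10_90
    positions, deltas = _steps(geometry)
    g = np.zeros_like(x_arr, dtype=float)
    for x0, dw in zip(positions, deltas):
        sig = 1.0 / (1.0 + np.exp(np.clip(-(x_arr - x0) / s, -500, 500)))
        g = g + dw * sig * (1.0 - sig) / s
    return g if g.ndim else float(g)


# Calibrated so that a tracer crosses x ∈ [0, 150] µm in ~30 frames at
# 11000 fps and 1 µL/min (units: µm³ · s⁻¹ per (µL/min), folded constant).
DEFAULT_VELOCITY_SCALE = 3.748e7


def centerline_velocity(geometry: ChannelGeometry, flow_rate: float, x,
                        velocity_scale: float = DEFAULT_VELOCITY_SCALE):
    """Centerline advection speed v(x) in µm/s.

    Mass conservation in a duct of varying width gives
    ``v = velocity_scale · flow_rate / (w(x) · height)``; the scale folds
    the flow-focusing and profile factors into one calibration constant.
    """
    if flow_rate <= 0:
        raise ValueError("flow_rate must be positive")
    if velocity_scale <= 0:
        raise ValueError("velocity_scale must be positive")
    w = width_profile(geometry, x)
    return velocity_scale * flow_rate / (np.asarray(w) * geometry.height) \
        if np.ndim(x) else velocity_scale * flow_rate / (w * geometry.height)


def stress_proxy(geometry: ChannelGeometry, flow_rate: float, x,
                 velocity_scale: float = DEFAULT_VELOCITY_SCALE):
    """Axial velocity gradient dv/dx in 1/s, the shear-stress proxy.

    Analytic: v = C/w(x) ⇒ dv/dx = −C · w'(x) / w(x)².  Positive when the
    channel narrows (cell stretched along the flow), negative when it
    widens, zero at the cavity midpoint.
    """
    if flow_rate <= 0:
        raise ValueError("flow_rate must be positive")
    c = velocity_scale * flow_rate / geometry.height
    w = np.asarray(width_profile(geometry, x), dtype=float)
    dw = np.asarray(width_gradient(geometry, x), dtype=float)
    out = -c * dw / w**2
    return out if out.ndim else float(out)


def transit_frame_count(geometry: ChannelGeometry, flow_rate: float,
                        fps: float,
                        velocity_scale: float = DEFAULT_VELOCITY_SCALE,
                        span: tuple[float, float] | None = None) -> float:
    """Number of frames a tracer spends in ``span`` (default [0, L])."""
    if span is None:
        span = (0.0, geometry.total_length)
    xs = np.linspace(span[0], span[1], 2001)
    v = centerline_velocity(geometry, flow_rate, xs, velocity_scale)
    transit = np.trapezoid(1.0 / v, xs)
    return float(transit * fps)


def cavity_zero_crossing(geometry: ChannelGeometry) -> float:
    """x position inside the cavity where dv/dx crosses zero (µm)."""
    lo, hi = geometry.cavity_span
    xs = np.linspace(lo, hi, 4001)
    dv = stress_proxy(geometry, 1.0, xs)
    sign = np.sign(dv)
    idx = np.nonzero(np.diff(sign) > 0)[0]
    if idx.size == 0:
        raise RuntimeError("no zero crossing found in cavity")
    i = idx[0]
    # linear interpolation between bracketing samples
    x0, x1, y0, y1 = xs[i], xs[i + 1], dv[i], dv[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
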