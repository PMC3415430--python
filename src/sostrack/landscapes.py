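"""Parametric 2D stimulus landscapes with analytic gradients.

Three field shapes cover the common single-animal orientation assays:

* ``linear`` — a constant spatial gradient, e.g. a thermal gradient of
  0.1 degC/mm across the arena;
* ``radial`` — an exponentially decaying odor plume around a point source,
  v(p) = peak * exp(-|p - source| / decay_length);
* ``sideways_light`` — light falling in from one side, decaying
  exponentially with distance from the source line, plus a lit/shadow
  half-plane used for body-surface exposure.

A gridded landscape (bilinear interpolation over a CSV grid) is provided
for empirically measured maps. All positions are arena millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from sostrack.errors import FlatFieldError, SosError


def _unit_vector(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


@dataclass(frozen=True)
class LinearLandscape:
    """v(p) = ref_value + slope * ((p - ref_point) . direction)."""

    slope: float                       # units per mm
    direction: tuple[float, float] = (1.0, 0.0)
    ref_point: tuple[float, float] = (0.0, 0.0)
    ref_value: float = 0.0
    units: str = "degC"
    kind: str = "linear"

    def field_at(self, p) -> float:
        u = _unit_vector(self.direction)
        d = np.asarray(p, float) - np.asarray(self.ref_point, float)
        return float(self.ref_value + self.slope * d.dot(u))

    def gradient_at(self, p) -> np.ndarray:
        return self.slope * _unit_vector(self.direction)


@dataclass(frozen=True)
class RadialLandscape:
    """v(p) = peak * exp(-|p - source| / decay_length)."""

    source: tuple[float, float]
    peak: float
    decay_length: float
    units: str = "uM"
    kind: str = "radial"

    def field_at(self, p) -> float:
        r = np.linalg.norm(np.asarray(p, float) - np.asarray(self.source, float))
        return float(self.peak * np.exp(-r / self.decay_length))

    def gradient_at(self, p) -> np.ndarray:
        d = np.asarray(p, float) - np.asarray(self.source, float)
        r = np.linalg.norm(d)
        if r == 0:
            raise SosError("radial gradient undefined at the source point")
        # points toward the source (field increases toward it)
        return -(d / r) * self.peak * np.exp(-r / self.decay_length) / self.decay_length


@dataclass(frozen=True)
class SidewaysLightLandscape:
    """Sideways illumination decaying with distance from a source line.

    The source line passes through ``source_point`` perpendicular to the
    unit ``normal``; intensity is I0 * exp(-d / decay_length) with d the
    distance from that line. The lit half-plane (used for contour exposure)
    lies on the side of ``boundary_point`` that ``normal`` points away
    from, i.e. a point is lit when (p - boundary_point) . normal <= 0
    (closer to the light than the shadow boundary).
    """

    source_point: tuple[float, float]
    intensity_at_source: float
    decay_length: float
    normal: tuple[float, float] = (1.0, 0.0)     # direction of increasing distance
    boundary_point: tuple[float, float] | None = None
    units: str = "lux"
    kind: str = "sideways_light"

    def _signed_distance(self, p) -> float:
        u = _unit_vector(self.normal)
        return float((np.asarray(p, float) - np.asarray(self.source_point, float)).dot(u))

    def field_at(self, p) -> float:
        d = abs(self._signed_distance(p))
        return float(self.intensity_at_source * np.exp(-d / self.decay_length))

    def gradient_at(self, p) -> np.ndarray:
        s = self._signed_distance(p)
        u = _unit_vector(self.normal)
        if s == 0:
            return 0.0 * u
        return -np.sign(s) * u * self.intensity_at_source * \
            np.exp(-abs(s) / self.decay_length) / self.decay_length

    def lit_signed_distance(self, p) -> float:
        """Negative = lit, positive = shadow, zero = on the boundary."""
        b = self.boundary_point if self.boundary_point is not None else self.source_point
        u = _unit_vector(self.normal)
        return float((np.asarray(p, float) - np.asarray(b, float)).dot(u))


@dataclass(frozen=True)
class GriddedLandscape:
    """Bilinear interpolation over a measured (x, y, value) grid."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray        # shape (len(y), len(x))
    units: str = "a.u."
    kind: str = "gridded"

    def _interp(self):
        return RegularGridInterpolator(
            (np.asarray(self.y, float), np.asarray(self.x, float)),
            np.asarray(self.values, float), bounds_error=False, fill_value=None)

    def field_at(self, p) -> float:
        x, y = np.asarray(p, float)
        return float(self._interp()((y, x)))

    def gradient_at(self, p, h: float = 1e-4) -> np.ndarray:
        f = self._interp()
        x, y = np.asarray(p, float)
        gx = (f((y, x + h)) - f((y, x - h))) / (2 * h)
        gy = (f((y + h, x)) - f((y - h, x))) / (2 * h)
        return np.array([float(gx), float(gy)])

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "a.u.") -> "GriddedLandscape":
        import pandas as pd
        df = pd.read_csv(path)
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        grid = df.pivot(index="y", columns="x", values="value").loc[ys, xs].to_numpy()
        return cls(x=xs, y=ys, values=grid, units=units)


def field_at(landscape, p) -> float:
    """Stimulus intensity at an arena point (mm)."""
    return landscape.field_at(p)


def gradient_at(landscape, p) -> np.ndarray:
    """Analytic spatial gradient (units/mm) at an arena point."""
    return landscape.gradient_at(p)


def sample_along_skeleton(landscape, skeleton_mm) -> tuple[np.ndarray, np.ndarray]:
    """Field values at each skeleton point (head first) and the differences
    relative to the head (first difference is zero by construction)."""
    skeleton_mm = np.asarray(skeleton_mm, dtype=float)
    if skeleton_mm.size == 0:
        raise SosError("empty skeleton")
    values = np.array([landscape.field_at(p) for p in skeleton_mm])
    return values, values - values[0]


def _lit_fraction(landscape: SidewaysLightLandscape, pts: np.ndarray) -> tuple[float, float]:
    """(lit arc length, total arc length) of an open polyline, splitting
    edges at the lit/shadow boundary crossing."""
    s = np.array([landscape.lit_signed_distance(p) for p in pts])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    lit = 0.0
    for i in range(len(seg)):
        s0, s1 = s[i], s[i + 1]
        if s0 <= 0 and s1 <= 0:
            lit += seg[i]
        elif s0 > 0 and s1 > 0:
            continue
        else:
            t = s0 / (s0 - s1)          # crossing parameter along the edge
            lit_frac = t if s0 <= 0 else 1 - t
            lit += seg[i] * lit_frac
    return lit, float(seg.sum())


def contour_light_fraction(landscape: SidewaysLightLandscape,
                           contour_mm) -> float:
    """Percentage of the contour arc length inside the lit half-plane.

    Edges crossing the lit/shadow boundary are split at the crossing point,
    so the result is independent of contour point density.
    """
    contour_mm = np.asarray(contour_mm, dtype=float)
    if len(contour_mm) < 3:
        raise SosError("contour must be a closed polygon (>= 3 points)")
    closed = np.vstack([contour_mm, contour_mm[:1]])
    lit, total = _lit_fraction(landscape, closed)
    if total == 0:
        raise SosError("degenerate contour")
    return float(np.clip(100.0 * lit / total, 0.0, 100.0))


def side_light_fractions(landscape: SidewaysLightLandscape, contour_mm,
                         head_mm, tail_mm) -> dict:
    """Light fraction on the left and right body sides.

    The contour is split into two arcs at the points nearest the head and
    tail; each arc is classed left or right by the sign of its mean cross
    product with the tail-to-head axis (y points down, so positive cross =
    right side).
    """
    contour_mm = np.asarray(contour_mm, dtype=float)
    head_mm = np.asarray(head_mm, float)
    tail_mm = np.asarray(tail_mm, float)
    i_h = int(np.argmin(np.linalg.norm(contour_mm - head_mm, axis=1)))
    i_t = int(np.argmin(np.linalg.norm(contour_mm - tail_mm, axis=1)))
    if i_h == i_t:
        raise SosError("head and tail collapse on the contour")
    lo, hi = sorted((i_h, i_t))
    arc_a = contour_mm[lo:hi + 1]
    arc_b = np.vstack([contour_mm[hi:], contour_mm[:lo + 1]])
    axis = head_mm - tail_mm
    out = {}
    for arc in (arc_a, arc_b):
        rel = arc - tail_mm
        cross = axis[0] * rel[:, 1] - axis[1] * rel[:, 0]
        side = "right" if np.mean(cross) > 0 else "left"
        lit, total = _lit_fraction(landscape, arc)
        out[side] = float(np.clip(100.0 * lit / total, 0.0, 100.0)) if total > 0 else 0.0
    return out


def bearing_to_gradient(landscape, p, axis) -> float:
    """Angle in degrees, within [0, 180], between a body/motion axis and the
    local stimulus gradient. Raises ``FlatFieldError`` on a zero gradient."""
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise SosError("zero axis vector")
    g = np.asarray(landscape.gradient_at(p), dtype=float)
    gn = np.linalg.norm(g)
    if gn == 0:
        raise FlatFieldError("flat_field: zero gradient")
    cosang = np.clip(axis.dot(g) / (np.linalg.norm(axis) * gn), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def landscape_from_config(cfg: dict):
    """Build a landscape from a config mapping ``{kind: ..., params...}``."""
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    if kind == "linear":
        return LinearLandscape(**cfg)
    if kind == "radial":
        return RadialLandscape(**cfg)
    if kind == "sideways_light":
        return SidewaysLightLandscape(**cfg)
    if kind == "gridded":
        return GriddedLandscape.from_csv(cfg.pop("path"), **cfg)
    raise SosError(f"unknown landscape kind {kind!r}")
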