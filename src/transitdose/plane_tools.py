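"""Profile normalization, 2D dose-plane synthesis, and profile extraction.

A 2D absolute dose plane at a given depth is synthesized by cross-multiplying
the central-axis-normalized crossline and inline scan profiles and scaling by
the measured central-axis point dose:

    plane(x, y) = n_x(x) * n_y(y) * D_cax

The construction is exactly separable by design; real planes are not exactly
separable in the corners, which is why the construction is validated against
2D-array measurements rather than assumed.  Profiles can be re-extracted from
planes along the crossline, inline, or diagonal axes (diagonal positions are
signed radial distances along the diagonal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .beam_data import BeamDataError, DosePlane, ScanProfile, _as_array


@dataclass(frozen=True)
class RelativeProfile:
    """A scan profile normalized to the central axis (value(0) = 1)."""

    axis: str
    depth: float
    field_size: float
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", _as_array(self.positions, "positions"))
        object.__setattr__(self, "values", _as_array(self.values, "values"))
        cax = float(np.interp(0.0, self.positions, self.values))
        if abs(cax - 1.0) > 1e-9:
            raise BeamDataError(f"relative profile must be 1 on the central axis, got {cax:.6g}")

    def value_at(self, position: float) -> float:
        if not (self.positions[0] - 1e-12 <= position <= self.positions[-1] + 1e-12):
            raise BeamDataError(f"position {position:g} outside profile range")
        return float(np.interp(position, self.positions, self.values))


def normalize_profile(p: ScanProfile | RelativeProfile) -> RelativeProfile:
    """Divide a profile by its central-axis value (interpolated if unsampled).

    Idempotent and scale-invariant: normalizing an already-relative profile
    returns it unchanged.
    """
    if isinstance(p, RelativeProfile):
        return p
    cax = p.cax_value
    if cax <= 0:
        raise BeamDataError("central-axis value must be positive for normalization")
    return RelativeProfile(
        axis=p.axis, depth=p.depth, field_size=p.field_size,
        positions=p.positions, values=p.values / cax,
    )


def _symmetric_grid(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Uniform grid containing 0, spanning as much of [lo, hi] as fits."""
    half = min(-lo, hi)
    n = int(math.floor(half / spacing + 1e-9))
    return np.arange(-n, n + 1) * spacing


def synthesize_plane(
    px: ScanProfile | RelativeProfile,
    py: ScanProfile | RelativeProfile,
    d_cax: float,
    spacing: float = 0.2,
) -> DosePlane:
    """Cross-multiply two orthogonal profiles into an absolute dose plane.

    ``px`` supplies the x (crossline) dependence, ``py`` the y (inline)
    dependence; both must be at the same depth and field size.  The grid is
    symmetric about the central axis at the given spacing (default 0.2 cm,
    the scan resolution), and plane(0, 0) = ``d_cax``.
    """
    if abs(px.depth - py.depth) > 1e-9:
        raise BeamDataError(f"profile depths differ: {px.depth:g} vs {py.depth:g}")
    if abs(px.field_size - py.field_size) > 1e-9:
        raise BeamDataError("profile field sizes differ")
    if not d_cax > 0:
        raise BeamDataError("central-axis dose must be positive")
    if not spacing > 0:
        raise BeamDataError("spacing must be positive")
    nx = normalize_profile(px)
    ny = normalize_profile(py)
    x = _symmetric_grid(nx.positions[0], nx.positions[-1], spacing)
    y = _symmetric_grid(ny.positions[0], ny.positions[-1], spacing)
    vx = np.interp(x, nx.positions, nx.values)
    vy = np.interp(y, ny.positions, ny.values)
    dose = np.outer(vy, vx) * d_cax
    return DosePlane(depth=px.depth, field_size=px.field_size,
                     x_coords=x, y_coords=y, dose=np.clip(dose, 0.0, None))


def _plane_interpolator(plane: DosePlane) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (plane.y_coords, plane.x_coords), plane.dose,
        method="linear", bounds_error=True,
    )


def extract_profile(plane: DosePlane, axis: str, spacing: float = 0.2) -> ScanProfile:
    """Sample a plane along an axis through the central axis.

    Bilinear interpolation; diagonal positions are radial distances along the
    x = y diagonal (a position s maps to the point (s/sqrt(2), s/sqrt(2))).
    """
    if not spacing > 0:
        raise BeamDataError("spacing must be positive")
    if axis == "crossline":
        half = min(-plane.x_coords[0], plane.x_coords[-1])
    elif axis == "inline":
        half = min(-plane.y_coords[0], plane.y_coords[-1])
    elif axis == "diagonal":
        half = min(-plane.x_coords[0], plane.x_coords[-1],
                   -plane.y_coords[0], plane.y_coords[-1]) * math.sqrt(2.0)
    else:
        raise BeamDataError(f"unknown axis {axis!r}")
    n = int(math.floor(half / spacing + 1e-9))
    s = np.arange(-n, n + 1) * spacing
    if axis == "crossline":
        pts = np.column_stack([np.zeros_like(s), s])
    elif axis == "inline":
        pts = np.column_stack([s, np.zeros_like(s)])
    else:
        pts = np.column_stack([s / math.sqrt(2.0), s / math.sqrt(2.0)])
    values = _plane_interpolator(plane)(pts)
    return ScanProfile(axis=axis, depth=plane.depth, field_size=plane.field_size,
                       positions=s, values=values)


@dataclass(frozen=True)
class ProfileComparison:
    """Pointwise difference (b - a) between two relative profiles.

    Differences are resampled onto the reference profile's positions and
    labelled by region: ``field`` is the inner 80% of the projected field
    width, ``shoulder`` the remaining in-field band, ``out`` everything else.
    """

    positions: np.ndarray
    delta: np.ndarray
    region: np.ndarray
    max_abs_field: float
    max_abs_shoulder: float


def compare_relative_profiles(
    a: RelativeProfile,
    b: RelativeProfile,
    ssd: float = 100.0,
) -> ProfileComparison:
    """Resample ``b`` onto ``a``'s positions and difference them by region.

    The field edge is the geometric projection of the reference profile's
    field size to its depth: half-width = fs * (ssd + depth) / (2 * 100)
    (field size defined at 100 cm from the source).
    """
    lo = max(a.positions[0], b.positions[0])
    hi = min(a.positions[-1], b.positions[-1])
    if lo >= hi:
        raise BeamDataError("profiles do not overlap")
    sel = (a.positions >= lo - 1e-12) & (a.positions <= hi + 1e-12)
    pos = a.positions[sel]
    delta = np.interp(pos, b.positions, b.values) - a.values[sel]
    half_width = a.field_size * (ssd + a.depth) / 200.0
    absp = np.abs(pos)
    region = np.where(absp <= 0.8 * half_width, "field",
                      np.where(absp <= half_width, "shoulder", "out"))
    in_field = region == "field"
    in_shoulder = region == "shoulder"
    return ProfileComparison(
        positions=pos, delta=delta, region=region,
        max_abs_field=float(np.abs(delta[in_field]).max()) if in_field.any() else float("nan"),
        max_abs_shoulder=float(np.abs(delta[in_shoulder]).max()) if in_shoulder.any() else float("nan"),
    )
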