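"""2D absolute gamma-index analysis (dose difference + distance to agreement).

For every reference point r the gamma index against an evaluated plane E is

    gamma(r) = min over e of sqrt( ((E(e) - R(r)) / dD)^2 + (|e - r| / dta)^2 )

where dD is the dose criterion expressed in absolute dose (a percentage of a
global normalization dose — by default the reference plane's central-axis
dose, since planes are made absolute via the measured CAX point dose) and
dta the distance-to-agreement criterion.  The evaluated plane is bilinearly
subsampled on a fine lattice (``subsample_step``); candidate positions are
searched out to ``search_radius_factor * dta``.  A point passes when
gamma <= 1.  Pass rates are reported over square field ROIs: the full
projected field area and the central 80% (linear edge scaling).

The search enumerates subsample offsets in order of increasing distance and
stops once the distance term alone exceeds every point's running minimum,
which is exact (identical to exhaustive search) but far cheaper on planes
that mostly agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .beam_data import BeamDataError, DosePlane

NORMALIZATIONS = ("global_cax", "global_max")


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria; defaults are the clinical 3%/3 mm global test."""

    dose_percent: float = 3.0
    dta_mm: float = 3.0
    normalization: str = "global_cax"
    search_radius_factor: float = 3.0
    subsample_step_mm: float = 0.3

    def __post_init__(self):
        if not self.dose_percent > 0:
            raise BeamDataError("dose criterion must be positive")
        if not self.dta_mm > 0:
            raise BeamDataError("DTA criterion must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise BeamDataError(f"normalization must be one of {NORMALIZATIONS}")
        if not self.search_radius_factor >= 1:
            raise BeamDataError("search radius factor must be >= 1")
        if self.subsample_step_mm > self.dta_mm / 3 + 1e-12:
            raise BeamDataError("subsample step must be <= dta/3 for a convergent search")


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values plus pass rates over the field ROI masks."""

    gamma: np.ndarray
    criteria: GammaCriteria
    roi_masks: Mapping[str, np.ndarray]
    pass_rate_full: float
    pass_rate_80: float


def field_roi(
    plane: DosePlane,
    field_size: float,
    depth: float,
    ssd: float = 100.0,
    area_fraction: float = 1.0,
) -> np.ndarray:
    """Square ROI mask centred on the beam axis.

    The 100% edge is the field size projected to the measurement plane,
    ``fs * (ssd + depth) / 100`` (field defined at 100 cm from the source);
    the 80% ROI scales the edge linearly by 0.8.
    """
    if area_fraction <= 0 or area_fraction > 1:
        raise BeamDataError("area_fraction must be in (0, 1]")
    half = area_fraction * field_size * (ssd + depth) / 100.0 / 2.0
    if half > -plane.x_coords[0] + 1e-9 or half > plane.x_coords[-1] + 1e-9 \
            or half > -plane.y_coords[0] + 1e-9 or half > plane.y_coords[-1] + 1e-9:
        raise BeamDataError(
            f"ROI half-width {half:g} cm exceeds plane extent"
        )
    xm = np.abs(plane.x_coords) <= half + 1e-9
    ym = np.abs(plane.y_coords) <= half + 1e-9
    return np.outer(ym, xm)


def pass_rates(gamma: np.ndarray, masks: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Percent of masked points with gamma <= 1, per mask."""
    out = {}
    for name, mask in masks.items():
        if mask.shape != gamma.shape:
            raise BeamDataError(f"mask {name!r} not aligned with the gamma grid")
        n = int(mask.sum())
        if n == 0:
            raise BeamDataError(f"mask {name!r} is empty")
        out[name] = float(100.0 * np.count_nonzero(gamma[mask] <= 1.0) / n)
    return out


def _sorted_offsets(radius_cm: float, step_cm: float) -> np.ndarray:
    """All (dx, dy) lattice offsets within the search radius, nearest first."""
    k = int(math.floor(radius_cm / step_cm + 1e-9))
    ii, jj = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
    dx = ii.ravel() * step_cm
    dy = jj.ravel() * step_cm
    dist = np.hypot(dx, dy)
    keep = dist <= radius_cm + 1e-12
    dx, dy, dist = dx[keep], dy[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return np.column_stack([dx[order], dy[order], dist[order]])


def gamma_index(
    ref: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria = GammaCriteria(),
    ssd: float = 100.0,
) -> GammaResult:
    """Absolute gamma of ``evaluated`` against the reference plane.

    Planes must be at the same depth and the evaluated grid must cover the
    reference grid; search offsets that fall outside the evaluated grid are
    excluded from the minimization.  The result carries 100% and central-80%
    field ROI pass rates derived from the reference plane's field size,
    depth, and the given SSD.
    """
    if abs(ref.depth - evaluated.depth) > 1e-9:
        raise BeamDataError("planes are at different depths")
    if (evaluated.x_coords[0] > ref.x_coords[0] + 1e-9
            or evaluated.x_coords[-1] < ref.x_coords[-1] - 1e-9
            or evaluated.y_coords[0] > ref.y_coords[0] + 1e-9
            or evaluated.y_coords[-1] < ref.y_coords[-1] - 1e-9):
        raise BeamDataError("evaluated grid too small: it must cover the reference grid")

    if criteria.normalization == "global_cax":
        norm_dose = ref.cax_dose
    else:
        norm_dose = float(ref.dose.max())
    if norm_dose <= 0:
        raise BeamDataError("normalization dose must be positive")

    dcrit = criteria.dose_percent / 100.0 * norm_dose
    dta_cm = criteria.dta_mm / 10.0
    step_cm = criteria.subsample_step_mm / 10.0
    radius_cm = criteria.search_radius_factor * dta_cm

    interp = RegularGridInterpolator(
        (evaluated.y_coords, evaluated.x_coords), evaluated.dose,
        method="linear", bounds_error=False, fill_value=np.nan,
    )
    gx, gy = np.meshgrid(ref.x_coords, ref.y_coords)
    pts = np.column_stack([gy.ravel(), gx.ravel()])
    rvals = ref.dose.ravel()

    # zero-offset seed: pure dose difference
    ev0 = interp(pts)
    running = np.where(np.isnan(ev0), np.inf, ((ev0 - rvals) / dcrit) ** 2)

    for dx, dy, dist in _sorted_offsets(radius_cm, step_cm):
        if dist == 0.0:
            continue
        dist_term = (dist / dta_cm) ** 2
        improvable = running > dist_term
        if not improvable.any():
            break
        q = pts[improvable] + np.array([dy, dx])
        ev = interp(q)
        cand = dist_term + ((ev - rvals[improvable]) / dcrit) ** 2
        cand = np.where(np.isnan(ev), np.inf, cand)
        running[improvable] = np.minimum(running[improvable], cand)

    gamma = np.sqrt(running).reshape(ref.dose.shape)
    masks = {
        "full": field_roi(ref, ref.field_size, ref.depth, ssd, 1.0),
        "central80": field_roi(ref, ref.field_size, ref.depth, ssd, 0.8),
    }
    rates = pass_rates(gamma, masks)
    return GammaResult(
        gamma=gamma, criteria=criteria, roi_masks=masks,
        pass_rate_full=rates["full"], pass_rate_80=rates["central80"],
    )
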