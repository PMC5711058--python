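"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from transitdose.beam_data import (
    BeamDataset,
    DosePlane,
    OutputFactorTable,
    PDDCurve,
    ScanProfile,
)
from transitdose import synthetic_data as sd


# ---------------------------------------------------------------------------
# independent gamma oracle: exhaustive fine-grid search, no shortcuts
# ---------------------------------------------------------------------------

def _bilinear(plane: DosePlane, x: float, y: float) -> float:
    """Plain bilinear interpolation; NaN outside the grid."""
    xs, ys = plane.x_coords, plane.y_coords
    if x < xs[0] or x > xs[-1] or y < ys[0] or y > ys[-1]:
        return math.nan
    i = min(np.searchsorted(xs, x, side="right") - 1, xs.size - 2)
    j = min(np.searchsorted(ys, y, side="right") - 1, ys.size - 2)
    tx = (x - xs[i]) / (xs[i + 1] - xs[i])
    ty = (y - ys[j]) / (ys[j + 1] - ys[j])
    d = plane.dose
    return ((1 - ty) * ((1 - tx) * d[j, i] + tx * d[j, i + 1])
            + ty * ((1 - tx) * d[j + 1, i] + tx * d[j + 1, i + 1]))


def brute_force_gamma(ref: DosePlane, ev: DosePlane, dose_percent: float,
                      dta_mm: float, search_radius_factor: float = 3.0,
                      subsample_step_mm: float | None = None,
                      normalization: str = "global_cax") -> np.ndarray:
    """Exhaustive gamma-by-definition on the subsample lattice.

    Loops every reference point against every lattice offset within the
    search radius with no early termination — the definition, evaluated
    directly.
    """
    if subsample_step_mm is None:
        subsample_step_mm = dta_mm / 10.0
    norm = _bilinear(ref, 0.0, 0.0) if normalization == "global_cax" else float(ref.dose.max())
    dcrit = dose_percent / 100.0 * norm
    dta = dta_mm / 10.0
    step = subsample_step_mm / 10.0
    radius = search_radius_factor * dta
    k = int(math.floor(radius / step + 1e-9))
    offsets = [(i * step, j * step) for i in range(-k, k + 1) for j in range(-k, k + 1)
               if math.hypot(i * step, j * step) <= radius + 1e-12]

    out = np.empty_like(ref.dose)
    for jy, y in enumerate(ref.y_coords):
        for ix, x in enumerate(ref.x_coords):
            r = ref.dose[jy, ix]
            best = math.inf
            for dx, dy in offsets:
                e = _bilinear(ev, x + dx, y + dy)
                if math.isnan(e):
                    continue
                g2 = ((e - r) / dcrit) ** 2 + (math.hypot(dx, dy) / dta) ** 2
                best = min(best, g2)
            out[jy, ix] = math.sqrt(best)
    return out


def random_small_plane(rng: np.random.Generator, n: int = 7,
                       spacing: float = 0.5, depth: float = 10.0) -> DosePlane:
    """A small random plane for oracle comparisons (doses around 100 cGy).

    Field size 2 cm so the field ROI fits the small grid.
    """
    half = (n - 1) // 2
    coords = np.arange(-half, half + 1) * spacing
    dose = rng.uniform(50.0, 150.0, size=(n, n))
    return DosePlane(depth=depth, field_size=2.0, x_coords=coords,
                     y_coords=coords, dose=dose)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_beam() -> BeamDataset:
    """Hand-made beam with simple piecewise-linear tables (easy arithmetic).

    PDD(10, 6.5) = 85 exactly; OF(10) = 1; d_dmax = 1 cGy/MU.
    """
    depths = np.array([1.5, 6.5, 11.5, 16.5, 21.5, 26.5, 31.5])
    base = np.array([100.0, 85.0, 71.0, 59.5, 50.0, 42.0, 35.5])
    pdd = {}
    for fs, scale in ((5.0, 0.97), (10.0, 1.0), (15.0, 1.02), (20.0, 1.04)):
        vals = base * scale
        vals = vals / vals.max() * 100.0
        pdd[fs] = PDDCurve(field_size=fs, depths=depths, values=vals, dmax=1.5)
    of = OutputFactorTable(field_sizes=[5.0, 10.0, 15.0, 20.0],
                           factors=[0.95, 1.0, 1.04, 1.07])
    return BeamDataset(machine_id="toy", pdd=pdd, of=of, d_dmax=1.0)


@pytest.fixture(scope="session")
def synthetic_beam() -> BeamDataset:
    return sd.generate_beam(sd.CLINAC_LIKE)


@pytest.fixture(scope="session")
def deficit() -> sd.BackscatterDeficitSpec:
    return sd.BackscatterDeficitSpec()


@pytest.fixture()
def gaussian_profiles():
    """A pair of Gaussian crossline/inline profiles at the same depth."""
    pos = np.round(np.arange(-8.0, 8.0 + 1e-9, 0.2), 10)
    vx = 80.0 * np.exp(-(pos / 4.0) ** 2)
    vy = 80.0 * np.exp(-(pos / 3.0) ** 2)
    px = ScanProfile(axis="crossline", depth=10.0, field_size=5.0, positions=pos, values=vx)
    py = ScanProfile(axis="inline", depth=10.0, field_size=5.0, positions=pos, values=vy)
    return px, py
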