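"""Analytic 6 MV beam, measurement, and TPS-emulation generators.

These generators stand in for commissioning scan data and slab-phantom
measurements so that every pipeline stage — dose reconstruction, BCF
derivation, plane synthesis, gamma analysis — can be exercised end to end
with known ground truth.

Beam model
----------
The depth-dose is a buildup/attenuation product,

    p(d) = (1 - exp(-b * (d + s))) * exp(-mu * d),

with the shift s chosen in closed form so the maximum falls exactly at dmax
(default 1.5 cm), normalized to 100 at dmax.  The effective attenuation mu
carries a mild field-size dependence (larger fields fall off more slowly,
as phantom scatter grows).  Default parameters put the beam-quality index
TPR20,10 in the 6 MV range (0.65-0.70); two presets bracket the clinical
beams this package's reference BCF tables describe (0.669 and 0.687).

Off-axis profiles are a flat core with error-function penumbra at the
divergence-scaled field edge, optional gentle horns, and a small
out-of-field tail.  Output factors are a mildly concave increasing
polynomial with OF(10) = 1.

Backscatter-deficit model
-------------------------
The programmed ground truth for BCF derivation: entrance BCF
1 - A(fs) * exp(-k * t) rises to unity with backscatter thickness t; exit
BCF B(fs) - c * (d - 6.5) falls with depth d; both fall with field size.

TPS emulation
-------------
``emulate_tps_plane`` produces dose planes as a planning system would:
``exact`` reproduces the ground truth; ``full_backscatter`` ignores the
backscatter deficit at the exit (overestimating the central axis by exactly
1/BCF - 1); ``shoulder_boost`` raises the in-field shoulder band of the
profile; ``center_dip`` lowers the central region — the characteristic
off-axis failure modes of deterministic-transport and Monte Carlo engines
respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

from .beam_data import (
    BeamDataError,
    BeamDataset,
    DoseMeasurement,
    DosePlane,
    ENTRANCE_EXIT_DEPTH,
    OutputFactorTable,
    PDDCurve,
    ScanProfile,
)
from .dose_engine import dose_full_backscatter
from .plane_tools import synthesize_plane

DEFAULT_FIELD_SIZES = (5.0, 10.0, 15.0, 20.0)
#: Table-layout grids: 7 backscatter thicknesses (entrance), 6 depths (exit).
DEFAULT_ENTRANCE_THICKNESSES = (1.5, 6.5, 11.5, 16.5, 21.5, 26.5, 31.5)
DEFAULT_EXIT_DEPTHS = (6.5, 11.5, 16.5, 21.5, 26.5, 31.5)
DEFAULT_PROFILE_DEPTHS = (1.5, 6.5, 11.5, 16.5, 21.5, 26.5, 31.5)

TPS_MODES = ("exact", "full_backscatter", "shoulder_boost", "center_dip")


@dataclass(frozen=True)
class SyntheticBeamSpec:
    """Parameters of the analytic beam (units in docstrings below).

    mu_eff : effective attenuation beyond buildup, 1/cm
    buildup_rate : electron-buildup rate constant, 1/cm
    dmax : depth of maximum dose, cm
    pdd_fs_slope : fractional change of mu_eff per cm of field size around 10
    of_params : (slope, curvature) of the output-factor polynomial around 10
    penumbra_sigma : penumbra width at the surface, cm
    penumbra_growth : additional penumbra width per cm depth, cm/cm
    horn_amplitude : relative height of in-field horns
    tail : out-of-field transmission level (fraction of CAX)
    ssd : source-to-surface distance, cm
    d_dmax : dose per MU at dmax for the reference field, cGy/MU
    """

    machine_id: str = "synthetic6mv"
    mu_eff: float = 0.0576
    buildup_rate: float = 2.0
    dmax: float = 1.5
    pdd_fs_slope: float = 0.004
    of_params: tuple[float, float] = (0.009, -0.0002)
    penumbra_sigma: float = 0.35
    penumbra_growth: float = 0.012
    horn_amplitude: float = 0.02
    tail: float = 0.02
    ssd: float = 100.0
    d_dmax: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mu_eff <= 0 or self.buildup_rate <= 0 or self.dmax <= 0:
            raise BeamDataError("beam parameters must be positive")


#: Presets bracketing the two clinical 6 MV beams (TPR20,10 0.669 / 0.687).
CLINAC_LIKE = SyntheticBeamSpec(machine_id="clinac-sim", mu_eff=0.0576)
SYNERGY_LIKE = SyntheticBeamSpec(machine_id="synergy-sim", mu_eff=0.0549)


def _mu_for(spec: SyntheticBeamSpec, field_size: float) -> float:
    return spec.mu_eff * (1.0 + spec.pdd_fs_slope * (10.0 - field_size))


def _pdd_shift(mu: float, b: float, dmax: float) -> float:
    # d/dd [(1 - e^{-b(d+s)}) e^{-mu d}] = 0 at d = dmax
    shift = math.log((b + mu) / mu) / b - dmax
    if shift < 0:
        raise BeamDataError(
            "buildup_rate/mu_eff combination puts the dose maximum shallower than dmax"
        )
    return shift


def _raw_pdd(spec: SyntheticBeamSpec, field_size: float, depths: np.ndarray) -> np.ndarray:
    mu = _mu_for(spec, field_size)
    s = _pdd_shift(mu, spec.buildup_rate, spec.dmax)
    return (1.0 - np.exp(-spec.buildup_rate * (depths + s))) * np.exp(-mu * depths)


def generate_pdd(spec: SyntheticBeamSpec, field_size: float,
                 depths: Sequence[float] | None = None) -> PDDCurve:
    """Analytic PDD, normalized to 100 exactly at dmax (dmax is on the grid)."""
    if depths is None:
        depths = np.round(np.arange(0.0, 35.0 + 1e-9, 0.1), 10)
    depths = np.asarray(depths, dtype=float)
    if not np.any(np.abs(depths - spec.dmax) < 1e-9):
        raise BeamDataError("depth grid must contain dmax")
    raw = _raw_pdd(spec, field_size, depths)
    peak = _raw_pdd(spec, field_size, np.array([spec.dmax]))[0]
    return PDDCurve(field_size=field_size, depths=depths,
                    values=raw / peak * 100.0, dmax=spec.dmax)


def field_edge(spec: SyntheticBeamSpec, field_size: float, depth: float) -> float:
    """Divergence-projected field half-width at depth (cm)."""
    return field_size * (spec.ssd + depth) / (2.0 * spec.ssd)


def profile_values(spec: SyntheticBeamSpec, field_size: float, depth: float,
                   positions: np.ndarray) -> np.ndarray:
    """Normalized off-axis ratio: erf-penumbra core, horns, flat tail."""
    edge = field_edge(spec, field_size, depth)
    sigma = spec.penumbra_sigma * (spec.ssd + depth) / spec.ssd + spec.penumbra_growth * depth
    x = np.asarray(positions, dtype=float)
    core = 0.5 * (erf((x + edge) / (sigma * math.sqrt(2.0)))
                  - erf((x - edge) / (sigma * math.sqrt(2.0))))
    horns = 1.0 + spec.horn_amplitude * np.exp(-((np.abs(x) - 0.8 * edge) / (0.15 * edge)) ** 2)
    prof = core * horns + spec.tail * (1.0 - core)
    cax = prof[np.argmin(np.abs(x))] if np.any(np.abs(x) < 1e-12) else np.interp(0.0, x, prof)
    return prof / cax


def generate_beam(
    spec: SyntheticBeamSpec,
    field_sizes: Sequence[float] = DEFAULT_FIELD_SIZES,
    profile_depths: Sequence[float] = DEFAULT_PROFILE_DEPTHS,
    profile_axes: Sequence[str] = ("crossline", "inline"),
    profile_spacing: float = 0.2,
) -> BeamDataset:
    """Full synthetic BeamDataset: PDD per field size, OF table, profiles."""
    pdd = {float(fs): generate_pdd(spec, float(fs)) for fs in field_sizes}
    slope, curv = spec.of_params
    fss = np.asarray(sorted(field_sizes), dtype=float)
    factors = 1.0 + slope * (fss - 10.0) + curv * (fss - 10.0) ** 2
    of = OutputFactorTable(field_sizes=fss, factors=factors)

    profiles = {}
    for fs in field_sizes:
        for depth in profile_depths:
            # symmetric grid out to 1.6x the projected half-field (penumbra + tail)
            half = 1.6 * field_edge(spec, fs, depth)
            n = int(math.floor(half / profile_spacing))
            pos = np.arange(-n, n + 1) * profile_spacing
            vals = profile_values(spec, fs, depth, pos)
            for axis in profile_axes:
                profiles[(axis, float(fs), float(depth))] = ScanProfile(
                    axis=axis, depth=float(depth), field_size=float(fs),
                    positions=pos, values=vals,
                )
    return BeamDataset(machine_id=spec.machine_id, pdd=pdd, of=of,
                       profiles=profiles, d_dmax=spec.d_dmax)


@dataclass(frozen=True)
class BackscatterDeficitSpec:
    """Programmed backscatter deficit (the ground-truth BCF surface).

    Entrance: BCF(fs, t) = 1 - A(fs) * exp(-entrance_decay * t), with
    A(fs) = entrance_amplitude_base + entrance_amplitude_slope * (fs - 5).
    Exit: BCF(fs, d) = min(1, B(fs) - exit_depth_slope * (d - 6.5)), with
    B(fs) = exit_base - exit_base_slope * (fs - 5).  Defaults keep every
    implied BCF within the measured 0.95-1.00 range.
    """

    entrance_amplitude_base: float = 0.015
    entrance_amplitude_slope: float = 0.0021
    entrance_decay: float = 0.35
    exit_base: float = 0.995
    exit_base_slope: float = 0.00093
    exit_depth_slope: float = 0.0006

    def entrance_bcf(self, field_size: float, backscatter_thickness: float) -> float:
        amp = self.entrance_amplitude_base + self.entrance_amplitude_slope * (field_size - 5.0)
        return 1.0 - amp * math.exp(-self.entrance_decay * backscatter_thickness)

    def exit_bcf(self, field_size: float, depth: float) -> float:
        base = self.exit_base - self.exit_base_slope * (field_size - 5.0)
        return min(1.0, base - self.exit_depth_slope * (depth - 6.5))

    def bcf(self, kind: str, field_size: float, key: float) -> float:
        if kind == "entrance":
            return self.entrance_bcf(field_size, key)
        if kind == "exit":
            return self.exit_bcf(field_size, key)
        raise BeamDataError(f"unknown kind {kind!r}")


def generate_measurements(
    beam: BeamDataset,
    deficit: BackscatterDeficitSpec,
    field_sizes: Sequence[float] = DEFAULT_FIELD_SIZES,
    entrance_thicknesses: Sequence[float] = DEFAULT_ENTRANCE_THICKNESSES,
    exit_depths: Sequence[float] = DEFAULT_EXIT_DEPTHS,
    noise_sd: float = 0.005,
    seed: int = 0,
    mu: float = 100.0,
) -> list[DoseMeasurement]:
    """Simulated slab-phantom measurement campaign over the table grid.

    Each dose is the full-backscatter reconstruction times the programmed
    BCF times multiplicative noise (1 + eps).  eps is a zero-mean normal
    with SD ``noise_sd`` truncated at two SDs: setup reproducibility is
    characterized as a *bound* on observed deviation (repeat measurements
    deviate by less than 0.5%), and the truncation also guarantees derived
    BCF ratios stay inside the physically plausible (0.9, 1.01] window.
    A single seeded stream makes the campaign reproducible.
    """
    if noise_sd < 0:
        raise BeamDataError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def _eps() -> float:
        if noise_sd == 0:
            return 0.0
        while True:
            e = rng.normal(0.0, noise_sd)
            if abs(e) <= 2.0 * noise_sd:
                return e
    out = []
    for fs in field_sizes:
        for t in entrance_thicknesses:
            truth = dose_full_backscatter(beam, fs, ENTRANCE_EXIT_DEPTH, mu) \
                * deficit.entrance_bcf(fs, t)
            out.append(DoseMeasurement(
                machine_id=beam.machine_id, field_size=float(fs),
                depth=ENTRANCE_EXIT_DEPTH, backscatter_thickness=float(t),
                dose=truth * (1.0 + _eps()),
                mu=mu,
            ))
        for d in exit_depths:
            truth = dose_full_backscatter(beam, fs, d, mu) * deficit.exit_bcf(fs, d)
            out.append(DoseMeasurement(
                machine_id=beam.machine_id, field_size=float(fs),
                depth=float(d), backscatter_thickness=ENTRANCE_EXIT_DEPTH,
                dose=truth * (1.0 + _eps()),
                mu=mu,
            ))
    return out


@dataclass(frozen=True)
class TPSEmulatorSpec:
    """How the emulated planning system deviates from the ground truth.

    magnitude : fractional size of the perturbation (e.g. 0.05 for 5%)
    onset_depth : shoulder/center perturbations apply at or beyond this depth
    shoulder_band : inner/outer bounds of the boosted band, as fractions of
        the projected field half-width.  The default (0.80, 0.95) is the
        in-field shoulder region — outside the central-80% analysis box but
        short of the penumbra, where distance-to-agreement would rescue the
        comparison — so shoulder failures concentrate in the outer 20% of
        the field area.
    center_fraction : extent of the central dip, as a fraction of the
        projected field half-width
    """

    mode: str = "exact"
    magnitude: float = 0.05
    onset_depth: float = 11.5
    shoulder_band: tuple[float, float] = (0.80, 0.95)
    center_fraction: float = 0.4

    def __post_init__(self):
        if self.mode not in TPS_MODES:
            raise BeamDataError(f"unknown TPS emulation mode {self.mode!r}; choose from {TPS_MODES}")
        if not 0 <= self.magnitude < 1:
            raise BeamDataError("magnitude must be in [0, 1)")


def truth_plane(
    beam: BeamDataset,
    deficit: BackscatterDeficitSpec,
    field_size: float,
    depth: float,
    mu: float = 100.0,
    spacing: float = 0.2,
) -> DosePlane:
    """Ground-truth absolute exit-geometry dose plane.

    Cross-multiplied from the beam's crossline/inline profiles and anchored
    to the deficit-corrected central-axis dose (exit geometry: 1.5 cm of
    backscatter beneath the measurement depth).
    """
    px = beam.profile("crossline", field_size, depth)
    py = beam.profile("inline", field_size, depth)
    d_cax = dose_full_backscatter(beam, field_size, depth, mu) \
        * deficit.exit_bcf(field_size, depth)
    return synthesize_plane(px, py, d_cax, spacing=spacing)


def emulate_tps_plane(
    beam: BeamDataset,
    deficit: BackscatterDeficitSpec,
    emu: TPSEmulatorSpec,
    field_size: float,
    depth: float,
    mu: float = 100.0,
    spacing: float = 0.2,
    ssd: float = 100.0,
) -> DosePlane:
    """Emulated TPS-computed exit dose plane (modes in the class docs)."""
    base = truth_plane(beam, deficit, field_size, depth, mu=mu, spacing=spacing)
    if emu.mode == "exact":
        return base
    if emu.mode == "full_backscatter":
        # the deficit is not modelled: every point scales by 1/BCF
        factor = 1.0 / deficit.exit_bcf(field_size, depth)
        return DosePlane(depth=base.depth, field_size=base.field_size,
                         x_coords=base.x_coords, y_coords=base.y_coords,
                         dose=base.dose * factor)
    if depth < emu.onset_depth - 1e-9:
        return base
    half = field_size * (ssd + depth) / 200.0
    gx, gy = np.meshgrid(base.x_coords, base.y_coords)
    r = np.maximum(np.abs(gx), np.abs(gy))  # square-field radial coordinate
    if emu.mode == "shoulder_boost":
        lo, hi = emu.shoulder_band
        mask = (r >= lo * half) & (r <= hi * half)
        dose = np.where(mask, base.dose * (1.0 + emu.magnitude), base.dose)
    else:  # center_dip
        mask = r <= emu.center_fraction * half
        dose = np.where(mask, base.dose * (1.0 - emu.magnitude), base.dose)
    return DosePlane(depth=base.depth, field_size=base.field_size,
                     x_coords=base.x_coords, y_coords=base.y_coords, dose=dose)
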