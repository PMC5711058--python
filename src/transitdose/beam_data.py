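"""Domain types and text I/O for linac beam scan data.

Everything is expressed in central-axis-centred coordinates in cm, with depth
measured from the beam entry surface.  Field size always means the side of the
square field defined at 100 cm from the source.  Doses are in cGy; percentage
depth dose (PDD) is normalized so its maximum is 100; output factors (OF) are
relative to the 10 x 10 cm reference field.

The backscatter correction factor (BCF) is the ratio of dose without
backscatter to dose with full backscatter, tabulated per machine in two
blocks: an *entrance* block (fixed depth 1.5 cm, varying backscatter
thickness) and an *exit* block (fixed backscatter thickness 1.5 cm, varying
depth).  The exit value at depth 1.5 cm coincides with the entrance value at
backscatter thickness 1.5 cm and is stored only in the entrance block.

File formats are plain comma-separated UTF-8 text with a mandatory header
row ("." decimal separator):

``pdd_<fs>.csv``
    columns ``depth_cm, pdd_percent``
``of.csv``
    columns ``field_size_cm, factor``
``profile_<axis>_<fs>_<depth>.csv``
    columns ``position_cm, value``
``bcf_<machine>.csv``
    metadata lines ``#machine,<id>`` and ``#tpr2010,<value>``, then an
    ``#entrance`` block and an ``#exit`` block, each a field-size-by-column
    matrix in the layout described above
``measurements.csv``
    columns ``machine_id, field_size_cm, depth_cm, backscatter_cm, dose_cgy``
    and optionally ``mu``
``beam_meta.csv`` (optional)
    columns ``machine_id, d_dmax_cgy_per_mu``; defaults to the directory name
    and 1.0 cGy/MU when absent
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AXES = ("crossline", "inline", "diagonal")

#: Reference field size (cm) for output factors and D_dmax.
REFERENCE_FIELD_SIZE = 10.0

#: Entrance/exit measurement depth from the respective surface (cm).
ENTRANCE_EXIT_DEPTH = 1.5

#: Physically plausible BCF range for 6 MV entrance/exit geometries.  Values
#: marginally above 1 occur from measurement noise and are tolerated (with a
#: warning) up to 1.01.
BCF_LOWER = 0.9
BCF_UPPER = 1.01


class BeamDataError(ValueError):
    """Invalid beam data: an invariant or file-format violation."""


class ExtrapolationError(BeamDataError):
    """A query fell outside the tabulated hull (no silent extrapolation)."""


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise BeamDataError(f"{name} must be one-dimensional")
    return arr


def _check_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise BeamDataError(f"{name} must be strictly increasing")


def interp1(grid: np.ndarray, values: np.ndarray, x: float, what: str) -> float:
    """Linear interpolation with a hard hull check (exact at grid nodes)."""
    if x < grid[0] - 1e-12 or x > grid[-1] + 1e-12:
        raise ExtrapolationError(
            f"{what}: query {x:g} outside tabulated range [{grid[0]:g}, {grid[-1]:g}]"
        )
    return float(np.interp(x, grid, values))


def interp2(
    rows: np.ndarray,
    cols: np.ndarray,
    table: np.ndarray,
    r: float,
    c: float,
    what: str,
) -> float:
    """Bilinear interpolation on a (rows x cols) table with hull checks."""
    if rows.size == 1:
        if abs(r - rows[0]) > 1e-9:
            raise ExtrapolationError(f"{what}: single row at {rows[0]:g}, query {r:g}")
        return interp1(cols, table[0], c, what)
    if r < rows[0] - 1e-12 or r > rows[-1] + 1e-12:
        raise ExtrapolationError(
            f"{what}: query {r:g} outside tabulated range [{rows[0]:g}, {rows[-1]:g}]"
        )
    # interpolate each row at c, then across rows at r
    per_row = np.array([np.interp(c, cols, row) for row in table])
    if c < cols[0] - 1e-12 or c > cols[-1] + 1e-12:
        raise ExtrapolationError(
            f"{what}: query {c:g} outside tabulated range [{cols[0]:g}, {cols[-1]:g}]"
        )
    return float(np.interp(r, rows, per_row))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDDCurve:
    """Central-axis percentage depth dose for one field size.

    ``values`` are percent, normalized so the maximum is 100; ``dmax`` is the
    depth of that maximum.
    """

    field_size: float
    depths: np.ndarray
    values: np.ndarray
    dmax: float

    def __post_init__(self):
        object.__setattr__(self, "depths", _as_array(self.depths, "depths"))
        object.__setattr__(self, "values", _as_array(self.values, "values"))
        if self.depths.shape != self.values.shape:
            raise BeamDataError("PDD depths and values must have equal length")
        _check_strictly_increasing(self.depths, "PDD depths")
        if np.any(self.values <= 0):
            raise BeamDataError("PDD values must be positive")
        if abs(self.values.max() - 100.0) > 1e-9:
            raise BeamDataError(
                f"PDD not normalized to 100 (field size {self.field_size:g}, "
                f"max {self.values.max():.6g})"
            )

    def value_at(self, depth: float) -> float:
        return interp1(self.depths, self.values, depth, "PDD depth")


@dataclass(frozen=True)
class OutputFactorTable:
    """Field-size output factors relative to the 10 x 10 reference field."""

    field_sizes: np.ndarray
    factors: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "field_sizes", _as_array(self.field_sizes, "field_sizes"))
        object.__setattr__(self, "factors", _as_array(self.factors, "factors"))
        if self.field_sizes.shape != self.factors.shape:
            raise BeamDataError("OF field sizes and factors must have equal length")
        _check_strictly_increasing(self.field_sizes, "OF field sizes")
        if not np.all(np.diff(self.factors) > 0):
            raise BeamDataError("output factors must increase strictly with field size")
        idx = np.flatnonzero(np.abs(self.field_sizes - REFERENCE_FIELD_SIZE) < 1e-9)
        if idx.size == 0:
            raise BeamDataError("reference field size missing from output factor table")
        if abs(self.factors[idx[0]] - 1.0) > 1e-12:
            raise BeamDataError("output factor at the reference field size must be 1.0")

    def factor_at(self, field_size: float) -> float:
        return interp1(self.field_sizes, self.factors, field_size, "OF field size")


@dataclass(frozen=True)
class ScanProfile:
    """1D off-axis dose samples at a given depth along one scan axis.

    ``values`` are either absolute dose (cGy) or dimensionless relative dose.
    Positions are off-axis distances in cm; for the diagonal axis they are
    signed radial distances along the diagonal.
    """

    axis: str
    depth: float
    field_size: float
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.axis not in AXES:
            raise BeamDataError(f"axis must be one of {AXES}, got {self.axis!r}")
        object.__setattr__(self, "positions", _as_array(self.positions, "positions"))
        object.__setattr__(self, "values", _as_array(self.values, "values"))
        if self.positions.shape != self.values.shape:
            raise BeamDataError("profile positions and values must have equal length")
        _check_strictly_increasing(self.positions, "profile positions")
        if not (self.positions[0] <= 0.0 <= self.positions[-1]):
            raise BeamDataError("profile must contain or bracket the central axis (position 0)")

    def value_at(self, position: float) -> float:
        return interp1(self.positions, self.values, position, "profile position")

    @property
    def cax_value(self) -> float:
        return self.value_at(0.0)


@dataclass(frozen=True)
class DosePlane:
    """2D absolute dose grid (cGy) at a fixed depth, origin on the central axis.

    ``dose[i, j]`` corresponds to ``(y_coords[i], x_coords[j])``.
    """

    depth: float
    field_size: float
    x_coords: np.ndarray
    y_coords: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x_coords", _as_array(self.x_coords, "x_coords"))
        object.__setattr__(self, "y_coords", _as_array(self.y_coords, "y_coords"))
        dose = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "dose", dose)
        if dose.shape != (self.y_coords.size, self.x_coords.size):
            raise BeamDataError("dose grid shape must be (len(y_coords), len(x_coords))")
        for name, coords in (("x_coords", self.x_coords), ("y_coords", self.y_coords)):
            _check_strictly_increasing(coords, name)
            steps = np.diff(coords)
            if steps.size and np.ptp(steps) > 1e-9:
                raise BeamDataError(f"{name} spacing must be uniform")
            if not (coords[0] <= 0.0 <= coords[-1]):
                raise BeamDataError(f"{name} must bracket the central axis (0)")
        if np.any(dose < 0):
            raise BeamDataError("dose must be non-negative everywhere")

    @property
    def spacing(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    def value_at(self, x: float, y: float) -> float:
        """Bilinear interpolation at an in-plane point."""
        if not (self.x_coords[0] - 1e-12 <= x <= self.x_coords[-1] + 1e-12):
            raise ExtrapolationError(f"plane x query {x:g} outside grid")
        per_row = np.array([np.interp(x, self.x_coords, row) for row in self.dose])
        return interp1(self.y_coords, per_row, y, "plane y")

    @property
    def cax_dose(self) -> float:
        return self.value_at(0.0, 0.0)


@dataclass(frozen=True)
class DoseMeasurement:
    """One measured central-axis dose point in the slab-phantom geometry.

    The dose is either given directly (cGy) or obtained from a charge reading
    via a calibration factor before construction; ``charge`` is retained for
    provenance only.  ``mu`` records the delivered monitor units.
    """

    machine_id: str
    field_size: float
    depth: float
    backscatter_thickness: float
    dose: float
    charge: float | None = None
    mu: float = 100.0

    def __post_init__(self):
        if not self.dose > 0:
            raise BeamDataError("measured dose must be positive")
        if not self.mu > 0:
            raise BeamDataError("monitor units must be positive")


def _check_bcf_block(values: np.ndarray, block: str, machine: str) -> None:
    if np.any(values <= BCF_LOWER) or np.any(values > BCF_UPPER):
        bad = values[(values <= BCF_LOWER) | (values > BCF_UPPER)]
        raise BeamDataError(
            f"{machine} {block} BCF outside ({BCF_LOWER}, {BCF_UPPER}]: {bad.tolist()}"
        )
    above = values[values > 1.0]
    for v in above:
        log.warning(
            "%s %s BCF %.3f exceeds 1 (tolerated measurement noise; "
            "the correction is defined as <= 1)",
            machine, block, v,
        )


@dataclass(frozen=True)
class BCFTable:
    """Entrance and exit backscatter correction factors for one machine.

    Entrance block: rows = field sizes, columns = backscatter thickness (cm),
    all at depth 1.5 cm.  Exit block: rows = field sizes, columns = depth (cm),
    all at backscatter thickness 1.5 cm; the 1.5 cm depth column is not stored
    (it equals the entrance column at thickness 1.5 cm).
    """

    machine_id: str
    tpr2010: float
    entrance_field_sizes: np.ndarray
    entrance_thicknesses: np.ndarray
    entrance: np.ndarray
    exit_field_sizes: np.ndarray
    exit_depths: np.ndarray
    exit: np.ndarray

    def __post_init__(self):
        for name in ("entrance_field_sizes", "entrance_thicknesses",
                     "exit_field_sizes", "exit_depths"):
            object.__setattr__(self, name, _as_array(getattr(self, name), name))
            _check_strictly_increasing(getattr(self, name), name)
        ent = np.asarray(self.entrance, dtype=float)
        ext = np.asarray(self.exit, dtype=float)
        object.__setattr__(self, "entrance", ent)
        object.__setattr__(self, "exit", ext)
        if ent.shape != (self.entrance_field_sizes.size, self.entrance_thicknesses.size):
            raise BeamDataError("entrance block shape mismatch")
        if ext.shape != (self.exit_field_sizes.size, self.exit_depths.size):
            raise BeamDataError("exit block shape mismatch")
        if np.any(self.exit_depths <= ENTRANCE_EXIT_DEPTH):
            raise BeamDataError(
                "exit depths must exceed 1.5 cm (the 1.5 cm column lives in the entrance block)"
            )
        _check_bcf_block(ent, "entrance", self.machine_id)
        _check_bcf_block(ext, "exit", self.machine_id)

    # -- lookups ------------------------------------------------------------

    def entrance_bcf(self, field_size: float, backscatter_thickness: float) -> float:
        """Entrance BCF, linearly interpolated in field size and thickness."""
        return interp2(
            self.entrance_field_sizes, self.entrance_thicknesses, self.entrance,
            field_size, backscatter_thickness, f"{self.machine_id} entrance BCF",
        )

    def exit_bcf(self, field_size: float, depth: float) -> float:
        """Exit BCF, linearly interpolated; depth 1.5 cm maps to the entrance block."""
        if abs(depth - ENTRANCE_EXIT_DEPTH) < 1e-9:
            return self.entrance_bcf(field_size, ENTRANCE_EXIT_DEPTH)
        return interp2(
            self.exit_field_sizes, self.exit_depths, self.exit,
            field_size, depth, f"{self.machine_id} exit BCF",
        )


@dataclass(frozen=True)
class BeamDataset:
    """Commissioning-style beam data: PDD per field size, OF table, profiles.

    ``d_dmax`` is the dose (cGy per MU) at the depth of maximum for the
    reference field size — the absolute anchor for dose reconstruction.
    Profiles are keyed by ``(axis, field_size, depth)``.
    """

    machine_id: str
    pdd: Mapping[float, PDDCurve]
    of: OutputFactorTable
    profiles: Mapping[tuple, ScanProfile] = field(default_factory=dict)
    d_dmax: float = 1.0

    def __post_init__(self):
        if not self.d_dmax > 0:
            raise BeamDataError("d_dmax must be positive")
        if not any(abs(fs - REFERENCE_FIELD_SIZE) < 1e-9 for fs in self.pdd):
            raise BeamDataError("reference field size missing from PDD set")
        # OF table validates its own reference-field invariant.

    @property
    def field_sizes(self) -> np.ndarray:
        return np.array(sorted(self.pdd))

    def pdd_value(self, field_size: float, depth: float) -> float:
        """PDD (percent), interpolated in depth per curve then across field size."""
        sizes = self.field_sizes
        if field_size < sizes[0] - 1e-12 or field_size > sizes[-1] + 1e-12:
            raise ExtrapolationError(
                f"field size {field_size:g} outside PDD set [{sizes[0]:g}, {sizes[-1]:g}]"
            )
        per_fs = np.array([self.pdd[fs].value_at(depth) for fs in sizes])
        return float(np.interp(field_size, sizes, per_fs))

    def profile(self, axis: str, field_size: float, depth: float) -> ScanProfile:
        key = (axis, float(field_size), float(depth))
        if key not in self.profiles:
            raise BeamDataError(f"no profile for axis={axis}, fs={field_size:g}, depth={depth:g}")
        return self.profiles[key]


def tpr20_10(pdd: PDDCurve, ssd: float = 100.0) -> float:
    """Beam-quality index TPR20,10 from a PDD curve measured at the given SSD.

    Uses the standard inverse-square conversion from depth-dose at fixed SSD
    to tissue-phantom ratio at fixed source-detector distance:
    TPR20,10 = PDD(20)/PDD(10) * ((ssd + 20) / (ssd + 10))**2.
    """
    return pdd.value_at(20.0) / pdd.value_at(10.0) * ((ssd + 20.0) / (ssd + 10.0)) ** 2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PROFILE_RE = re.compile(r"profile_(crossline|inline|diagonal)_([0-9.]+)_([0-9.]+)\.csv$")
_PDD_RE = re.compile(r"pdd_([0-9.]+)\.csv$")


def read_pdd(path: Path | str, field_size: float) -> PDDCurve:
    df = pd.read_csv(path)
    depths = df["depth_cm"].to_numpy(float)
    if np.any(np.diff(depths) <= 0):
        # offending row: diff index i flags depths[i+1]; +1 header, +1 one-based
        row = int(np.flatnonzero(np.diff(depths) <= 0)[0]) + 3
        raise BeamDataError(f"{path}: non-monotone depth grid at row {row}")
    values = df["pdd_percent"].to_numpy(float)
    dmax = float(depths[np.argmax(values)])
    return PDDCurve(field_size=field_size, depths=depths, values=values, dmax=dmax)


def read_beam_dataset(path: Path | str) -> BeamDataset:
    """Load a BeamDataset from a directory of CSV files (formats in module docs)."""
    root = Path(path)
    if not root.is_dir():
        raise BeamDataError(f"{root} is not a directory")

    pdd: dict[float, PDDCurve] = {}
    profiles: dict[tuple, ScanProfile] = {}
    for f in sorted(root.iterdir()):
        m = _PDD_RE.match(f.name)
        if m:
            fs = float(m.group(1))
            pdd[fs] = read_pdd(f, fs)
            continue
        m = _PROFILE_RE.match(f.name)
        if m:
            axis, fs, depth = m.group(1), float(m.group(2)), float(m.group(3))
            df = pd.read_csv(f)
            profiles[(axis, fs, depth)] = ScanProfile(
                axis=axis, depth=depth, field_size=fs,
                positions=df["position_cm"].to_numpy(float),
                values=df["value"].to_numpy(float),
            )
    if not pdd:
        raise BeamDataError(f"no pdd_<fs>.csv files found in {root}")

    of_path = root / "of.csv"
    if not of_path.exists():
        raise BeamDataError(f"missing {of_path}")
    of_df = pd.read_csv(of_path)
    of = OutputFactorTable(
        field_sizes=of_df["field_size_cm"].to_numpy(float),
        factors=of_df["factor"].to_numpy(float),
    )

    machine_id, d_dmax = root.name, 1.0
    meta_path = root / "beam_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        machine_id = str(meta["machine_id"].iloc[0])
        d_dmax = float(meta["d_dmax_cgy_per_mu"].iloc[0])

    return BeamDataset(machine_id=machine_id, pdd=pdd, of=of,
                       profiles=profiles, d_dmax=d_dmax)


def write_beam_dataset(beam: BeamDataset, path: Path | str) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for fs, curve in beam.pdd.items():
        pd.DataFrame({"depth_cm": curve.depths, "pdd_percent": np.round(curve.values, 1)}) \
            .to_csv(root / f"pdd_{fs:g}.csv", index=False)
    pd.DataFrame({"field_size_cm": beam.of.field_sizes, "factor": beam.of.factors}) \
        .to_csv(root / "of.csv", index=False)
    for (axis, fs, depth), prof in beam.profiles.items():
        pd.DataFrame({"position_cm": prof.positions, "value": prof.values}) \
            .to_csv(root / f"profile_{axis}_{fs:g}_{depth:g}.csv", index=False)
    pd.DataFrame({"machine_id": [beam.machine_id], "d_dmax_cgy_per_mu": [beam.d_dmax]}) \
        .to_csv(root / "beam_meta.csv", index=False)


def read_bcf_table(path: Path | str) -> BCFTable:
    """Parse a two-block BCF CSV (``#entrance`` / ``#exit`` markers)."""
    path = Path(path)
    machine_id, tpr = path.stem, float("nan")
    blocks: dict[str, tuple[list[float], list[list[float]], list[float]]] = {}
    current: str | None = None
    cols: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#machine"):
                machine_id = line.split(",", 1)[1].strip()
            elif line.startswith("#tpr2010"):
                tpr = float(line.split(",", 1)[1])
            elif line.startswith("#entrance") or line.startswith("#exit"):
                current = line.lstrip("#").strip()
                blocks[current] = ([], [], [])
                cols = []
            elif current is not None:
                parts = [p.strip() for p in line.split(",")]
                if parts[0] == "field_size_cm":
                    cols = [float(p) for p in parts[1:]]
                    blocks[current] = (cols, [], [])
                else:
                    fs = float(parts[0])
                    _, rows, seen = blocks[current]
                    if fs in seen:
                        raise BeamDataError(f"{path}: duplicate field size {fs:g} in {current} block")
                    seen.append(fs)
                    rows.append([float(p) for p in parts[1:]])
    for name in ("entrance", "exit"):
        if name not in blocks or not blocks[name][1]:
            raise BeamDataError(f"{path}: missing #{name} block")
    (ecols, erows, efs) = blocks["entrance"]
    (xcols, xrows, xfs) = blocks["exit"]
    return BCFTable(
        machine_id=machine_id, tpr2010=tpr,
        entrance_field_sizes=efs, entrance_thicknesses=ecols, entrance=erows,
        exit_field_sizes=xfs, exit_depths=xcols, exit=xrows,
    )


def write_bcf_table(table: BCFTable, path: Path | str) -> None:
    """Serialize a BCFTable; values are rounded to 3 decimals (tabulated precision)."""
    lines = [f"#machine,{table.machine_id}", f"#tpr2010,{table.tpr2010:.4f}", "#entrance"]
    lines.append("field_size_cm," + ",".join(f"{c:g}" for c in table.entrance_thicknesses))
    for fs, row in zip(table.entrance_field_sizes, table.entrance):
        lines.append(f"{fs:g}," + ",".join(f"{v:.3f}" for v in row))
    lines.append("#exit")
    lines.append("field_size_cm," + ",".join(f"{c:g}" for c in table.exit_depths))
    for fs, row in zip(table.exit_field_sizes, table.exit):
        lines.append(f"{fs:g}," + ",".join(f"{v:.3f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_measurements(path: Path | str) -> list[DoseMeasurement]:
    df = pd.read_csv(path)
    mu = df["mu"] if "mu" in df.columns else pd.Series(100.0, index=df.index)
    return [
        DoseMeasurement(
            machine_id=str(r.machine_id), field_size=float(r.field_size_cm),
            depth=float(r.depth_cm), backscatter_thickness=float(r.backscatter_cm),
            dose=float(r.dose_cgy), mu=float(m),
        )
        for r, m in zip(df.itertuples(index=False), mu)
    ]


def write_measurements(measurements: Iterable[DoseMeasurement], path: Path | str) -> None:
    rows = [
        {
            "machine_id": m.machine_id, "field_size_cm": m.field_size,
            "depth_cm": m.depth, "backscatter_cm": m.backscatter_thickness,
            "dose_cgy": m.dose, "mu": m.mu,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dose_plane(plane: DosePlane, path: Path | str) -> None:
    """Plane CSV: two metadata lines, then the dense dose grid (rows = y)."""
    lines = [
        f"#depth_cm,{plane.depth:g}",
        f"#field_size_cm,{plane.field_size:g}",
        "#x," + ",".join(f"{x:.4f}" for x in plane.x_coords),
        "#y," + ",".join(f"{y:.4f}" for y in plane.y_coords),
    ]
    for row in plane.dose:
        lines.append(",".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_dose_plane(path: Path | str) -> DosePlane:
    depth = fs = None
    x = y = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#depth_cm"):
                depth = float(line.split(",")[1])
            elif line.startswith("#field_size_cm"):
                fs = float(line.split(",")[1])
            elif line.startswith("#x,"):
                x = [float(v) for v in line.split(",")[1:]]
            elif line.startswith("#y,"):
                y = [float(v) for v in line.split(",")[1:]]
            else:
                rows.append([float(v) for v in line.split(",")])
    if depth is None or fs is None or x is None or y is None:
        raise BeamDataError(f"{path}: incomplete plane header")
    return DosePlane(depth=depth, field_size=fs, x_coords=x, y_coords=y, dose=rows)
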