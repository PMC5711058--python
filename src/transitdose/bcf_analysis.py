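"""Deriving and summarizing backscatter correction factor (BCF) tables.

A BCF is the ratio of the dose measured without (full) backscatter to the
dose reconstructed under full-backscatter conditions from PDD and output
factors.  Entrance-block values are strictly partial-backscatter ratios
(dose with partial backscatter over dose with full backscatter); they are
tabulated anyway because patients present variable backscatter thickness.

This module builds BCF tables from measurement sets, extracts the summary
statistics used to characterize them (extrema, dose-reduction thresholds),
and compares tables cell by cell (cross-machine agreement, SSD invariance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .beam_data import (
    BCF_LOWER,
    BCF_UPPER,
    BCFTable,
    BeamDataError,
    BeamDataset,
    DoseMeasurement,
    ENTRANCE_EXIT_DEPTH,
    tpr20_10,
)
from .dose_engine import dose_full_backscatter

log = logging.getLogger(__name__)


class BCFCell(NamedTuple):
    """A BCF value with its grid location (field size, thickness-or-depth)."""

    value: float
    field_size: float
    key: float


class BlockDifference(NamedTuple):
    """Mean and population SD of absolute per-cell differences, in percent."""

    mean_pct: float
    sd_pct: float


@dataclass(frozen=True)
class BCFSummary:
    """Summary statistics of one BCF table.

    ``max_entrance_reduction_pct`` is the largest entrance dose reduction
    (1 - BCF) * 100 over cells at or beyond ``reduction_threshold_cm`` of
    backscatter; ``cross_machine`` holds per-block difference statistics
    against a second table when one was supplied.  Entrance-block values are
    partial-backscatter ratios (see module docs).
    """

    machine_id: str
    min_entrance: BCFCell
    max_exit: BCFCell
    min_exit: BCFCell
    reduction_threshold_cm: float
    max_entrance_reduction_pct: float
    cross_machine: Mapping[str, BlockDifference] | None = None


def compute_bcf(dose_without: float, dose_full: float) -> float:
    """BCF = dose without backscatter / dose with full backscatter (<= 1).

    Ratios marginally above 1 (up to 1.01) are tolerated with a warning —
    they arise from measurement noise; ratios outside (0.9, 1.01] are
    physically implausible for these geometries and rejected.
    """
    if not (dose_without > 0 and dose_full > 0):
        raise BeamDataError("doses must be positive")
    ratio = dose_without / dose_full
    if ratio <= BCF_LOWER or ratio > BCF_UPPER:
        raise BeamDataError(
            f"BCF {ratio:.4f} outside plausible range ({BCF_LOWER}, {BCF_UPPER}]"
        )
    if ratio > 1.0:
        log.warning("BCF %.4f exceeds 1 (the correction is defined as <= 1)", ratio)
    return ratio


def build_bcf_table(
    measurements: Iterable[DoseMeasurement],
    beam: BeamDataset,
    machine_id: str | None = None,
) -> BCFTable:
    """Derive a BCF table from central-axis slab-phantom measurements.

    Measurements at depth 1.5 cm populate the entrance block (keyed by
    backscatter thickness, including the shared 1.5 cm cell); measurements
    with 1.5 cm backscatter at greater depth populate the exit block (keyed
    by depth).  Denominators are full-backscatter doses reconstructed from
    the beam's PDD and output factors.  The derived grid must be complete
    (the cross product of observed field sizes and thicknesses/depths).
    """
    measurements = list(measurements)
    if not measurements:
        raise BeamDataError("no measurements supplied")
    if machine_id is None:
        machine_id = measurements[0].machine_id

    entrance: dict[tuple[float, float], float] = {}
    exit_: dict[tuple[float, float], float] = {}
    for m in measurements:
        ratio = compute_bcf(m.dose, dose_full_backscatter(beam, m.field_size, m.depth, m.mu))
        if abs(m.depth - ENTRANCE_EXIT_DEPTH) < 1e-9:
            key = (m.field_size, m.backscatter_thickness)
            if key in entrance:
                raise BeamDataError(f"duplicate entrance measurement at (fs, thickness) = {key}")
            entrance[key] = ratio
        elif abs(m.backscatter_thickness - ENTRANCE_EXIT_DEPTH) < 1e-9:
            key = (m.field_size, m.depth)
            if key in exit_:
                raise BeamDataError(f"duplicate exit measurement at (fs, depth) = {key}")
            exit_[key] = ratio
        else:
            raise BeamDataError(
                f"measurement (fs={m.field_size:g}, depth={m.depth:g}, "
                f"backscatter={m.backscatter_thickness:g}) matches neither the entrance "
                f"(depth 1.5) nor the exit (backscatter 1.5) geometry"
            )

    def _grid(cells: Mapping[tuple[float, float], float], label: str):
        fss = sorted({k[0] for k in cells})
        keys = sorted({k[1] for k in cells})
        missing = [(fs, k) for fs in fss for k in keys if (fs, k) not in cells]
        if missing:
            raise BeamDataError(f"incomplete {label} grid; missing cells: {missing}")
        values = np.array([[cells[(fs, k)] for k in keys] for fs in fss])
        return np.array(fss), np.array(keys), values

    if not entrance:
        raise BeamDataError("no entrance-geometry measurements (depth 1.5 cm)")
    if not exit_:
        raise BeamDataError("no exit-geometry measurements (backscatter 1.5 cm, depth > 1.5 cm)")
    efs, ethick, eval_ = _grid(entrance, "entrance")
    xfs, xdepth, xval = _grid(exit_, "exit")
    tpr = tpr20_10(beam.pdd[10.0]) if 10.0 in beam.pdd else float("nan")
    return BCFTable(
        machine_id=machine_id, tpr2010=tpr,
        entrance_field_sizes=efs, entrance_thicknesses=ethick, entrance=eval_,
        exit_field_sizes=xfs, exit_depths=xdepth, exit=xval,
    )


def _extreme(values: np.ndarray, rows: np.ndarray, cols: np.ndarray, take_min: bool) -> BCFCell:
    idx = np.argmin(values) if take_min else np.argmax(values)
    i, j = np.unravel_index(idx, values.shape)
    return BCFCell(value=float(values[i, j]), field_size=float(rows[i]), key=float(cols[j]))


def summarize_bcf(
    table: BCFTable,
    reduction_threshold_cm: float = 11.5,
    compare_to: BCFTable | None = None,
) -> BCFSummary:
    """Extrema and dose-reduction statistics of a BCF table.

    The threshold check reports the worst entrance dose reduction
    (1 - BCF) * 100 over cells whose backscatter thickness is at or beyond
    the cut — the quantity used to declare the deficit clinically negligible.
    """
    sel = table.entrance_thicknesses >= reduction_threshold_cm - 1e-9
    if not sel.any():
        raise BeamDataError(
            f"no entrance columns at or beyond {reduction_threshold_cm:g} cm"
        )
    reduction = float(np.max((1.0 - table.entrance[:, sel]) * 100.0))
    return BCFSummary(
        machine_id=table.machine_id,
        min_entrance=_extreme(table.entrance, table.entrance_field_sizes,
                              table.entrance_thicknesses, take_min=True),
        max_exit=_extreme(table.exit, table.exit_field_sizes, table.exit_depths, take_min=False),
        min_exit=_extreme(table.exit, table.exit_field_sizes, table.exit_depths, take_min=True),
        reduction_threshold_cm=reduction_threshold_cm,
        max_entrance_reduction_pct=reduction,
        cross_machine=compare_bcf_tables(table, compare_to) if compare_to is not None else None,
    )


def _check_same_grid(a: BCFTable, b: BCFTable) -> None:
    pairs = (
        (a.entrance_field_sizes, b.entrance_field_sizes),
        (a.entrance_thicknesses, b.entrance_thicknesses),
        (a.exit_field_sizes, b.exit_field_sizes),
        (a.exit_depths, b.exit_depths),
    )
    for x, y in pairs:
        if x.shape != y.shape or not np.allclose(x, y):
            raise BeamDataError("BCF tables are tabulated on different grids")


def compare_bcf_tables(a: BCFTable, b: BCFTable) -> dict[str, BlockDifference]:
    """Per-block mean and population SD of absolute cell differences (percent).

    Unsigned differences; both tables must share the exact grid.
    """
    _check_same_grid(a, b)
    out = {}
    for name, da, db in (("entrance", a.entrance, b.entrance), ("exit", a.exit, b.exit)):
        diff = np.abs(da - db) * 100.0
        out[name] = BlockDifference(mean_pct=float(diff.mean()), sd_pct=float(diff.std()))
    return out


def ssd_invariance_check(
    table_fixed_ssd: BCFTable, table_isocentric: BCFTable
) -> tuple[float, float]:
    """Max and population SD of absolute per-cell differences (percent).

    Used to verify that BCF tables derived at fixed SSD 100 cm and in
    isocentric (variable-SSD) geometry agree, which justifies using a single
    table clinically.
    """
    _check_same_grid(table_fixed_ssd, table_isocentric)
    diff = np.abs(
        np.concatenate([
            (table_fixed_ssd.entrance - table_isocentric.entrance).ravel(),
            (table_fixed_ssd.exit - table_isocentric.exit).ravel(),
        ])
    ) * 100.0
    return float(diff.max()), float(diff.std())
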