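"""Central-axis dose reconstruction and expected entrance/exit doses.

The full-backscatter reference dose at field size *fs* and depth *d* is

    Dose(fs, d) = D_dmax * MU * PDD(fs, d) / 100 * OF(fs)

with D_dmax the dose per MU at the depth of maximum for the reference field,
PDD the percentage depth dose and OF the field-size output factor.  The
expected in-vivo dose corrects this for the missing backscatter:

    Dose_expected = Dose(fs, d) * BCF

where BCF <= 1 is the backscatter correction factor looked up in the machine's
table — by backscatter thickness for entrance points (fixed depth 1.5 cm) and
by depth for exit points (fixed backscatter thickness 1.5 cm).  Mixed
geometries are rejected rather than guessed.

The same BCF table is used for fixed-SSD and isocentric setups (the factor is
experimentally SSD-independent); pass ``allow_isocentric=False`` to forbid
this and make non-SSD-100 use an explicit caller decision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .beam_data import (
    BCFTable,
    BeamDataset,
    ENTRANCE_EXIT_DEPTH,
    BeamDataError,
)

KINDS = ("entrance", "exit")


@dataclass(frozen=True)
class CalibrationFactor:
    """Charge-to-dose conversion factor (cGy per detector unit).

    Derived from a charge reading at the calibration condition, where the
    machine output is 1 cGy/MU.
    """

    machine_id: str
    factor: float

    def __post_init__(self):
        if not self.factor > 0:
            raise BeamDataError("calibration factor must be positive")


def charge_to_dose(charge: float, calib: CalibrationFactor) -> float:
    """Convert a raw charge reading to dose (cGy); linear in the reading."""
    if not charge > 0:
        raise BeamDataError("charge reading must be positive")
    return charge * calib.factor


@dataclass(frozen=True)
class ExpectedDose:
    """Reconstructed dose with and without the backscatter correction."""

    kind: str
    field_size: float
    depth: float
    backscatter_thickness: float
    mu: float
    dose_full_backscatter: float
    bcf_applied: float

    @property
    def dose_expected(self) -> float:
        return self.dose_full_backscatter * self.bcf_applied


def dose_full_backscatter(beam: BeamDataset, field_size: float, depth: float,
                          mu: float = 100.0) -> float:
    """Central-axis dose (cGy) under full-backscatter conditions."""
    return beam.d_dmax * mu * beam.pdd_value(field_size, depth) / 100.0 \
        * beam.of.factor_at(field_size)


def expected_dose(
    beam: BeamDataset,
    bcf: BCFTable,
    kind: str,
    field_size: float,
    depth: float,
    backscatter_thickness: float,
    mu: float = 100.0,
) -> ExpectedDose:
    """Expected entrance/exit dose: Eq.-2-style reconstruction times BCF.

    Entrance points must sit at depth 1.5 cm (BCF keyed by backscatter
    thickness); exit points must have 1.5 cm backscatter (BCF keyed by depth).
    """
    if kind not in KINDS:
        raise BeamDataError(f"kind must be one of {KINDS}, got {kind!r}")
    if kind == "entrance":
        if abs(depth - ENTRANCE_EXIT_DEPTH) > 1e-9:
            raise BeamDataError(
                f"entrance dose is defined at depth {ENTRANCE_EXIT_DEPTH} cm, got {depth:g}"
            )
        factor = bcf.entrance_bcf(field_size, backscatter_thickness)
    else:
        if abs(backscatter_thickness - ENTRANCE_EXIT_DEPTH) > 1e-9:
            raise BeamDataError(
                f"exit dose is defined at backscatter thickness {ENTRANCE_EXIT_DEPTH} cm, "
                f"got {backscatter_thickness:g}"
            )
        factor = bcf.exit_bcf(field_size, depth)
    full = dose_full_backscatter(beam, field_size, depth, mu)
    return ExpectedDose(
        kind=kind, field_size=field_size, depth=depth,
        backscatter_thickness=backscatter_thickness, mu=mu,
        dose_full_backscatter=full, bcf_applied=factor,
    )
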