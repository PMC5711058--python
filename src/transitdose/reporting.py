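"""Pipeline orchestration and reporting.

``run_pipeline`` chains the stages — simulate a beam, simulate a measurement
campaign, derive the BCF table, synthesize truth and emulated TPS dose
planes, run gamma analysis — and writes a deterministic markdown + JSON
report: a BCF table with summary, a central-axis percent-difference table
per emulation mode, and a gamma pass-rate table with full-field and
central-80% columns.  The percent-difference convention is
(computed / measured) - 1.  Every report carries the seed and a hash of the
configuration so any number can be reproduced by re-running the named stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bcf_analysis, beam_data, gamma_analysis, synthetic_data
from .beam_data import BeamDataError
from .synthetic_data import (
    BackscatterDeficitSpec,
    SyntheticBeamSpec,
    TPSEmulatorSpec,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one end-to-end synthetic run."""

    seed: int = 0
    machine_id: str = "synthetic6mv"
    field_sizes: tuple[float, ...] = synthetic_data.DEFAULT_FIELD_SIZES
    entrance_thicknesses: tuple[float, ...] = synthetic_data.DEFAULT_ENTRANCE_THICKNESSES
    exit_depths: tuple[float, ...] = synthetic_data.DEFAULT_EXIT_DEPTHS
    noise_sd: float = 0.005
    emulator_modes: tuple[str, ...] = ("exact", "full_backscatter", "shoulder_boost")
    emulator_magnitude: float = 0.05
    emulator_onset_depth: float = 11.5
    gamma_cases: tuple[tuple[float, float], ...] = ((10.0, 21.5), (20.0, 31.5))
    dose_percent: float = 3.0
    dta_mm: float = 3.0
    plane_spacing: float = 0.2
    bcf_reduction_threshold_cm: float = 11.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_cases"] = [list(c) for c in self.gamma_cases]
        for key in ("field_sizes", "entrance_thicknesses", "exit_depths", "emulator_modes"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gamma_cases" in d:
            d["gamma_cases"] = tuple(tuple(float(v) for v in c) for c in d["gamma_cases"])
        for key in ("field_sizes", "entrance_thicknesses", "exit_depths"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        if "emulator_modes" in d:
            d["emulator_modes"] = tuple(d["emulator_modes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir: Path | str) -> dict:
    """Run every stage on synthetic data and write report files.

    Returns the result dictionary that is also serialized to report.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = dataclasses.replace(synthetic_data.CLINAC_LIKE,
                               machine_id=config.machine_id, seed=config.seed)
    deficit = BackscatterDeficitSpec()
    beam = synthetic_data.generate_beam(
        spec, field_sizes=config.field_sizes,
        profile_depths=tuple(sorted({1.5, *config.exit_depths})),
        profile_spacing=config.plane_spacing,
    )
    beam_data.write_beam_dataset(beam, out / "beam")

    measurements = synthetic_data.generate_measurements(
        beam, deficit,
        field_sizes=config.field_sizes,
        entrance_thicknesses=config.entrance_thicknesses,
        exit_depths=config.exit_depths,
        noise_sd=config.noise_sd, seed=config.seed,
    )
    beam_data.write_measurements(measurements, out / "measurements.csv")

    try:
        table = bcf_analysis.build_bcf_table(measurements, beam)
    except BeamDataError as exc:
        raise BeamDataError(f"stage derive-bcf failed: {exc}") from exc
    beam_data.write_bcf_table(table, out / f"bcf_{config.machine_id}.csv")
    summary = bcf_analysis.summarize_bcf(table, config.bcf_reduction_threshold_cm)
    bcf_warnings = sorted(
        f"entrance (fs={fs:g}, t={t:g}): {v:.3f}"
        for (fs, t, v) in _cells(table.entrance_field_sizes, table.entrance_thicknesses,
                                 table.entrance) if v > 1.0
    ) + sorted(
        f"exit (fs={fs:g}, d={d:g}): {v:.3f}"
        for (fs, d, v) in _cells(table.exit_field_sizes, table.exit_depths, table.exit)
        if v > 1.0
    )

    # central-axis percent differences per emulation mode over the exit grid
    cax_rows = []
    for mode in config.emulator_modes:
        emu = TPSEmulatorSpec(mode=mode, magnitude=config.emulator_magnitude,
                              onset_depth=config.emulator_onset_depth)
        for fs in config.field_sizes:
            for d in config.exit_depths:
                try:
                    truth = synthetic_data.truth_plane(beam, deficit, fs, d,
                                                      spacing=config.plane_spacing)
                    emulated = synthetic_data.emulate_tps_plane(
                        beam, deficit, emu, fs, d, spacing=config.plane_spacing)
                except BeamDataError as exc:
                    raise BeamDataError(f"stage emulate-tps failed for (fs={fs:g}, "
                                        f"depth={d:g}): {exc}") from exc
                cax_rows.append({
                    "mode": mode, "field_size_cm": fs, "depth_cm": d,
                    "cax_diff_pct": round(
                        (emulated.cax_dose / truth.cax_dose - 1.0) * 100.0, 6),
                })

    # gamma comparisons on the configured cases
    criteria = gamma_analysis.GammaCriteria(dose_percent=config.dose_percent,
                                            dta_mm=config.dta_mm)
    gamma_rows = []
    for mode in config.emulator_modes:
        emu = TPSEmulatorSpec(mode=mode, magnitude=config.emulator_magnitude,
                              onset_depth=config.emulator_onset_depth)
        for fs, d in config.gamma_cases:
            try:
                ref = synthetic_data.truth_plane(beam, deficit, fs, d,
                                                 spacing=config.plane_spacing)
                emulated = synthetic_data.emulate_tps_plane(
                    beam, deficit, emu, fs, d, spacing=config.plane_spacing)
                res = gamma_analysis.gamma_index(ref, emulated, criteria)
            except BeamDataError as exc:
                raise BeamDataError(f"stage gamma-compare failed for mode={mode}, "
                                    f"(fs={fs:g}, depth={d:g}): {exc}") from exc
            row = {
                "mode": mode, "field_size_cm": fs, "depth_cm": d,
                "cax_diff_pct": round((emulated.cax_dose / ref.cax_dose - 1.0) * 100.0, 6),
                "pass_rate_full_pct": round(res.pass_rate_full, 4),
                "pass_rate_80_pct": round(res.pass_rate_80, 4),
            }
            gamma_rows.append(row)
            gpath = out / f"gamma_{mode}_{fs:g}_{d:g}.json"
            gpath.write_text(json.dumps(row, sort_keys=True, indent=2) + "\n",
                             encoding="utf-8")

    results = {
        "provenance": {"seed": config.seed, "config_hash": config.config_hash},
        "bcf": {
            "machine_id": table.machine_id,
            "tpr2010": round(table.tpr2010, 4),
            "n_entrance_cells": int(table.entrance.size),
            "n_exit_cells": int(table.exit.size),
            "min_entrance": list(summary.min_entrance),
            "max_exit": list(summary.max_exit),
            "min_exit": list(summary.min_exit),
            "max_entrance_reduction_pct_beyond_threshold": round(
                summary.max_entrance_reduction_pct, 4),
            "reduction_threshold_cm": summary.reduction_threshold_cm,
            "warnings_above_unity": bcf_warnings,
        },
        "cax_differences": cax_rows,
        "gamma": gamma_rows,
    }
    (out / "report.json").write_text(
        json.dumps(results, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    (out / "report.md").write_text(render_report(results), encoding="utf-8")
    return results


def _cells(rows, cols, values):
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            yield r, c, values[i, j]


def render_report(results: dict) -> str:
    """Deterministic markdown rendering of a pipeline result dictionary."""
    p = results["provenance"]
    b = results["bcf"]
    lines = [
        "# Entrance/exit dose verification report",
        "",
        f"seed: {p['seed']}  |  config hash: {p['config_hash']}",
        "",
        "## Backscatter correction factors",
        "",
        f"- machine: {b['machine_id']} (TPR20,10 = {b['tpr2010']})",
        f"- grid: {b['n_entrance_cells']} entrance cells, {b['n_exit_cells']} exit cells",
        f"- min entrance BCF: {b['min_entrance'][0]:.3f} at "
        f"(fs {b['min_entrance'][1]:g} cm, thickness {b['min_entrance'][2]:g} cm)",
        f"- exit BCF range: {b['min_exit'][0]:.3f} to {b['max_exit'][0]:.3f}",
        f"- max entrance dose reduction at/beyond {b['reduction_threshold_cm']:g} cm "
        f"backscatter: {b['max_entrance_reduction_pct_beyond_threshold']:.2f}%",
    ]
    if b["warnings_above_unity"]:
        lines.append("- cells above unity (measurement noise; BCF is defined as <= 1):")
        lines += [f"  - {w}" for w in b["warnings_above_unity"]]
    lines += ["", "## Central-axis differences (emulated TPS / truth - 1)", ""]
    lines.append("| mode | fs (cm) | depth (cm) | CAX diff (%) |")
    lines.append("|---|---|---|---|")
    for r in results["cax_differences"]:
        lines.append(f"| {r['mode']} | {r['field_size_cm']:g} | {r['depth_cm']:g} "
                     f"| {r['cax_diff_pct']:+.2f} |")
    lines += ["", "## 2D absolute gamma (pass rates, %)", ""]
    if not results["gamma"]:
        lines.append("no plane comparisons run")
    else:
        lines.append("| mode | fs (cm) | depth (cm) | CAX diff (%) | 100% area | 80% area |")
        lines.append("|---|---|---|---|---|---|")
        for r in results["gamma"]:
            lines.append(
                f"| {r['mode']} | {r['field_size_cm']:g} | {r['depth_cm']:g} "
                f"| {r['cax_diff_pct']:+.2f} | {r['pass_rate_full_pct']:.1f} "
                f"| {r['pass_rate_80_pct']:.1f} |")
    return "\n".join(lines) + "\n"
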