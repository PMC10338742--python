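"""Study-level aggregation of EPOM shifts and the end-to-end driver.

A study is a set of raw chamber scans organized per (chamber type, serial,
energy, session) together with one reference dose curve per energy.  The
driver corrects each session for recombination and polarity, averages the
session ionization curves, fits the optimal shift against the reference, and
aggregates: per-serial means over energies, type-level mean and standard
deviation, per-energy means over serials and their max-minus-min spread, and
the clinical impact of the shift at the protocol reference depth.

Standard deviations are sample SDs (n-1).  Because it is ambiguous whether a
type-level SD should be taken over the serial means or over all
(serial, energy) shift values, both are reported, labelled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corrections import correct_scan
from .epom import EPOMConfig, find_epom
from .physics import BURNS, compute_r50, reference_depth
from .scan_io import DepthValueCurve, Quantity, average_curves, read_scan, resample


@dataclass(frozen=True)
class ShiftSummary:
    """Aggregate of one chamber type's optimal shifts (all in cm)."""

    chamber_type: str
    per_serial: dict  # serial -> {"per_energy": {energy: dz}, "mean": float}
    type_mean: float  # mean of serial means
    type_sd: float  # sample SD over all (serial, energy) values
    serial_means_sd: float  # sample SD over the serial means
    energy_means: dict  # energy -> mean dz over serials
    energy_spread: float  # max - min of energy means


def summarize_shifts(shifts: pd.DataFrame, chamber_type: str) -> ShiftSummary:
    """Aggregate a table with columns ``serial``, ``energy``, ``dz_cm``.

    Permutation-invariant in both serials and energies.
    """
    required = {"serial", "energy", "dz_cm"}
    if not required.issubset(shifts.columns):
        raise ValueError(f"shift table needs columns {sorted(required)}")
    if len(shifts) == 0:
        raise ValueError("empty shift table")
    per_serial = {}
    for serial, group in shifts.groupby("serial"):
        per_energy = dict(zip(group["energy"].astype(str), group["dz_cm"].astype(float)))
        per_serial[serial] = {"per_energy": per_energy, "mean": float(group["dz_cm"].mean())}
    serial_means = np.array([entry["mean"] for entry in per_serial.values()])
    all_values = shifts["dz_cm"].to_numpy(dtype=float)
    energy_means = {
        str(energy): float(group["dz_cm"].mean())
        for energy, group in shifts.groupby("energy")
    }
    return ShiftSummary(
        chamber_type=chamber_type,
        per_serial=per_serial,
        type_mean=float(serial_means.mean()),
        type_sd=float(all_values.std(ddof=1)) if all_values.size > 1 else 0.0,
        serial_means_sd=float(serial_means.std(ddof=1)) if serial_means.size > 1 else 0.0,
        energy_means=energy_means,
        energy_spread=float(max(energy_means.values()) - min(energy_means.values())),
    )


def dose_difference_at_reference_depth(
    pdd: DepthValueCurve, dz_opt: float, r50: float
) -> float:
    """|PDD(z_ref + dz) - PDD(z_ref)| in percentage points of the normalized curve.

    Measures what ignoring the EPOM shift costs at the protocol reference
    depth z_ref = 0.6 R50 - 0.1 cm, where reference dosimetry is performed.
    """
    pdd = pdd.require(Quantity.DOSE).normalized()
    z_ref = reference_depth(r50)
    lo, hi = pdd.span
    if not (lo <= z_ref <= hi and lo <= z_ref + dz_opt <= hi):
        raise ValueError(
            f"z_ref = {z_ref:g} cm (+ shift {dz_opt:g}) outside curve support [{lo:g}, {hi:g}]"
        )
    values = resample(pdd, np.array([z_ref, z_ref + dz_opt]))
    return float(abs(values[1] - values[0]))


def discover_study(study_dir: str | Path) -> dict:
    """Build a study layout from the fixture naming convention.

    Expects ``ref_<energy>.csv`` reference curves and
    ``<type>_<serial>_<energy>_s<session>.csv`` raw scans.  The ground-truth
    manifest, if present, is deliberately ignored.
    """
    study_dir = Path(study_dir)
    layout: dict = {"references": {}, "scans": {}}
    for path in sorted(study_dir.glob("ref_*.csv")):
        layout["references"][path.stem.split("_", 1)[1]] = path
    for path in sorted(study_dir.glob("*_*_*_s*.csv")):
        chamber_type, serial, energy, session = path.stem.rsplit("_", 3)
        key = (chamber_type, serial, energy)
        layout["scans"].setdefault(key, []).append(path)
    if not layout["scans"]:
        raise ValueError(f"no chamber scans found in {study_dir}")
    return layout


def run_study(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    cfg: EPOMConfig | None = None,
) -> dict:
    """Run the full analysis over a study directory and return the report.

    Per (type, serial, energy): correct every session scan, average the
    ionization curves, fit the EPOM shift against that energy's reference
    curve.  Per-scan failures are collected in the report; only a missing
    reference curve for an energy with scans aborts the run.  When ``out_dir``
    is given, writes ``report.json``, ``shifts.csv``, ``corrections.csv`` and
    ``energy_means.csv`` (figure-ready: dz versus R50 per chamber type).
    """
    cfg = cfg or EPOMConfig()
    layout = discover_study(study_dir)
    needed = {energy for (_, _, energy) in layout["scans"]}
    missing = sorted(needed - set(layout["references"]))
    if missing:
        raise ValueError(f"no reference curve for energy/energies: {missing}")

    references = {}
    r50s = {}
    for energy, path in layout["references"].items():
        curve = read_scan(path, quantity=Quantity.DOSE)
        references[energy] = curve
        r50s[energy] = compute_r50(curve)

    rows = []
    correction_rows = []
    failures = []
    for (chamber_type, serial, energy), paths in sorted(layout["scans"].items()):
        try:
            corrected = []
            for path in paths:
                readings = read_scan(path)
                curve, profile = correct_scan(readings)
                corrected.append(curve)
                correction_rows += [
                    {
                        "chamber_type": chamber_type, "serial": serial, "energy": energy,
                        "file": Path(path).name, "depth_cm": z, "ks": s, "kpol": p,
                    }
                    for z, s, p in zip(profile.depth, profile.ks, profile.kpol)
                ]
            mean_pdi = average_curves(corrected)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # infeasible-dz drops are expected
                result = find_epom(references[energy], mean_pdi, r50s[energy], cfg)
            rows.append(
                {
                    "chamber_type": chamber_type, "serial": serial, "energy": energy,
                    "r50_cm": r50s[energy], "dz_cm": result.dz_opt,
                    "rms_min": result.rms_min, "n_points": result.n_points,
                    "n_sessions": len(paths),
                }
            )
        except (ValueError, OSError) as exc:
            failures.append({"chamber_type": chamber_type, "serial": serial,
                             "energy": energy, "error": str(exc)})

    shifts = pd.DataFrame(rows)
    report: dict = {
        "provenance": {
            "sp_depth_convention": cfg.sp_depth_convention,
            "amplitude_mode": cfg.amplitude_mode,
            "dz_grid_cm": [cfg.dz_min, cfg.dz_max, cfg.dz_step],
            "eval_window": [cfg.eval_z_min, cfg.eval_zr_max],
            "sd_definition": "sample SD (n-1); type SD over all (serial, energy) values,"
                             " SD over serial means reported separately",
        },
        "r50_cm": r50s,
        "failures": failures,
        "types": {},
    }
    for chamber_type, group in shifts.groupby("chamber_type"):
        summary = summarize_shifts(group, str(chamber_type))
        ref_impacts = {}
        for energy, dz in summary.energy_means.items():
            ref_impacts[energy] = dose_difference_at_reference_depth(
                references[energy], dz, r50s[energy]
            )
        report["types"][str(chamber_type)] = {
            "type_mean_cm": summary.type_mean,
            "type_sd_cm": summary.type_sd,
            "serial_means_sd_cm": summary.serial_means_sd,
            "per_serial": summary.per_serial,
            "energy_means_cm": summary.energy_means,
            "energy_spread_cm": summary.energy_spread,
            "refdepth_dose_diff_pct": ref_impacts,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        shifts.to_csv(out_dir / "shifts.csv", index=False)
        pd.DataFrame(correction_rows).to_csv(out_dir / "corrections.csv", index=False)
        energy_rows = [
            {"chamber_type": t, "energy": e, "r50_cm": r50s[e], "dz_mean_cm": dz}
            for t, entry in report["types"].items()
            for e, dz in entry["energy_means_cm"].items()
        ]
        pd.DataFrame(energy_rows).sort_values(
            ["chamber_type", "r50_cm"], ignore_index=True
        ).to_csv(out_dir / "energy_means.csv", index=False)
    return report
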