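"""Synthetic water-tank data with known ground truth.

Every stage of the analysis chain (correction, conversion, shift fitting,
aggregation) is exercised against simulated scans whose true EPOM shift,
noise level and correction profiles are known, because the real study's
water-tank scans are not publicly archived.

The reference depth-dose family is analytic, not a Monte Carlo surrogate:

* build-up from ``surface_frac * 100`` at the surface to exactly 100 at
  ``zmax`` (raised-sine, C^1 at both ends);
* distal falloff ``exp(-((z - zmax)/lam)^p)`` with ``lam`` and ``p`` solved in
  closed form so the curve crosses exactly 50 at ``r50`` and has essentially
  vanished at the practical range ``rp``;
* a linear bremsstrahlung-like tail of relative amplitude ``tail_frac``
  decaying to zero well beyond ``rp``.

The chamber scan inverts the analysis chain: the ideal ionization signal is
the reference dose at the shifted depth divided by the stopping-power ratio
there, and the raw two-voltage / two-polarity channels are constructed so the
protocol corrections recover it exactly.  Multiplicative Gaussian noise is
applied per channel, seeded for exact reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corrections import TRS398_PULSED_KS, two_voltage_ratio_for_ks
from .physics import BURNS, BurnsStoppingPower
from .scan_io import DepthValueCurve, Quantity, RawDepthReadings, write_raw, write_scan


@dataclass(frozen=True)
class SyntheticBeam:
    """Analytic electron-beam shape parameters (all depths in cm)."""

    r50: float
    rp: float
    surface_frac: float
    zmax: float
    tail_frac: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.zmax < self.r50 < self.rp):
            raise ValueError("need 0 < zmax < r50 < rp")
        if not (0 < self.surface_frac < 1):
            raise ValueError("surface_frac must be in (0, 1)")
        if not (0 <= self.tail_frac < 0.1):
            raise ValueError("tail_frac must be in [0, 0.1)")

    @classmethod
    def nominal(cls, energy: str) -> "SyntheticBeam":
        """Typical clinical-linac beams at the four nominal energies studied."""
        table = {
            "6": dict(r50=2.40, surface_frac=0.81, tail_frac=0.005),
            "12": dict(r50=4.93, surface_frac=0.88, tail_frac=0.015),
            "18": dict(r50=7.37, surface_frac=0.92, tail_frac=0.030),
            "22": dict(r50=8.82, surface_frac=0.94, tail_frac=0.040),
        }
        if energy not in table:
            raise KeyError(f"no nominal beam for energy {energy!r}; have {sorted(table)}")
        p = table[energy]
        r50 = p["r50"]
        return cls(
            r50=r50,
            rp=1.271 * r50 - 0.23,
            surface_frac=p["surface_frac"],
            zmax=min(0.58 * r50, 3.0),
            tail_frac=p["tail_frac"],
        )


def _falloff_params(beam: SyntheticBeam) -> tuple[float, float, float]:
    """Closed-form (lam, p, z_end) so the main falloff passes 50 at r50 and ~0.5% at rp."""
    z_end = 1.5 * beam.rp  # tail extinction depth
    t_r50 = (z_end - beam.r50) / (z_end - beam.zmax)
    phi1 = (0.5 - beam.tail_frac * t_r50) / (1.0 - beam.tail_frac)
    phi2 = 0.005 / (1.0 - beam.tail_frac)
    u1 = beam.r50 - beam.zmax
    u2 = beam.rp - beam.zmax
    p = np.log(np.log(phi2) / np.log(phi1)) / np.log(u2 / u1)
    lam = u1 / (-np.log(phi1)) ** (1.0 / p)
    return lam, p, z_end


def pdd_value(beam: SyntheticBeam, z: np.ndarray | float) -> np.ndarray | float:
    """Analytic percentage depth dose of ``beam`` at depth ``z`` (cm)."""
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    lam, p, z_end = _falloff_params(beam)
    out = np.empty_like(z_arr)
    rising = z_arr <= beam.zmax
    s = beam.surface_frac
    out[rising] = 100.0 * (s + (1 - s) * np.sin(0.5 * np.pi * z_arr[rising] / beam.zmax) ** 2)
    u = z_arr[~rising] - beam.zmax
    main = np.exp(-((u / lam) ** p))
    tail = np.clip((z_end - z_arr[~rising]) / (z_end - beam.zmax), 0.0, 1.0)
    out[~rising] = 100.0 * ((1 - beam.tail_frac) * main + beam.tail_frac * tail)
    return float(out[0]) if np.isscalar(z) else out


def make_reference_pdd(beam: SyntheticBeam, depths: np.ndarray) -> DepthValueCurve:
    """Sample the analytic PDD on ``depths`` as the reference-detector curve.

    The grid must span at least [0.05, 1.25 r50] so that every shifted lookup
    the grid search needs stays inside measured support.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.min() > 0.05 or depths.max() < 1.25 * beam.r50:
        raise ValueError(
            f"reference grid [{depths.min():g}, {depths.max():g}] cm must span"
            f" [0.05, {1.25 * beam.r50:g}] cm"
        )
    meta = {"detector": "synthetic-reference", "r50_true": beam.r50}
    return DepthValueCurve(depths, pdd_value(beam, depths), Quantity.DOSE, meta)


def default_reference_grid(beam: SyntheticBeam, step: float = 0.02) -> np.ndarray:
    return np.round(np.arange(0.02, 1.25 * beam.r50 + 0.3 + step / 2, step), 6)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one simulated chamber scan.

    The kS and kpol depth profiles are linear in the scaled depth z/R50:
    ``ks(z) = ks0 + ks1 * z/r50`` (and likewise kpol), which reproduces the
    slowly varying depth dependence seen in electron beams while staying
    exactly invertible and JSON-serializable.
    """

    dz_true: float
    noise_sigma: float = 0.003
    seed: int = 0
    ks0: float = 1.002
    ks1: float = 0.004
    kpol0: float = 0.998
    kpol1: float = 0.005
    v1: float = 400.0
    v2: float = 200.0

    def ks_profile(self, z: np.ndarray, r50: float) -> np.ndarray:
        return self.ks0 + self.ks1 * np.asarray(z) / r50

    def kpol_profile(self, z: np.ndarray, r50: float) -> np.ndarray:
        return self.kpol0 + self.kpol1 * np.asarray(z) / r50


def make_chamber_scan(
    ref: DepthValueCurve,
    truth: SyntheticTruth,
    beam: SyntheticBeam,
    grid_step: float = 0.1,
    model: BurnsStoppingPower = BURNS,
) -> list[RawDepthReadings]:
    """Simulate one raw chamber depth scan against a reference dose curve.

    Nominal depths run from max(0.1 cm, the shallowest depth keeping the
    shifted stopping-power argument valid) down to z/R50 = 1.2 at the shifted
    depth, in ``grid_step`` increments.  Noise-free, the full pipeline
    (correct -> fit) returns exactly ``truth.dz_true`` whenever it lies on the
    search grid.
    """
    if grid_step < 0.01:
        raise ValueError("grid_step must be >= 0.01 cm")
    from .scan_io import resample

    r50 = beam.r50
    dz = truth.dz_true
    z_start = max(0.1, model.zr_min * r50 - dz)
    z_stop = min(model.zr_max * r50 - dz, ref.span[1] - dz)
    depths = np.round(np.arange(z_start, z_stop, grid_step), 6)
    # rounding can nudge endpoints just past the validity bounds; drop those
    depths = depths[
        ((depths + dz) / r50 >= model.zr_min) & ((depths + dz) / r50 <= model.zr_max)
        & (depths + dz >= ref.span[0]) & (depths + dz <= ref.span[1])
    ]
    if depths.size < 10:
        raise ValueError("scan would have fewer than 10 depths; widen the reference grid")
    shifted = depths + dz
    ideal = resample(ref, shifted) / model.ratio(shifted, r50)

    ks = truth.ks_profile(depths, r50)
    kpol = truth.kpol_profile(depths, r50)
    m_v1 = ideal / (ks * kpol)
    ratio = np.array([two_voltage_ratio_for_ks(k, truth.v1, truth.v2) for k in ks])
    m_v2 = m_v1 / ratio
    m_pos = m_v1.copy()
    m_neg = -(2.0 * kpol - 1.0) * m_v1

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        for channel in (m_v1, m_v2, m_pos, m_neg):
            channel *= 1.0 + truth.noise_sigma * rng.standard_normal(channel.size)

    return [
        RawDepthReadings(z, a, b, c, d, truth.v1, truth.v2)
        for z, a, b, c, d in zip(depths, m_v1, m_v2, m_pos, m_neg)
    ]


# ---------------------------------------------------------------------------
# Full-study fixture: chamber types x serials x energies x sessions
# ---------------------------------------------------------------------------

#: Type-level mean shifts (cm) used as study conditions.
DEFAULT_TYPE_MEANS: dict[str, float] = {
    "NACP-02": 0.104,
    "Roos": 0.040,
    "AdvMarkus": 0.012,
}

#: Mean-zero per-energy offsets (cm) added to the type mean: minimum at 6 MeV
#: and maximum at 18 MeV, with energy spreads of 0.026, 0.020 and 0.021 cm.
DEFAULT_ENERGY_OFFSETS: dict[str, dict[str, float]] = {
    "NACP-02": {"6": -0.0150, "12": 0.0005, "18": 0.0110, "22": 0.0035},
    "Roos": {"6": -0.0115, "12": 0.0005, "18": 0.0085, "22": 0.0025},
    "AdvMarkus": {"6": -0.0120, "12": 0.0005, "18": 0.0090, "22": 0.0025},
}


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic measurement campaign.

    Defaults emulate the study conditions: 3 chamber types x 3 serials x
    4 energies x 3 repeat sessions, 0.1 cm scan step, 0.3% per-channel
    multiplicative noise, voltage pair 400/200 V, serial-to-serial true-shift
    scatter of 0.003 cm (1 sigma) around the type mean.
    """

    energies: dict[str, float] = field(
        default_factory=lambda: {"6": 2.40, "12": 4.93, "18": 7.37, "22": 8.82}
    )
    type_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MEANS))
    energy_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENERGY_OFFSETS.items()}
    )
    n_serials: int = 3
    n_sessions: int = 3
    serial_sigma: float = 0.003
    noise_sigma: float = 0.003
    grid_step: float = 0.1
    v1: float = 400.0
    v2: float = 200.0
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def make_study_fixture(config: StudyConfig, out_dir: str | Path) -> dict:
    """Write a full synthetic study to ``out_dir`` and return its truth manifest.

    Layout: ``ref_<energy>.csv`` reference PDDs (curve CSV) and
    ``<type>_<serial>_<energy>_s<session>.csv`` raw chamber scans (raw CSV),
    plus ``manifest.json`` recording every per-scan ground truth and seed.
    Identical config (including seed) reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    manifest: dict = {"config": asdict(config), "scans": [], "references": {}}

    beams = {e: SyntheticBeam.nominal(e) for e in config.energies}
    refs = {}
    for energy, beam in beams.items():
        # honour a non-default R50 by rescaling the nominal beam
        if abs(beam.r50 - config.energies[energy]) > 1e-9:
            scale = config.energies[energy] / beam.r50
            beam = SyntheticBeam(
                r50=beam.r50 * scale, rp=beam.rp * scale,
                surface_frac=beam.surface_frac, zmax=beam.zmax * scale,
                tail_frac=beam.tail_frac,
            )
            beams[energy] = beam
        ref = make_reference_pdd(beam, default_reference_grid(beam))
        refs[energy] = ref
        path = out_dir / f"ref_{energy}.csv"
        write_scan(path, ref)
        manifest["references"][energy] = {"file": path.name, "r50_true": beam.r50}

    # deterministic serial-level scatter: one spawned stream per (type, serial)
    types = sorted(config.type_means)
    serial_seq = root_seq.spawn(len(types) * config.n_serials)
    noise_seq = root_seq.spawn(
        len(types) * config.n_serials * len(config.energies) * config.n_sessions
    )
    noise_iter = iter(noise_seq)
    for t_idx, chamber_type in enumerate(types):
        for serial in range(1, config.n_serials + 1):
            rng = np.random.default_rng(serial_seq[t_idx * config.n_serials + serial - 1])
            serial_offset = config.serial_sigma * rng.standard_normal()
            for energy in sorted(config.energies, key=float):
                dz_true = (
                    config.type_means[chamber_type]
                    + config.energy_offsets[chamber_type][energy]
                    + serial_offset
                )
                for session in range(1, config.n_sessions + 1):
                    seed = int(next(noise_iter).generate_state(1)[0] % (2**31))
                    truth = SyntheticTruth(
                        dz_true=dz_true, noise_sigma=config.noise_sigma, seed=seed,
                        v1=config.v1, v2=config.v2,
                    )
                    readings = make_chamber_scan(
                        refs[energy], truth, beams[energy], config.grid_step
                    )
                    name = f"{chamber_type}_{serial}_{energy}_s{session}.csv"
                    write_raw(out_dir / name, readings)
                    manifest["scans"].append(
                        {
                            "file": name,
                            "chamber_type": chamber_type,
                            "serial": serial,
                            "energy": energy,
                            "session": session,
                            "dz_true": dz_true,
                            "noise_sigma": config.noise_sigma,
                            "seed": seed,
                        }
                    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
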