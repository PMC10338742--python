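#!/usr/bin/env python
"""Simulate the measurement campaign: 3 plane-parallel chamber types x 3
serial numbers x 4 electron energies x 3 repeat sessions of water-tank depth
scans, plus one reference depth-dose curve per energy.

Scans are written under scratch/study/ (bulky, regenerable); the ground-truth
manifest travels with them.  Run from the repository root.
"""

from pathlib import Path

from epomfit import StudyConfig, make_study_fixture

OUT = Path("scratch/study")


def main() -> None:
    config = StudyConfig(seed=0)
    manifest = make_study_fixture(config, OUT)
    n_scans = len(manifest["scans"])
    print(f"wrote {n_scans} raw chamber scans and {len(manifest['references'])} "
          f"reference curves to {OUT}/")
    print(f"energies (R50 cm): { {e: b for e, b in config.energies.items()} }")
    print(f"type-level true mean shifts (cm): {config.type_means}")
    print(f"per-channel noise: {100 * config.noise_sigma:.1f}% ; "
          f"serial scatter: {config.serial_sigma} cm (1 sigma)")
    print(f"truth manifest: {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
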