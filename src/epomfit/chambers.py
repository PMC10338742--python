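"""Plane-parallel chamber geometry constants.

Nominal dimensions of the three chamber types studied (NACP-02, PTW 34001
Roos, PTW 34045 Advanced Markus) plus the alternative NACP-02 entrance-window
models that have circulated in the literature (the published specification
versus independently reported window build-ups).  These are documentation
fixtures: nothing in the analysis chain consumes the geometry, since the EPOM
shift is determined purely from measured depth curves.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry constants of a plane-parallel ionization chamber.

    All lengths in cm; ``water_equiv_scaling`` is the manufacturer's
    water-equivalent window thickness in g/cm^2; ``sensitive_volume`` in cm^3.
    """

    name: str
    window_thickness: float
    water_equiv_scaling: float
    cavity_radius: float
    guard: float
    sensitive_volume: float

    def __post_init__(self) -> None:
        for field_name in (
            "window_thickness",
            "water_equiv_scaling",
            "cavity_radius",
            "guard",
            "sensitive_volume",
        ):
            if getattr(self, field_name) <= 0:
                raise ValueError(f"{self.name}: {field_name} must be positive")


#: Nominal dimensions of the three chamber types.
CHAMBERS: dict[str, ChamberSpec] = {
    "NACP-02": ChamberSpec("NACP-02", 0.060, 0.104, 0.500, 0.300, 0.160),
    "Roos": ChamberSpec("Roos", 0.112, 0.118, 0.800, 0.400, 0.350),
    "AdvMarkus": ChamberSpec("AdvMarkus", 0.130, 0.106, 0.250, 0.200, 0.020),
}

#: NACP-02 entrance-window variants reported in the literature
#: (window thickness cm, graphite layer cm, graphite density g/cm^3, mylar cm).
NACP02_WINDOW_MODELS: dict[str, dict[str, float]] = {
    "specification": {"window": 0.060, "graphite": 0.050, "graphite_density": 1.75, "mylar": 0.010},
    "wang": {"window": 0.090, "graphite": 0.075, "graphite_density": 1.75, "mylar": 0.015},
    "muir": {"window": 0.060, "graphite": 0.050, "graphite_density": 2.25, "mylar": 0.010},
    "chin": {"window": 0.067, "graphite": 0.050, "graphite_density": 2.25, "mylar": 0.017},
}
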