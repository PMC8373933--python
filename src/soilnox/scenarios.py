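"""Emission scenario labels.

A scenario is identified by the fraction of anthropogenic emissions retained,
the state of the soil NOx source (on / off / uniformly scaled), and which
anthropogenic species are controlled (NOx alone, or NOx + VOC + CO jointly).
The four corner scenarios carry their conventional zero-out names: BASE,
NoSoil, NoAnthro, NoAnthroSoil.  Label strings round-trip through
:meth:`ScenarioLabel.parse`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_CANONICAL = {
    "BASE": (1.0, "on"),
    "NoSoil": (1.0, "off"),
    "NoAnthro": (0.0, "on"),
    "NoAnthroSoil": (0.0, "off"),
}
_LABEL_RE = re.compile(
    r"^A(?P<pct>\d{1,3})_S(?P<soil>on|off|x(?P<factor>[\d.]+))(?P<joint>_joint)?$"
)


@dataclass(frozen=True)
class ScenarioLabel:
    anthro_fraction: float = 1.0        # 1.0 = full emissions, 0.0 = NoAnthro
    soil_mode: str = "on"               # "on" | "off" | "scaled:<factor>"
    controlled_species: str = "NOx-only"  # or "NOx+VOC+CO"

    def __post_init__(self):
        if not 0.0 <= self.anthro_fraction <= 1.0:
            raise ValueError("anthro_fraction must lie in [0, 1]")
        if self.soil_mode not in ("on", "off") and not self.soil_mode.startswith("scaled:"):
            raise ValueError(f"invalid soil_mode {self.soil_mode!r}")
        if self.controlled_species not in ("NOx-only", "NOx+VOC+CO"):
            raise ValueError(f"invalid controlled_species {self.controlled_species!r}")

    @property
    def soil_factor(self) -> float:
        if self.soil_mode == "on":
            return 1.0
        if self.soil_mode == "off":
            return 0.0
        return float(self.soil_mode.split(":", 1)[1])

    def __str__(self) -> str:
        if self.controlled_species == "NOx-only":
            for name, (af, sm) in _CANONICAL.items():
                if self.anthro_fraction == af and self.soil_mode == sm:
                    return name
        soil = {"on": "on", "off": "off"}.get(self.soil_mode)
        if soil is None:
            soil = f"x{self.soil_factor:g}"
        s = f"A{int(round(100 * self.anthro_fraction)):03d}_S{soil}"
        if self.controlled_species == "NOx+VOC+CO":
            s += "_joint"
        return s

    @classmethod
    def parse(cls, s: str) -> "ScenarioLabel":
        if s in _CANONICAL:
            af, sm = _CANONICAL[s]
            return cls(anthro_fraction=af, soil_mode=sm)
        m = _LABEL_RE.match(s)
        if not m:
            raise ValueError(
                f"unrecognised scenario label {s!r}; expected one of "
                f"{sorted(_CANONICAL)} or the pattern A<pct>_S<on|off|x<f>>[_joint]"
            )
        soil = m.group("soil")
        mode = soil if soil in ("on", "off") else f"scaled:{float(m.group('factor')):g}"
        return cls(
            anthro_fraction=int(m.group("pct")) / 100.0,
            soil_mode=mode,
            controlled_species="NOx+VOC+CO" if m.group("joint") else "NOx-only",
        )


def reduction_ladder(soil_mode: str = "on", fractions=(1.0, 0.8, 0.6, 0.4, 0.2, 0.0),
                     controlled_species: str = "NOx-only"):
    """Scenario labels for an anthropogenic emission-reduction ladder."""
    return [ScenarioLabel(anthro_fraction=f, soil_mode=soil_mode,
                          controlled_species=controlled_species) for f in fractions]
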