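"""Radionuclide decay data: half-life and emission spectrum.

The dose formalism only needs, per emission, the particle type (photon or
beta/electron), the energy in MeV (mean energy for beta spectra) and the
yield per decay.  Positrons are encoded as a ``beta`` emission with the mean
spectrum energy plus two 0.511 MeV annihilation photons, which keeps the
dosimetry code nuclide-agnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

PARTICLE_TYPES = ("photon", "beta", "electron")

#: F-18 physical half-life in minutes (standard nuclear-data value).
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class Emission:
    particle_type: str
    energy_mev: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.particle_type not in PARTICLE_TYPES:
            raise ValueError(
                f"unknown particle type {self.particle_type!r}; "
                f"expected one of {PARTICLE_TYPES}"
            )
        if self.energy_mev <= 0:
            raise ValueError(f"emission energy must be > 0 MeV, got {self.energy_mev}")
        if self.yield_per_decay <= 0:
            raise ValueError(f"emission yield must be > 0, got {self.yield_per_decay}")


@dataclass(frozen=True)
class NuclideData:
    """Half-life (hours) and emission list of a radionuclide."""

    name: str
    half_life_h: float
    emissions: tuple[Emission, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError(f"half-life must be > 0 h, got {self.half_life_h}")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda = ln 2 / T1/2, in h^-1."""
        return math.log(2.0) / self.half_life_h

    @classmethod
    def f18(cls) -> "NuclideData":
        """F-18: T1/2 = 109.77 min; beta+ (mean 0.2498 MeV, yield 0.9673)
        and the two 0.511 MeV annihilation photons."""
        return cls(
            name="F-18",
            half_life_h=F18_HALF_LIFE_MIN / 60.0,
            emissions=(
                Emission("beta", 0.2498, 0.9673),
                Emission("photon", 0.511, 2 * 0.9673),
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NuclideData":
        """Load from a JSON file with keys ``name``, ``half_life_min`` (or
        ``half_life_h``) and ``emissions``: [{type, energy_MeV, yield}]."""
        with open(path) as fh:
            raw = json.load(fh)
        if "half_life_min" in raw:
            hl = float(raw["half_life_min"]) / 60.0
        elif "half_life_h" in raw:
            hl = float(raw["half_life_h"])
        else:
            raise ValueError(f"{path}: needs half_life_min or half_life_h")
        emissions = tuple(
            Emission(e["type"], float(e["energy_MeV"]), float(e["yield"]))
            for e in raw.get("emissions", [])
        )
        return cls(name=raw.get("name", Path(path).stem), half_life_h=hl, emissions=emissions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "half_life_min": self.half_life_h * 60.0,
            "emissions": [
                {"type": e.particle_type, "energy_MeV": e.energy_mev, "yield": e.yield_per_decay}
                for e in self.emissions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
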