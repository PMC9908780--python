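"""SAF-based absorbed-dose coefficients and ICRP 103 effective dose.

The MIRD/ICRP S-value formalism: the absorbed dose rate to target T per
unit activity in source S is

    S(T <- S) = sum_emissions  y_i  E_i  SAF(T <- S; type_i, E_i)

in MeV/kg per decay; multiplying by a TIAC (MBq h/MBq) and the unit
conversion 3.6e9 decays/(MBq h) x 1.602e-13 J/MeV x 1e3 mGy/Gy gives the
absorbed dose coefficient in mGy/MBq.  The effective dose is the
tissue-weighted sex-average  E = sum_T w_T (H_T^male + H_T^female)/2  with
radiation weighting 1 for photons, electrons and positrons.

Reference-phantom SAF datasets are external user inputs; the package ships
only loaders plus small synthetic fixtures for testing the formalism.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nuclide import NuclideData
from .tiac import TIACTable

_DATA_DIR = Path(__file__).parent / "data"
ICRP103_WEIGHTS_PATH = _DATA_DIR / "tissue_weights_icrp103.json"
ICRP60_WEIGHTS_PATH = _DATA_DIR / "tissue_weights_icrp60.json"

#: mGy per MBq h per (MeV/kg): 3.6e9 x 1.602176634e-13 x 1e3
MGY_PER_MBQH_PER_MEV_KG = 3.6e9 * 1.602176634e-13 * 1e3


class SAFTable:
    """Specific absorbed fractions (kg^-1) per (source, target, type, energy).

    Energy interpolation is linear on the tabulated grid of each
    (source, target, type) triple.  A missing source-target pair yields an
    explicit zero with a warning — cross-fire absent from a table must never
    be silently invented.
    """

    def __init__(self, table: pd.DataFrame, phantom: str = "n/a"):
        required = {"source", "target", "particle_type", "energy_MeV", "saf_per_kg"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"SAF table missing columns: {sorted(missing)}")
        if (table["saf_per_kg"] < 0).any():
            raise ValueError("SAFs must be >= 0")
        self.table = table
        self.phantom = phantom
        self._groups = {
            key: grp.sort_values("energy_MeV")
            for key, grp in table.groupby(["source", "target", "particle_type"])
        }

    @classmethod
    def from_csv(cls, path, phantom: str | None = None) -> "SAFTable":
        return cls(pd.read_csv(path, comment="#"), phantom=phantom or str(path))

    @property
    def sources(self) -> list[str]:
        return sorted(self.table["source"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.table["target"].unique())

    def saf(self, source: str, target: str, particle_type: str, energy_mev: float) -> float:
        kind = "beta" if particle_type in ("beta", "electron") else particle_type
        grp = self._groups.get((source, target, kind))
        if grp is None:
            warnings.warn(
                f"no SAF rows for {target!r} <- {source!r} ({kind}); using 0",
                stacklevel=2,
            )
            return 0.0
        e = grp["energy_MeV"].to_numpy()
        s = grp["saf_per_kg"].to_numpy()
        return float(np.interp(energy_mev, e, s))

    def sha256(self) -> str:
        payload = self.table.to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass(frozen=True)
class TissueWeights:
    """ICRP tissue weighting factors w_T (must sum to 1)."""

    scheme: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"tissue weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("tissue weights must be >= 0")

    @classmethod
    def from_json(cls, path) -> "TissueWeights":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(scheme=raw["scheme"], weights={k: float(v) for k, v in raw["weights"].items()})

    @classmethod
    def icrp103(cls) -> "TissueWeights":
        return cls.from_json(ICRP103_WEIGHTS_PATH)

    @classmethod
    def icrp60(cls) -> "TissueWeights":
        return cls.from_json(ICRP60_WEIGHTS_PATH)


@dataclass
class DoseReport:
    """Per-target absorbed dose coefficients (mGy/MBq) for one phantom."""

    doses: pd.Series
    sex: str = "n/a"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.doses < 0).any():
            raise ValueError("absorbed doses must be >= 0")

    def __getitem__(self, target: str) -> float:
        return float(self.doses[target])

    def to_frame(self, reference: pd.Series | None = None) -> pd.DataFrame:
        frame = self.doses.rename("dose_mGy_per_MBq").to_frame()
        if reference is not None:
            frame["diff_vs_reference_pct"] = [
                dose_percent_diff(self.doses[t], reference.get(t)) for t in frame.index
            ]
        return frame


def s_value(source: str, target: str, saf: SAFTable, nuclide: NuclideData) -> float:
    """S-value in mGy/MBq per MBq h/MBq (additive over the emission list)."""
    mev_per_kg = sum(
        em.yield_per_decay * em.energy_mev * saf.saf(source, target, em.particle_type, em.energy_mev)
        for em in nuclide.emissions
    )
    return mev_per_kg * MGY_PER_MBQH_PER_MEV_KG


def organ_doses(
    tiacs: TIACTable,
    saf: SAFTable,
    nuclide: NuclideData,
    source_map: dict[str, str] | None = None,
    bladder_wall_override: float | None = None,
    bladder_wall_target: str = "Urinary bladder wall",
    bladder_source: str = "UB contents",
    sex: str = "n/a",
) -> DoseReport:
    """D(T) = sum_S TIAC_S x S(T <- S) over every target of the SAF table.

    ``source_map`` renames TIAC source regions to the SAF vocabulary (e.g.
    "Other" -> a total-body-minus-sources surrogate region); identity by
    default.  When ``bladder_wall_override`` is given (the dynamic-bladder
    wall dose from the content source), it replaces the static content
    contribution to the bladder wall while cross-fire from all other sources
    is kept.
    """
    source_map = source_map or {}
    doses = pd.Series(0.0, index=saf.targets)
    for region in tiacs.entries.index:
        mapped = source_map.get(region, region)
        if mapped not in saf.sources:
            raise KeyError(
                f"TIAC source region {region!r} (mapped to {mapped!r}) "
                "has no rows in the SAF table"
            )
        for target in doses.index:
            if bladder_wall_override is not None and (
                target == bladder_wall_target and mapped == bladder_source
            ):
                continue
            doses[target] += tiacs[region] * s_value(mapped, target, saf, nuclide)
    if bladder_wall_override is not None:
        doses[bladder_wall_target] += bladder_wall_override
    provenance = {
        "saf_sha256": saf.sha256(),
        "phantom": saf.phantom,
        "nuclide": nuclide.name,
        "bladder_wall_override": bladder_wall_override,
    }
    return DoseReport(doses=doses, sex=sex, provenance=provenance)


def effective_dose(
    male: DoseReport,
    female: DoseReport,
    weights: TissueWeights,
) -> float:
    """Sex-averaged tissue-weighted effective dose, mSv/MBq.

    Targets present in only one phantom (gonads, prostate, uterus) enter the
    average with the other sex contributing zero dose, per the sex-averaging
    convention for sex-specific organs.
    """
    total = 0.0
    for target, w in weights.weights.items():
        if w == 0:
            continue
        in_m = target in male.doses.index
        in_f = target in female.doses.index
        if not in_m and not in_f:
            raise KeyError(
                f"weighted target {target!r} (w={w}) missing from both dose reports"
            )
        hm = male[target] if in_m else 0.0
        hf = female[target] if in_f else 0.0
        total += w * (hm + hf) / 2.0
    return total


def dose_percent_diff(revised: float, reference: float | None) -> float | None:
    """100 x (revised - reference)/reference; None marks N/A."""
    if reference is None or (isinstance(reference, float) and np.isnan(reference)):
        return None
    if reference == 0:
        return None
    return 100.0 * (revised - reference) / reference
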