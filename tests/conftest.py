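import numpy as np
import pandas as pd
import pytest

from fdgdose import CompartmentalSystem, NuclideData, SAFTable
from fdgdose.bladder import VolumeSAFTable


@pytest.fixture(scope="session")
def default_system() -> CompartmentalSystem:
    return CompartmentalSystem.default()


@pytest.fixture(scope="session")
def f18() -> NuclideData:
    return NuclideData.f18()


@pytest.fixture()
def two_compartment() -> CompartmentalSystem:
    return CompartmentalSystem(["A", "B"], [("A", "B", 1.0)], "A")


def _toy_saf_frame() -> pd.DataFrame:
    """Synthetic 3-region SAF fixture (not a real phantom dataset)."""
    rows = []
    regions = ["R1", "R2", "R3"]
    rng = np.random.default_rng(1234)
    for src in regions:
        for tgt in regions:
            for ptype in ("photon", "beta"):
                for e in (0.05, 0.2, 0.511, 1.0):
                    base = 0.5 if src == tgt else 0.01
                    rows.append(
                        {
                            "source": src,
                            "target": tgt,
                            "particle_type": ptype,
                            "energy_MeV": e,
                            "saf_per_kg": base * (1 + 0.3 * rng.random()),
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_saf() -> SAFTable:
    return SAFTable(_toy_saf_frame(), phantom="synthetic-toy")


@pytest.fixture(scope="session")
def toy_saf_frame() -> pd.DataFrame:
    return _toy_saf_frame()


def make_volume_saf(const: float | None = None) -> VolumeSAFTable:
    """Synthetic bladder-wall volume-SAF table; SAF ~ 1/volume unless const."""
    rows = []
    for ptype, scale in (("photon", 0.2), ("beta", 5.0)):
        for e in (0.05, 0.2, 0.511, 1.0):
            for v in (5.0, 50.0, 100.0, 200.0, 300.0):
                saf = scale if const is not None else scale * 200.0 / v
                rows.append(
                    {
                        "volume_ml": v,
                        "particle_type": ptype,
                        "energy_MeV": e,
                        "saf_per_kg": saf,
                    }
                )
    return VolumeSAFTable(pd.DataFrame(rows))
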