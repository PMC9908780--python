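"""Mapping compartment activities to what a PET measurement sees.

Activity quantified from a PET image of an organ cannot distinguish tracer
taken up by the parenchyma from tracer in the blood contained in the organ.
Each *sample* is therefore a fixed linear combination of compartment
activities, e.g.::

    measured lungs = 1.0 * q_Lungs + f_lungs * (q_Blood1 + q_Blood2)

where f_organ is the organ's share of the total blood volume.  The inverse
operation subtracts the blood term from a measured series to estimate the
parenchyma curve.  During fitting only the forward form is used — the blood
fractions enter as fixed coefficients, never as free parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .system import TimeActivitySet

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_BLOOD_FRACTIONS_PATH = _DATA_DIR / "blood_fractions.csv"

#: Compartments making up whole blood.  Both sub-pools are included in the
#: organ blood term: plasma and erythrocytes exchange so fast that whole
#: blood acts as a single central compartment.
BLOOD_COMPARTMENTS = ("Blood 1", "Blood 2")


@dataclass(frozen=True)
class SampleDefinition:
    """A named linear combination of compartments observed by PET."""

    sample_id: str
    terms: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"sample {self.sample_id!r}: needs at least one term")
        for comp, coeff in self.terms:
            if coeff < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative coefficient {coeff} on {comp!r}"
                )

    def evaluate(self, tacs: TimeActivitySet) -> np.ndarray:
        out = np.zeros(len(tacs.times))
        for comp, coeff in self.terms:
            if comp not in tacs.frame.columns:
                raise KeyError(f"sample {self.sample_id!r}: compartment {comp!r} not in solution")
            out += coeff * tacs.activity(comp)
        return out


@dataclass
class ObservationSeries:
    """Measured activities of one sample: times (h), values (fraction of
    administered activity) and optionally per-point SDs.

    ``variance_model`` is ``"data-based"`` (use the measured SDs as weights)
    or ``"model-based"`` (sigma = fractional SD x model prediction, default
    10%)."""

    sample_id: str
    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray | None = None
    variance_model: str = "model-based"
    model_based_fraction: float = 0.10
    decay_corrected: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError(f"sample {self.sample_id!r}: times/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError(f"sample {self.sample_id!r}: negative observed values")
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if self.sds.shape != self.values.shape:
                raise ValueError(f"sample {self.sample_id!r}: sds length mismatch")
            if np.any(self.sds <= 0):
                raise ValueError(f"sample {self.sample_id!r}: SDs must be > 0")
        if self.variance_model not in ("data-based", "model-based"):
            raise ValueError(f"unknown variance model {self.variance_model!r}")
        if self.variance_model == "data-based" and self.sds is None:
            raise ValueError(
                f"sample {self.sample_id!r}: data-based variance model requires SDs"
            )

    def __len__(self) -> int:
        return len(self.times)


def predict_samples(
    tacs: TimeActivitySet,
    definitions,
    times=None,
) -> pd.DataFrame:
    """Evaluate sample equations on an already-solved grid.

    ``times``, when given, must be a subset of the solved grid — predictions
    are never interpolated; re-solve the system on the grid you need.
    """
    if times is not None:
        times = np.asarray(times, dtype=float)
        missing = np.setdiff1d(times, tacs.times)
        if len(missing):
            raise ValueError(
                f"times {missing.tolist()} not on the solved grid; "
                "re-solve the system instead of interpolating"
            )
        sub = TimeActivitySet(
            tacs.frame.loc[times], tacs.decay_corrected, tacs.injection_amount
        )
    else:
        sub = tacs
    data = {d.sample_id: d.evaluate(sub) for d in definitions}
    return pd.DataFrame(data, index=pd.Index(sub.times, name="time_h"))


def partition_organ_activity(
    measured: np.ndarray,
    blood: np.ndarray,
    fraction: float,
) -> np.ndarray:
    """Estimated parenchyma series: measured - fraction x blood, floored at 0.

    ``fraction`` is the organ's share of the total blood volume (0 <= f < 1).
    Negative differences are physical impossibilities caused by noise; they
    are floored at zero and logged.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"blood fraction must be in [0, 1), got {fraction}")
    measured = np.asarray(measured, dtype=float)
    blood = np.asarray(blood, dtype=float)
    if measured.shape != blood.shape:
        raise ValueError("measured and blood series must share the time grid")
    parenchyma = measured - fraction * blood
    neg = parenchyma < 0
    if neg.any():
        logger.warning(
            "partition_organ_activity: %d point(s) floored at 0 "
            "(blood term exceeded measurement)", int(neg.sum()),
        )
        parenchyma = np.where(neg, 0.0, parenchyma)
    return parenchyma


def read_blood_fractions(path=DEFAULT_BLOOD_FRACTIONS_PATH) -> dict[str, float]:
    """organ -> fraction of total blood, from a two-column CSV."""
    table = pd.read_csv(path, comment="#")
    fractions = dict(zip(table["organ"], table["fraction"].astype(float)))
    for organ, f in fractions.items():
        if not 0 <= f < 1:
            raise ValueError(f"blood fraction for {organ!r} out of [0, 1): {f}")
    return fractions


def default_sample_definitions(
    blood_fractions: dict[str, float] | None = None,
) -> list[SampleDefinition]:
    """Sample equations for the shipped model.

    Whole blood is observed directly; each organ measurement is parenchyma
    plus its regional blood content; the two heart-wall and "Other" pools are
    observed jointly; urine is the cumulative bladder content.
    """
    if blood_fractions is None:
        blood_fractions = read_blood_fractions()
    blood_terms = tuple((c, 1.0) for c in BLOOD_COMPARTMENTS)
    defs = [
        SampleDefinition("blood", blood_terms),
        # plasma and erythrocytes are also measured separately (well-counter
        # samples); without them the fast exchange between the two blood
        # pools is not identifiable from whole blood alone
        SampleDefinition("plasma", (("Blood 1", 1.0),)),
        SampleDefinition("erythrocytes", (("Blood 2", 1.0),)),
    ]
    organ_compartments = {
        "brain": ("Brain",),
        "lungs": ("Lungs",),
        "liver": ("Liver",),
        "heart wall": ("Heart wall 1", "Heart wall 2"),
        "kidneys": ("Kidneys",),
        "pancreas": ("Pancreas",),
        "spleen": ("Spleen",),
    }
    for sample_id, comps in organ_compartments.items():
        f = blood_fractions.get(comps[0], 0.0)
        terms = tuple((c, 1.0) for c in comps) + tuple((c, f) for c in BLOOD_COMPARTMENTS)
        defs.append(SampleDefinition(sample_id, terms))
    defs.append(SampleDefinition("urine", (("UB contents", 1.0),)))
    return defs


def sample_definitions_from_json(path) -> list[SampleDefinition]:
    """{sample_id: [{compartment, coefficient}, ...], ...}"""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        SampleDefinition(sid, tuple((t["compartment"], float(t["coefficient"])) for t in terms))
        for sid, terms in raw.items()
    ]
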