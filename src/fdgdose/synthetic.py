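"""Synthetic data with the statistical structure the analysis assumes.

The study data behind the shipped transfer coefficients (serial blood
samples, PET organ time-activity measurements, cumulative urine collections
and single bladder PET snapshots) are not publicly deposited.  This module
generates stand-ins with the same design so the fitting and cohort-summary
machinery is testable end to end:

* time-activity observations are the *with-blood* sample-equation
  predictions of a known truth system, perturbed by multiplicative Gaussian
  noise (default fractional SD 10%, matching the model-based variance
  weight) and truncated at zero;
* bladder snapshot cohorts mimic a PET protocol with an encouraged void
  ~40-49 min p.i. and imaging ~60 min p.i., with inter-patient variability
  in void time and urinary production rate; reported %IA is physical (not
  decay-corrected), as a PET scanner sees it.

The 23-patient measured cohort shipped under ``data/`` is real published
data, kept separate from anything generated here.

Sampling-time defaults mirror the data inventory the model was built from:
blood densely over 0-8 h, heart wall / liver / lungs to 95 min, the other
organs on sparse grids, urine cumulatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bladder import BladderConfig, simulate_bladder
from .measurement import ObservationSeries, SampleDefinition, default_sample_definitions
from .nuclide import NuclideData
from .system import CompartmentalSystem

_DATA_DIR = Path(__file__).parent / "data"
MEASURED_COHORT_PATH = _DATA_DIR / "bladder_cohort_measured.csv"

_MIN = 1.0 / 60.0


def default_schedules() -> dict[str, np.ndarray]:
    """Observation times (hours) per sample, mimicking the source studies."""
    return {
        "blood": np.array([2, 5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 360, 480]) * _MIN,
        # input-function-style sampling in the first minute: the
        # plasma/erythrocyte exchange equilibrates within seconds, so its
        # magnitude (not just the pool ratio) is identifiable only from
        # samples on that timescale
        "plasma": np.array([5 / 60, 10 / 60, 20 / 60, 0.5, 1, 3, 6, 12, 25, 45, 70, 95, 150])
        * _MIN,
        "erythrocytes": np.array(
            [5 / 60, 10 / 60, 20 / 60, 0.5, 1, 3, 6, 12, 25, 45, 70, 95, 150]
        ) * _MIN,
        "heart wall": np.array([3, 5, 10, 15, 25, 40, 55, 75, 95]) * _MIN,
        "liver": np.array([3, 5, 10, 15, 25, 40, 55, 75, 95]) * _MIN,
        "lungs": np.array([3, 5, 10, 15, 25, 40, 55, 75, 95]) * _MIN,
        "brain": np.array([10, 20, 30, 60, 90, 120, 180]) * _MIN,
        "kidneys": np.array([10, 20, 30, 60, 90, 120, 180]) * _MIN,
        "spleen": np.array([10, 20, 30, 60, 90, 120]) * _MIN,
        "pancreas": np.array([10, 20, 30, 60, 90, 120]) * _MIN,
        "urine": np.array([30, 60, 120, 240, 480]) * _MIN,
    }


@dataclass
class SyntheticDesign:
    """Truth system + sampling design + noise model for TAC generation."""

    truth: CompartmentalSystem
    seed: int
    schedules: dict[str, np.ndarray] = field(default_factory=default_schedules)
    sample_definitions: list[SampleDefinition] | None = None
    noise_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible synthesis")
        if self.noise_fraction < 0:
            raise ValueError("fractional SD must be >= 0")
        for sid, times in self.schedules.items():
            times = np.asarray(times, dtype=float)
            if np.any(times < 0):
                raise ValueError(f"schedule {sid!r}: negative times")
            self.schedules[sid] = times
        if self.sample_definitions is None:
            self.sample_definitions = default_sample_definitions()


def generate_tac_dataset(design: SyntheticDesign) -> list[ObservationSeries]:
    """Noisy decay-corrected observations from the truth system.

    Per-point SDs (= fractional SD x true value) are emitted so both the
    data-based and model-based variance models are exercisable downstream.
    """
    rng = np.random.default_rng(design.seed)
    defs = {d.sample_id: d for d in design.sample_definitions}
    all_times = np.unique(np.concatenate(list(design.schedules.values())))
    tacs = design.truth.solve(all_times)
    out = []
    for sample_id, times in design.schedules.items():
        if sample_id not in defs:
            raise KeyError(f"schedule {sample_id!r} has no sample definition")
        series = defs[sample_id].evaluate(tacs)
        pos = np.searchsorted(all_times, times)
        truth_vals = series[pos]
        noisy = truth_vals * (1.0 + design.noise_fraction * rng.standard_normal(len(times)))
        noisy = np.clip(noisy, 0.0, None)
        sds = design.noise_fraction * truth_vals
        out.append(
            ObservationSeries(
                sample_id=sample_id,
                times=times,
                values=noisy,
                sds=sds if design.noise_fraction > 0 else None,
                variance_model="model-based",
                model_based_fraction=design.noise_fraction or 0.10,
                decay_corrected=True,
            )
        )
    return out


def generate_bladder_snapshot_cohort(
    n: int,
    system: CompartmentalSystem,
    nuclide: NuclideData,
    seed: int,
    sex_ratio: float = 0.5,
    first_void_range_min: tuple[float, float] = (40.0, 49.0),
    void_to_scan_range_min: tuple[float, float] = (8.0, 25.0),
    production_rate_gsd: float = 1.3,
) -> pd.DataFrame:
    """Simulated single-snapshot bladder cohort (one row per patient).

    Per patient the encouraged first void is uniform over the observed
    40-49 min window, the urinary production rate is log-normal around the
    sex reference (geometric SD ``production_rate_gsd``), and the bladder
    PET snapshot is taken ``void_to_scan`` minutes after the void.  %IA is
    not decay-corrected.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sex = "M" if rng.random() < sex_ratio else "F"
        base = BladderConfig.male() if sex == "M" else BladderConfig.female()
        production = base.urine_production_ml_per_day * np.exp(
            np.log(production_rate_gsd) * rng.standard_normal()
        )
        first_void_min = rng.uniform(*first_void_range_min)
        offset_min = rng.uniform(*void_to_scan_range_min)
        cfg = BladderConfig(
            urine_production_ml_per_day=production,
            void_volume_ml=base.void_volume_ml,
            residual_volume_ml=base.residual_volume_ml,
            initial_volume_ml=base.initial_volume_ml,
            forced_void_times_h=(first_void_min * _MIN,),
            max_time_h=6.0,
            mixing=base.mixing,
        )
        traj = simulate_bladder(system, nuclide, cfg)
        t_scan = (first_void_min + offset_min) * _MIN
        rows.append(
            {
                "patient": i + 1,
                "sex": sex,
                "pct_ia": 100.0 * float(traj.activity(t_scan)[0]),
                "first_void_min": first_void_min,
                "void_to_scan_min": offset_min,
                "bladder_volume_ml": float(traj.volume_ml(t_scan)[0]),
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Mean +/- sample SD and range of the first-void time; mean %IA."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a sample SD")
    fv = records["first_void_min"].astype(float)
    return {
        "n": int(len(records)),
        "first_void_mean_min": float(fv.mean()),
        "first_void_sd_min": float(fv.std(ddof=1)),
        "first_void_min_min": float(fv.min()),
        "first_void_max_min": float(fv.max()),
        "mean_pct_ia": float(records["pct_ia"].astype(float).mean()),
    }


def load_measured_cohort() -> pd.DataFrame:
    """The 23-patient published bladder PET cohort (11 M / 12 F)."""
    return pd.read_csv(MEASURED_COHORT_PATH, comment="#")
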