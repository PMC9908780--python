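"""File formats, run configuration and the pipeline driver.

Dialect conventions: comma-separated values with '.' decimals and '#'
comment lines; time columns are hours everywhere (a ``*_min`` column name is
the only accepted way to supply minutes); report CSVs round to 3 significant
figures in E-notation, machine-readable JSON keeps full precision.  Every
written artefact carries provenance (package version, seed, input hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bladder import BladderConfig, bladder_tiac, simulate_bladder
from .dosimetry import SAFTable, TissueWeights, organ_doses
from .measurement import ObservationSeries, read_blood_fractions, sample_definitions_from_json
from .nuclide import NuclideData
from .system import CompartmentalSystem
from .tiac import tiacs_table

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def sig3(x: float) -> str:
    """3-significant-figure E-notation used in report CSVs."""
    return f"{x:.2E}"


# --------------------------------------------------------------------------- #
# readers / writers


def read_model(path) -> CompartmentalSystem:
    """Model config from YAML or JSON; schema errors name the offending key."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return CompartmentalSystem.from_config(raw)


def write_model(system: CompartmentalSystem, path) -> None:
    path = Path(path)
    cfg = system.to_config()
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def read_nuclide(path) -> NuclideData:
    return NuclideData.from_json(path)


def read_observations(path) -> list[ObservationSeries]:
    """Observation CSV: sample_id, time_h, value_frac_ia[, sd].

    Rows with an SD get the data-based variance model; a series is
    data-based only when every point has one.
    """
    table = pd.read_csv(path, comment="#")
    required = {"sample_id", "time_h", "value_frac_ia"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sample_id, grp in table.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise ValueError(f"{path}: non-monotone/duplicate times in {sample_id!r}")
        sds = None
        variance_model = "model-based"
        if "sd" in grp.columns and grp["sd"].notna().all():
            sds = grp["sd"].to_numpy(dtype=float)
            variance_model = "data-based"
        out.append(
            ObservationSeries(
                sample_id=str(sample_id),
                times=times,
                values=grp["value_frac_ia"].to_numpy(dtype=float),
                sds=sds,
                variance_model=variance_model,
            )
        )
    return out


def write_observations(observations: list[ObservationSeries], path) -> None:
    rows = []
    for obs in observations:
        for i in range(len(obs)):
            rows.append(
                {
                    "sample_id": obs.sample_id,
                    "time_h": obs.times[i],
                    "value_frac_ia": obs.values[i],
                    "sd": obs.sds[i] if obs.sds is not None else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_saf(path, phantom: str | None = None) -> SAFTable:
    table = pd.read_csv(path, comment="#")
    return SAFTable(table, phantom=phantom or str(path))


def read_reference_tiacs(path) -> pd.Series:
    table = pd.read_csv(path, comment="#")
    return pd.Series(
        table["tiac_mbqh_per_mbq"].astype(float).to_numpy(),
        index=table["source_region"],
    )


# --------------------------------------------------------------------------- #
# pipeline


@dataclass
class RunConfig:
    """Paths and settings for a full simulate -> TIAC -> bladder -> dose run."""

    model_path: str
    nuclide_path: str
    output_dir: str
    seed: int = 0
    observations_path: str | None = None
    sample_definitions_path: str | None = None
    blood_fractions_path: str | None = None
    saf_path: str | None = None
    weights_path: str | None = None
    reference_tiacs_path: str | None = None
    fit_free_parameters: str | list = "all"
    fit_starts: int = 10
    bladder_male: BladderConfig = field(default_factory=BladderConfig.male)
    bladder_female: BladderConfig = field(default_factory=BladderConfig.female)
    skip_dose: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("model_path", "nuclide_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline stages and write the artefact bundle.

    Stages: simulate -> (fit when observations given) -> TIAC -> dynamic
    bladder -> (dose when SAF given).  Any stage failure aborts with the
    stage name; outputs land in ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "package": f"fdgdose {__version__}",
        "seed": config.seed,
        "inputs": {
            "model": _sha256(config.model_path),
            "nuclide": _sha256(config.nuclide_path),
        },
    }
    artefacts: dict = {"provenance": provenance}
    stage = "read-inputs"
    try:
        system = read_model(config.model_path)
        nuclide = read_nuclide(config.nuclide_path)

        stage = "simulate"
        times = np.concatenate([[0.0], np.geomspace(1e-3, 12.0, 400)])
        tacs = system.solve(times)
        tacs.to_csv(out_dir / "tacs_decay_corrected.csv")
        artefacts["tacs"] = tacs

        if config.observations_path:
            stage = "fit"
            from .fitting import BiokineticModel

            observations = read_observations(config.observations_path)
            provenance["inputs"]["observations"] = _sha256(config.observations_path)
            if config.sample_definitions_path:
                defs = sample_definitions_from_json(config.sample_definitions_path)
            else:
                from .measurement import default_sample_definitions

                fractions = (
                    read_blood_fractions(config.blood_fractions_path)
                    if config.blood_fractions_path
                    else None
                )
                defs = default_sample_definitions(fractions)
            model = BiokineticModel(observations, system, defs, config.fit_free_parameters)
            results = model.fit(n_starts=config.fit_starts, seed=config.seed,
                                start_values=_free_start(model, system))
            payload = {"provenance": provenance, **results.to_dict()}
            with open(out_dir / "fit.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            results.corr.to_csv(out_dir / "fit_correlations.csv")
            system = results.fitted_system()
            artefacts["fit"] = results

        stage = "tiac"
        table = tiacs_table(system, nuclide)
        reference = (
            read_reference_tiacs(config.reference_tiacs_path)
            if config.reference_tiacs_path
            else None
        )

        stage = "bladder"
        bladder = {}
        for sex, cfg in (("male", config.bladder_male), ("female", config.bladder_female)):
            traj = simulate_bladder(system, nuclide, cfg)
            bladder[sex] = bladder_tiac(traj)
            traj.to_frame().to_csv(out_dir / f"bladder_trajectory_{sex}.csv", index=False)
        table_m = table.with_entry("UB contents", bladder["male"])
        table_f = table.with_entry("UB contents", bladder["female"])
        frame = table_m.to_frame(reference)
        frame["tiac_mbqh_per_mbq"] = frame["tiac_mbqh_per_mbq"].map(sig3)
        frame.to_csv(out_dir / "tiacs_male.csv")
        artefacts["tiacs_male"] = table_m
        artefacts["tiacs_female"] = table_f

        if config.saf_path and not config.skip_dose:
            stage = "dose"
            saf = read_saf(config.saf_path)
            provenance["inputs"]["saf"] = _sha256(config.saf_path)
            report = organ_doses(table_m, saf, nuclide, sex="male")
            report.to_frame().to_csv(out_dir / "doses_male.csv")
            artefacts["doses_male"] = report
            if config.weights_path:
                TissueWeights.from_json(config.weights_path)  # validated; effective
                # dose needs both sexes' SAF sets — reported only when provided

        with open(out_dir / "run.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return artefacts


def _free_start(model, system) -> np.ndarray:
    """Stored system rates as the first optimiser start."""
    return np.array([system.rate(s, d) for s, d in model.free_parameters])
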