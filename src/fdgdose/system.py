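"""Linear first-order compartment system and its exact solution.

The whole-body kinetics of 2-[18F]FDG are described by a mammillary system
of linear, first-order transfers between named compartments (plasma,
erythrocytes, organs, a generic "Other" pool and the urinary-bladder
contents).  With rate matrix K (off-diagonal K[j,i] = transfer coefficient
i->j, diagonal the negative total outflow) the decay-corrected activity
vector obeys dq/dt = K q, solved exactly as q(t) = expm(K t) q0.

Rates in the shipped model span 0.20 to 441 h^-1, i.e. the system is stiff;
the matrix exponential is exact for linear systems and avoids step-size
control altogether.  An adaptive stiff integrator is used only as a test
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from .nuclide import NuclideData

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_MODEL_PATH = _DATA_DIR / "fdg_model.yaml"

#: Name of the urine collecting compartment in the shipped model.
URINE_COMPARTMENT = "UB contents"


class ModelDefinitionError(ValueError):
    """Raised when a compartmental model definition is invalid."""


@dataclass(frozen=True)
class Transfer:
    source: str
    dest: str
    rate_per_h: float


class CompartmentalSystem:
    """Named compartments, first-order transfers and the injection site.

    Parameters
    ----------
    compartments : sequence of str
        Ordered unique compartment names.
    transfers : sequence of (source, dest, rate_per_h)
        First-order transfer coefficients in h^-1; all >= 0, no self-loops,
        no duplicate edges.
    injection_compartment : str
        Compartment receiving the instantaneous unit bolus at t = 0.
    injection_amount : float
        Administered amount (1 = 100 %IA = 1 MBq per MBq).
    urine_compartment : str or None
        Terminal collecting compartment; it must have no outflow in the rate
        matrix (voiding is a discrete process handled by the bladder module).
    """

    def __init__(
        self,
        compartments,
        transfers,
        injection_compartment: str,
        injection_amount: float = 1.0,
        urine_compartment: str | None = None,
    ) -> None:
        compartments = list(compartments)
        if len(set(compartments)) != len(compartments):
            dupes = sorted({c for c in compartments if compartments.count(c) > 1})
            raise ModelDefinitionError(f"duplicate compartment names: {dupes}")
        self.compartments = compartments
        self._index = {name: i for i, name in enumerate(compartments)}

        seen: set[tuple[str, str]] = set()
        tlist: list[Transfer] = []
        for entry in transfers:
            t = entry if isinstance(entry, Transfer) else Transfer(*entry)
            for name in (t.source, t.dest):
                if name not in self._index:
                    raise ModelDefinitionError(
                        f"transfer {t.source!r} -> {t.dest!r}: unknown compartment {name!r}"
                    )
            if t.source == t.dest:
                raise ModelDefinitionError(f"self-loop forbidden: {t.source!r} -> {t.dest!r}")
            if t.rate_per_h < 0:
                raise ModelDefinitionError(
                    f"negative coefficient {t.rate_per_h} on {t.source!r} -> {t.dest!r}"
                )
            if (t.source, t.dest) in seen:
                raise ModelDefinitionError(f"duplicate transfer edge {t.source!r} -> {t.dest!r}")
            seen.add((t.source, t.dest))
            tlist.append(t)
        self.transfers = tuple(tlist)

        if injection_compartment not in self._index:
            raise ModelDefinitionError(
                f"injection compartment {injection_compartment!r} not declared"
            )
        if injection_amount <= 0:
            raise ModelDefinitionError("injection amount must be > 0")
        self.injection_compartment = injection_compartment
        self.injection_amount = float(injection_amount)

        if urine_compartment is not None and urine_compartment not in self._index:
            raise ModelDefinitionError(f"urine compartment {urine_compartment!r} not declared")
        self.urine_compartment = urine_compartment
        if urine_compartment is not None:
            outflows = [t for t in tlist if t.source == urine_compartment and t.rate_per_h > 0]
            if outflows:
                raise ModelDefinitionError(
                    f"urine compartment {urine_compartment!r} must have no outflow; "
                    f"found {outflows[0].source!r} -> {outflows[0].dest!r}"
                )

    # ------------------------------------------------------------------ #

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def rate_matrix(self) -> np.ndarray:
        """K with K[j,i] = rate i->j and K[i,i] = -(total outflow of i)."""
        n = self.n_compartments
        K = np.zeros((n, n))
        for t in self.transfers:
            i, j = self._index[t.source], self._index[t.dest]
            K[j, i] += t.rate_per_h
            K[i, i] -= t.rate_per_h
        return K

    @property
    def initial_state(self) -> np.ndarray:
        q0 = np.zeros(self.n_compartments)
        q0[self._index[self.injection_compartment]] = self.injection_amount
        return q0

    def outflow(self, compartment: str) -> float:
        """Total first-order outflow of a compartment, h^-1."""
        return sum(t.rate_per_h for t in self.transfers if t.source == compartment)

    def rate(self, source: str, dest: str) -> float:
        for t in self.transfers:
            if t.source == source and t.dest == dest:
                return t.rate_per_h
        raise KeyError(f"no transfer {source!r} -> {dest!r}")

    def with_rates(self, updates: dict[tuple[str, str], float]) -> "CompartmentalSystem":
        """Copy of the system with the given edge rates replaced."""
        new = [
            Transfer(t.source, t.dest, updates.get((t.source, t.dest), t.rate_per_h))
            for t in self.transfers
        ]
        return CompartmentalSystem(
            self.compartments, new, self.injection_compartment,
            self.injection_amount, self.urine_compartment,
        )

    # ------------------------------------------------------------------ #

    def solve(self, times) -> "TimeActivitySet":
        """Decay-corrected activities q(t) = expm(K t) q0 on the given grid.

        Times must be non-decreasing and start at >= 0 h.  Mass balance of
        the closed system is verified to 1e-9 relative.
        """
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or len(times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(times) < 0) or times[0] < 0:
            raise ValueError("times must be non-decreasing and >= 0")
        K = self.rate_matrix
        q0 = self.initial_state
        Q = _propagate(K, q0, times)
        if not np.all(np.isfinite(Q)):
            raise FloatingPointError("non-finite activities; pathological rate matrix")
        # the rate matrix conserves mass whenever every outflow re-enters
        # another compartment (no external sink); check only in that case
        if np.allclose(K.sum(axis=0), 0.0, atol=1e-10):
            total = Q.sum(axis=1)
            if not np.allclose(total, self.injection_amount, rtol=1e-9, atol=1e-12):
                raise FloatingPointError("mass balance violated beyond 1e-9 relative")
        frame = pd.DataFrame(Q, index=pd.Index(times, name="time_h"), columns=self.compartments)
        return TimeActivitySet(frame, decay_corrected=True, injection_amount=self.injection_amount)

    # ------------------------------------------------------------------ #
    # configuration round trip

    @classmethod
    def from_config(cls, config: dict) -> "CompartmentalSystem":
        """Build from a validated dict (see the shipped fdg_model.yaml)."""
        known = {"compartments", "transfers", "injection", "urine_compartment"}
        unknown = set(config) - known
        if unknown:
            raise ModelDefinitionError(f"unknown model-config keys: {sorted(unknown)}")
        try:
            compartments = list(config["compartments"])
            injection = config["injection"]
        except KeyError as err:
            raise ModelDefinitionError(f"missing model-config key: {err}") from None
        transfers = [
            (t["from"], t["to"], float(t["rate_per_h"])) for t in config.get("transfers", [])
        ]
        return cls(
            compartments,
            transfers,
            injection_compartment=injection["compartment"],
            injection_amount=float(injection.get("amount", 1.0)),
            urine_compartment=config.get("urine_compartment"),
        )

    def to_config(self) -> dict:
        cfg = {
            "compartments": list(self.compartments),
            "transfers": [
                {"from": t.source, "to": t.dest, "rate_per_h": t.rate_per_h}
                for t in self.transfers
            ],
            "injection": {
                "compartment": self.injection_compartment,
                "amount": self.injection_amount,
            },
        }
        if self.urine_compartment is not None:
            cfg["urine_compartment"] = self.urine_compartment
        return cfg

    @classmethod
    def default(cls) -> "CompartmentalSystem":
        """The shipped 13-compartment 2-[18F]FDG model."""
        with open(DEFAULT_MODEL_PATH) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CompartmentalSystem({self.n_compartments} compartments, "
            f"{len(self.transfers)} transfers, inject {self.injection_compartment!r})"
        )


def _propagate(K: np.ndarray, q0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """expm(K t) q0 for all t, via eigendecomposition when well conditioned."""
    try:
        w, V = np.linalg.eig(K)
        Vi = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            c = Vi @ q0
            Q = np.real(np.exp(np.outer(times, w)) * c @ V.T)
            return np.clip(Q, 0.0, None) if Q.min() > -1e-12 else Q
    except np.linalg.LinAlgError:
        pass
    return np.stack([expm(K * t) @ q0 for t in times])


class TimeActivitySet:
    """Per-compartment activity versus time, as fraction of administered.

    ``decay_corrected=True`` means physical decay has been divided out and
    the curves show biokinetics only; applying :meth:`apply_physical_decay`
    multiplies every activity by exp(-lambda t) and flips the flag.
    """

    def __init__(self, frame: pd.DataFrame, decay_corrected: bool, injection_amount: float = 1.0):
        if (frame.values < -1e-12).any():
            raise ValueError("activities must be >= 0")
        self.frame = frame
        self.decay_corrected = bool(decay_corrected)
        self.injection_amount = float(injection_amount)

    @property
    def times(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def compartments(self) -> list[str]:
        return list(self.frame.columns)

    def activity(self, compartment: str) -> np.ndarray:
        return self.frame[compartment].to_numpy()

    def total_body_activity(self) -> pd.Series:
        """Per-time sum over all compartments."""
        if self.frame.shape[1] == 0:
            raise ValueError("empty system: no compartments to sum")
        return self.frame.sum(axis=1)

    def apply_physical_decay(self, nuclide: NuclideData) -> "TimeActivitySet":
        """Return physical (not decay-corrected) activities."""
        if not self.decay_corrected:
            raise ValueError("activities are already physical; decay applied twice")
        factor = np.exp(-nuclide.decay_constant * self.times)
        return TimeActivitySet(
            self.frame.mul(factor, axis=0), decay_corrected=False,
            injection_amount=self.injection_amount,
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# decay_corrected: {str(self.decay_corrected).lower()}\n")
            self.frame.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "TimeActivitySet":
        decay_corrected = True
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                decay_corrected = "true" in first.lower()
                frame = pd.read_csv(fh, index_col=0)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh, index_col=0)
        frame.index.name = "time_h"
        return cls(frame, decay_corrected=decay_corrected)


def build_system(config: dict) -> CompartmentalSystem:
    """Functional alias for :meth:`CompartmentalSystem.from_config`."""
    return CompartmentalSystem.from_config(config)


def solve_biokinetics(system: CompartmentalSystem, times) -> TimeActivitySet:
    """Functional alias for :meth:`CompartmentalSystem.solve`."""
    return system.solve(times)


def apply_physical_decay(tacs: TimeActivitySet, nuclide: NuclideData) -> TimeActivitySet:
    return tacs.apply_physical_decay(nuclide)


def total_body_activity(tacs: TimeActivitySet) -> pd.Series:
    return tacs.total_body_activity()


def stiff_integrator_oracle(system: CompartmentalSystem, times) -> np.ndarray:
    """Reference solution by an adaptive implicit integrator (test oracle).

    Deliberately independent of the matrix-exponential path used by
    :meth:`CompartmentalSystem.solve`.
    """
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    K = system.rate_matrix
    sol = solve_ivp(
        lambda _t, q: K @ q,
        (0.0, float(times.max()) if len(times) else 0.0),
        system.initial_state,
        method="Radau",
        jac=lambda _t, _q: K,
        t_eval=times,
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return sol.y.T
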