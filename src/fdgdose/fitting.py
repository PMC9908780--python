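"""Weighted-least-squares estimation of transfer coefficients.

The model predictions (sample equations evaluated on the solved linear
system) are fitted simultaneously to all observation series by minimising
the sum of squared weighted residuals

    SSWR = sum_i ((y_i - yhat_i) / sigma_i)^2

with sigma_i from the series' variance model: the experimental SD where one
is available (data-based), otherwise a fixed fraction (default 10%) of the
model prediction (model-based).  Under the fitted model SSWR follows a
chi-squared distribution with N - M degrees of freedom, which yields the
goodness-of-fit p-value; the fit is conventionally rejected for p < 0.05.

The API follows the Model/Results convention: construct a
:class:`BiokineticModel` from observations + system + sample definitions,
call :meth:`~BiokineticModel.fit`, inspect the returned
:class:`BiokineticResults` (estimates, SDs, CVs, correlations, SSWR, p,
AIC/BIC) or print ``results.summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .measurement import ObservationSeries, SampleDefinition
from .system import CompartmentalSystem

__all__ = [
    "BiokineticModel",
    "BiokineticResults",
    "weighted_residuals",
    "goodness_of_fit",
    "information_criteria",
]


def weighted_residuals(
    observed: np.ndarray,
    predicted: np.ndarray,
    sds: np.ndarray | None = None,
    model_based_fraction: float = 0.10,
) -> np.ndarray:
    """(y - yhat)/sigma with sigma per the variance model.

    Points whose model-based sigma is zero (prediction exactly 0) carry no
    usable weight; they are excluded with a warning.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if sds is not None:
        sigma = np.asarray(sds, dtype=float)
    else:
        sigma = model_based_fraction * np.abs(predicted)
    ok = sigma > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} point(s) excluded: zero model-based sigma",
            stacklevel=2,
        )
    return (observed[ok] - predicted[ok]) / sigma[ok]


def goodness_of_fit(sswr: float, n_data: int, n_params: int) -> tuple[float, bool]:
    """Upper-tail chi-squared probability of the SSWR and the rejection flag
    (rejected when p < 0.05)."""
    dof = n_data - n_params
    if dof <= 0:
        raise ValueError(f"degrees of freedom must be > 0, got {dof}")
    p = float(stats.chi2.sf(sswr, dof))
    return p, p < 0.05


def information_criteria(sswr: float, n_data: int, n_params: int) -> tuple[float, float]:
    """Gaussian-WLS AIC and BIC:

        AIC = N ln(SSWR/N) + 2M,   BIC = N ln(SSWR/N) + M ln N

    Only differences between competing structures on the same data are
    meaningful.  SSWR = 0 (perfect interpolation) makes both undefined;
    a -inf sentinel is returned with a warning.
    """
    if sswr < 0:
        raise ValueError("SSWR must be >= 0")
    if sswr == 0:
        warnings.warn("SSWR = 0: information criteria undefined (-inf sentinel)", stacklevel=2)
        return -np.inf, -np.inf
    aic = n_data * np.log(sswr / n_data) + 2 * n_params
    bic = n_data * np.log(sswr / n_data) + n_params * np.log(n_data)
    return float(aic), float(bic)


class BiokineticModel:
    """Compartmental model + observations, ready to fit.

    Parameters
    ----------
    observations : list of ObservationSeries
        All series fitted simultaneously; each must match a sample
        definition by ``sample_id``.
    system : CompartmentalSystem
        Model structure; its stored rates are the fixed values of the
        non-free parameters and the reference for bound checks.
    sample_definitions : list of SampleDefinition
        Forward map from compartments to measured samples.
    free_parameters : "all" or list of (source, dest)
        Transfer edges to estimate; the rest stay fixed.
    """

    def __init__(
        self,
        observations: list[ObservationSeries],
        system: CompartmentalSystem,
        sample_definitions: list[SampleDefinition],
        free_parameters="all",
    ) -> None:
        self.observations = list(observations)
        self.system = system
        self.sample_definitions = {d.sample_id: d for d in sample_definitions}
        for obs in self.observations:
            if obs.sample_id not in self.sample_definitions:
                raise KeyError(f"no sample definition for observation {obs.sample_id!r}")
        edges = [(t.source, t.dest) for t in system.transfers]
        if free_parameters == "all":
            self.free_parameters = edges
        else:
            for edge in free_parameters:
                if tuple(edge) not in edges:
                    raise KeyError(f"free parameter {edge} is not a transfer edge")
            self.free_parameters = [tuple(e) for e in free_parameters]
        self.param_names = [f"{s} -> {d}" for s, d in self.free_parameters]
        # union grid solved once per parameter evaluation
        self._times = np.unique(np.concatenate([obs.times for obs in self.observations]))
        self.nobs = sum(len(obs) for obs in self.observations)
        self.n_params = len(self.free_parameters)
        if self.nobs - self.n_params <= 0:
            raise ValueError(
                f"dof <= 0: {self.nobs} data points for {self.n_params} parameters"
            )

    # ------------------------------------------------------------------ #

    def _system_with(self, params: np.ndarray) -> CompartmentalSystem:
        return self.system.with_rates(dict(zip(self.free_parameters, params)))

    def predict(self, params: np.ndarray) -> dict[str, np.ndarray]:
        """Sample predictions at each observation's times."""
        tacs = self._system_with(params).solve(self._times)
        out = {}
        for obs in self.observations:
            series = self.sample_definitions[obs.sample_id].evaluate(tacs)
            pos = np.searchsorted(self._times, obs.times)
            out[obs.sample_id] = series[pos]
        return out

    def residuals(self, params: np.ndarray) -> np.ndarray:
        """Stacked weighted residuals over all series."""
        preds = self.predict(params)
        parts = []
        for obs in self.observations:
            yhat = preds[obs.sample_id]
            if obs.variance_model == "data-based":
                sigma = obs.sds
            else:
                sigma = obs.model_based_fraction * np.abs(yhat)
                sigma = np.where(sigma > 0, sigma, np.inf)  # zero-prediction points drop out
            parts.append((obs.values - yhat) / sigma)
        # keep pathological corners of parameter space (predictions ~ 0 with
        # model-based weights) finite so trust-region steps can leave them
        return np.clip(np.nan_to_num(np.concatenate(parts), nan=1e12), -1e12, 1e12)

    def sswr(self, params: np.ndarray) -> float:
        r = self.residuals(params)
        return float(r @ r)

    # ------------------------------------------------------------------ #

    def fit(
        self,
        n_starts: int = 10,
        seed: int | None = None,
        start_values: np.ndarray | None = None,
        bounds: tuple[float, float] = (1e-8, 1e4),
        start_range: tuple[float, float] = (1e-2, 1e3),
        xtol: float = 1e-10,
        ftol: float = 1e-10,
    ) -> "BiokineticResults":
        """Multi-start bounded trust-region least squares.

        The optimiser works on log10-transformed rates (the shipped model
        spans 0.20-441 h^-1); start points are log-uniform in
        ``start_range`` from a seeded generator, plus ``start_values``
        when given.  Ties across starts break on lowest objective, then
        lowest parameter-vector norm.  Reported uncertainties come from a
        finite-difference Jacobian on the natural scale at the optimum
        (covariance = (J'J)^-1 x SSWR/dof).
        """
        lo, hi = bounds
        if lo <= 0:
            raise ValueError("lower bound must be > 0 (rates are log-transformed)")
        rng = np.random.default_rng(seed)
        starts = []
        if start_values is not None:
            starts.append(np.clip(np.asarray(start_values, dtype=float), lo, hi))
            n_starts = max(n_starts - 1, 0)
        s_lo, s_hi = np.log10(start_range[0]), np.log10(start_range[1])
        for _ in range(n_starts):
            starts.append(10 ** rng.uniform(s_lo, s_hi, size=self.n_params))

        def func(z):
            return self.residuals(10.0 ** z)

        best = None
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    func,
                    np.log10(x0),
                    bounds=(np.log10(lo), np.log10(hi)),
                    method="trf",
                    xtol=xtol,
                    ftol=ftol,
                    gtol=1e-12,
                )
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
            key = (res.cost, float(np.linalg.norm(10.0 ** res.x)))
            if best is None or key < best[0]:
                best = (key, res)
        if best is None:
            raise RuntimeError("all optimiser starts failed")
        res = best[1]
        params = 10.0 ** res.x
        converged = bool(res.success)
        at_bound = (params <= lo * (1 + 1e-6)) | (params >= hi * (1 - 1e-6))
        return self._results(params, converged, at_bound)

    # ------------------------------------------------------------------ #

    def _jacobian(self, params: np.ndarray) -> np.ndarray:
        """Finite-difference Jacobian of the weighted residuals w.r.t. the
        natural-scale parameters (predictions' sigma held at the optimum so
        the Gauss-Newton approximation matches the WLS contract)."""
        preds0 = self.predict(params)
        sigmas = []
        for obs in self.observations:
            if obs.variance_model == "data-based":
                sigmas.append(np.asarray(obs.sds, dtype=float))
            else:
                s = obs.model_based_fraction * np.abs(preds0[obs.sample_id])
                sigmas.append(np.where(s > 0, s, np.inf))
        sigma = np.concatenate(sigmas)

        def stacked(p):
            preds = self.predict(p)
            return np.concatenate([preds[o.sample_id] for o in self.observations])

        y0 = stacked(params)
        J = np.empty((len(y0), self.n_params))
        for j in range(self.n_params):
            h = max(1e-6 * abs(params[j]), 1e-10)
            p = params.copy()
            p[j] += h
            J[:, j] = -(stacked(p) - y0) / (h * sigma)
        return J

    def _results(self, params, converged, at_bound) -> "BiokineticResults":
        sswr = self.sswr(params)
        dof = self.nobs - self.n_params
        J = self._jacobian(params)
        JtJ = J.T @ J
        # numerically rank-deficient JtJ (relative threshold well above
        # finite-difference noise) marks structural unidentifiability
        sv, vh = np.linalg.svd(JtJ)[1:]
        rank = int(np.sum(sv > sv[0] * 1e-10))
        if rank < self.n_params:
            null_weights = np.abs(vh[rank:]).sum(axis=0)
            order = np.argsort(null_weights)[::-1][: self.n_params - rank + 1]
            culprits = [self.param_names[i] for i in order]
            raise np.linalg.LinAlgError(
                "structurally unidentifiable parameters (rank-deficient Jacobian); "
                f"null space involves: {culprits}"
            )
        cov = np.linalg.inv(JtJ) * (sswr / dof if sswr > 0 else 1.0)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sds, sds)
        np.fill_diagonal(corr, 1.0)
        p_value, rejected = goodness_of_fit(sswr, self.nobs, self.n_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aic, bic = information_criteria(sswr, self.nobs, self.n_params)
        return BiokineticResults(
            model=self,
            params=pd.Series(params, index=self.param_names),
            bse=pd.Series(sds, index=self.param_names),
            corr=pd.DataFrame(corr, index=self.param_names, columns=self.param_names),
            cov=pd.DataFrame(cov, index=self.param_names, columns=self.param_names),
            objective=sswr,
            sswr=sswr,
            p_value=p_value,
            rejected=rejected,
            aic=aic,
            bic=bic,
            converged=converged,
            at_bound=pd.Series(at_bound, index=self.param_names),
        )


@dataclass
class BiokineticResults:
    """Estimates and fit diagnostics of a :class:`BiokineticModel` fit."""

    model: BiokineticModel
    params: pd.Series  # h^-1
    bse: pd.Series  # one standard deviation, h^-1
    corr: pd.DataFrame
    cov: pd.DataFrame
    objective: float
    sswr: float
    p_value: float
    rejected: bool
    aic: float
    bic: float
    converged: bool
    at_bound: pd.Series

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def df_resid(self) -> int:
        return self.nobs - self.n_params

    @property
    def cv_percent(self) -> pd.Series:
        """Coefficient of variation, 100 x sd / |estimate|."""
        with np.errstate(divide="ignore"):
            return (100.0 * self.bse / self.params.abs()).rename("cv_percent")

    def fitted_system(self) -> CompartmentalSystem:
        return self.model._system_with(self.params.to_numpy())

    def summary(self) -> str:
        lines = [
            "Compartmental biokinetic model — weighted least squares",
            "=" * 64,
            f"N data points        {self.nobs}",
            f"M free parameters    {self.n_params}",
            f"degrees of freedom   {self.df_resid}",
            f"SSWR (objective)     {self.sswr:.4g}",
            f"chi2 p-value         {self.p_value:.3f}"
            + ("   (fit rejected, p < 0.05)" if self.rejected else ""),
            f"AIC / BIC            {self.aic:.2f} / {self.bic:.2f}",
            f"converged            {self.converged}",
            "-" * 64,
            f"{'parameter':<32}{'estimate':>10}{'sd':>10}{'cv %':>8}",
        ]
        for name in self.params.index:
            flag = "  (at bound)" if self.at_bound[name] else ""
            lines.append(
                f"{name:<32}{self.params[name]:>10.4g}{self.bse[name]:>10.3g}"
                f"{self.cv_percent[name]:>8.1f}{flag}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates_per_h": self.params.to_dict(),
            "sds_per_h": self.bse.to_dict(),
            "cv_percent": self.cv_percent.to_dict(),
            "sswr": self.sswr,
            "n_data": self.nobs,
            "n_params": self.n_params,
            "dof": self.df_resid,
            "p_value": self.p_value,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }
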