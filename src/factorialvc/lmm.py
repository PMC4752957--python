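"""Gaussian linear mixed models with crossed random intercepts.

The standard factorial model carries random intercepts for dam, sire
and the dam-by-sire family; extra random intercepts (position, block)
and arbitrary fixed terms may be added through the :class:`ModelSpec`.
Estimation is by REML (default) or ML on the profiled deviance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._mixed import DesignMatrices, GaussianProfile, build_design
from .design_data import ObservationTable
from .errors import ConfigurationError, DesignError
from .modelspec import ModelSpec

__all__ = ["FittedVCModel", "fit_lmm", "information_criteria"]


@dataclass
class FittedVCModel:
    """A fitted variance-component model (Gaussian or latent-scale)."""

    variance_estimates: dict[str, float]
    fixed_estimates: dict[str, float]
    log_likelihood: float
    n_parameters: int
    n_obs: int
    method: str
    converged: bool
    spec: ModelSpec
    intercept_only_beta0: float | None = None
    boundary: bool = False
    fixed_design: np.ndarray = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.fixed_estimates.values()))

    @property
    def random_terms(self) -> tuple[str, ...]:
        return tuple(
            t for t in self.variance_estimates if t not in ("residual", "olre")
        )

    def fixed_group_values(self) -> np.ndarray:
        """Linear-predictor contributions X @ beta on the original rows."""
        return self.fixed_design @ self.beta

    def summary(self) -> dict[str, Any]:
        """JSON-serializable fit summary."""
        crit = information_criteria(self)
        return {
            "family": self.spec.family,
            "link": self.spec.link,
            "method": self.method,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
            "variance_estimates": {
                k: float(v) for k, v in self.variance_estimates.items()
            },
            "fixed_estimates": {
                k: float(v) for k, v in self.fixed_estimates.items()
            },
            "logLik": crit["logLik"],
            "AIC": crit["AIC"],
            "BIC": crit["BIC"],
            "n_parameters": self.n_parameters,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


def _check_identifiability(dm: DesignMatrices, table: ObservationTable) -> None:
    df = table.data
    if "dam" in dm.term_names and df[table.dam].nunique() < 2:
        raise DesignError("need at least 2 dams to fit the model")
    if "sire" in dm.term_names and df[table.sire].nunique() < 2:
        raise DesignError("need at least 2 sires to fit the model")
    if dm.n_obs_original <= dm.X.shape[1]:
        raise DesignError(
            f"model not identifiable: {dm.n_obs_original} observations for "
            f"{dm.X.shape[1]} fixed-effect parameters"
        )


def fit_lmm(
    table: ObservationTable,
    spec: ModelSpec,
    random_terms: tuple[str, ...] | None = None,
    theta0: np.ndarray | None = None,
    fast: bool = False,
) -> FittedVCModel:
    """Fit a Gaussian mixed model by (RE)ML.

    ``random_terms`` overrides the random structure for expert use
    (e.g. a one-way layout); by default the spec's dam/sire/dam-by-sire
    structure plus declared extras is used.  ``theta0`` warm-starts the
    optimizer (relative standard deviations, one per random term).
    """
    if not spec.is_gaussian:
        raise ConfigurationError(
            f"fit_lmm requires a gaussian spec, got family {spec.family!r}; "
            "use fit_glmm for nonnormal data"
        )
    dm = build_design(table, spec, random_terms=random_terms)
    _check_identifiability(dm, table)
    res = GaussianProfile(dm, method=spec.method).fit(theta0=theta0, fast=fast)
    variances = dict(res.sigma2)
    variances["residual"] = res.sigma2_resid
    return FittedVCModel(
        variance_estimates=variances,
        fixed_estimates=dict(zip(dm.fixed_names, res.beta)),
        log_likelihood=res.loglik,
        n_parameters=dm.p + len(dm.term_names) + 1,
        n_obs=dm.n_obs_original,
        method=res.method,
        converged=res.converged,
        spec=spec,
        boundary=res.boundary,
        fixed_design=dm.X_original,
    )


def information_criteria(model: FittedVCModel) -> dict[str, float]:
    """AIC/BIC/logLik with k = fixed coefficients + variance parameters."""
    ll = model.log_likelihood
    k = model.n_parameters
    n = model.n_obs
    return {
        "logLik": float(ll),
        "AIC": float(-2.0 * ll + 2.0 * k),
        "BIC": float(-2.0 * ll + k * np.log(n)),
    }
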