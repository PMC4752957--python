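"""Binomial and Poisson mixed models via the Laplace approximation.

Estimation is always ML: the inner PIRLS loop locates the joint
conditional modes of the random and fixed effects, the outer optimizer
moves the variance parameters on the Laplace-approximated deviance.
Overdispersion of proportion/count data is modeled — and tested — with
an observation-level random effect (OLRE); binary data carry none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._mixed import LaplaceProfile, build_design
from .design_data import ObservationTable
from .errors import ConfigurationError, UsageError
from .families import get_family, get_link
from .lmm import FittedVCModel, _check_identifiability
from .modelspec import ModelSpec

__all__ = ["LatentScaleModel", "OverdispersionTest", "fit_glmm", "overdispersion_test"]


@dataclass
class LatentScaleModel(FittedVCModel):
    """Nonnormal fit whose variance components live on the link scale."""

    olre_variance: float | None = None

    def summary(self):
        out = super().summary()
        if self.olre_variance is not None:
            out["olre_variance"] = float(self.olre_variance)
        return out


def _is_binary_spec(table: ObservationTable, spec: ModelSpec) -> bool:
    return spec.is_binomial and spec.failures is None


def fit_glmm(
    table: ObservationTable,
    spec: ModelSpec,
    random_terms: tuple[str, ...] | None = None,
    compute_beta0: bool = True,
    theta0: np.ndarray | None = None,
    fast: bool = False,
) -> LatentScaleModel:
    """Fit a binomial or Poisson mixed model by Laplace-approximated ML.

    For Poisson models with the log link, a second fit containing only
    the random effects is run and its intercept stored as
    ``intercept_only_beta0``; the latent-scale residual constant
    ln(1/exp(beta0) + 1) depends on it.
    """
    if spec.is_gaussian:
        raise ConfigurationError(
            "fit_glmm requires a binomial or poisson spec; use fit_lmm "
            "for gaussian data"
        )
    if spec.has_olre and _is_binary_spec(table, spec):
        raise UsageError(
            "quasi- families are not defined for binary responses: there is "
            "no overdispersion with binary data"
        )
    dm = build_design(table, spec, random_terms=random_terms)
    _check_identifiability(dm, table)
    res = LaplaceProfile(
        dm, get_family(spec.family), get_link(spec.link)
    ).fit(theta0=theta0, fast=fast)

    beta0 = None
    if spec.is_poisson and spec.link == "log" and compute_beta0:
        if spec.fixed:
            dm0 = build_design(table, spec, random_terms=random_terms,
                               fixed_terms=())
            res0 = LaplaceProfile(
                dm0, get_family(spec.family), get_link(spec.link)
            ).fit()
            beta0 = float(res0.beta[0])
        else:
            beta0 = float(res.beta[0])

    variances = dict(res.sigma2)
    n_params = dm.p + len(dm.term_names) + (1 if dm.olre else 0)
    return LatentScaleModel(
        variance_estimates=variances,
        fixed_estimates=dict(zip(dm.fixed_names, res.beta)),
        log_likelihood=res.loglik - dm.loglik_offset,
        n_parameters=n_params,
        n_obs=dm.n_obs_original,
        method="ML",
        converged=res.converged,
        spec=spec,
        intercept_only_beta0=beta0,
        boundary=res.boundary,
        fixed_design=dm.X_original,
        olre_variance=res.olre_variance,
    )


@dataclass
class OverdispersionTest:
    """LRT of the observation-level random effect (df = 1, ML)."""

    olre_variance: float
    chi_sq: float
    p_value: float


def overdispersion_test(
    table: ObservationTable, spec: ModelSpec
) -> OverdispersionTest:
    """Compare the model with vs without an OLRE by likelihood ratio.

    Defined for proportion (success/failure counts) and count
    responses only; binary data cannot be overdispersed.
    """
    if spec.is_gaussian:
        raise UsageError("overdispersion is not defined for gaussian models")
    if _is_binary_spec(table, spec):
        raise UsageError(
            "overdispersion test requires proportion or count data: there is "
            "no overdispersion with binary data"
        )

    def one_fit(olre: bool):
        dm = build_design(table, spec, olre=olre)
        res = LaplaceProfile(
            dm, get_family(spec.family), get_link(spec.link)
        ).fit()
        return res.loglik - dm.loglik_offset, res

    ll_with, res_with = one_fit(True)
    ll_without, _ = one_fit(False)
    chi_sq = max(0.0, 2.0 * (ll_with - ll_without))
    return OverdispersionTest(
        olre_variance=float(res_with.olre_variance or 0.0),
        chi_sq=float(chi_sq),
        p_value=float(stats.chi2.sf(chi_sq, df=1)) if chi_sq > 0 else 1.0,
    )
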