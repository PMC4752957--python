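"""Significance tests: LRTs for random effects, parametric bootstrap for fixed.

Random effects use the likelihood ratio test against the model without
the single term, always with 1 degree of freedom on the naive chi-square
reference — conservative at the variance boundary, and reported as such.
Fixed effects use a parametric bootstrap of the ML likelihood-ratio
statistic under the term-deleted null, with the analytic ML LRT p-value
reported alongside as an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .design_data import ObservationTable
from .errors import ConfigurationError, FactorialVCError, TestError
from .families import get_link
from .glmm import fit_glmm
from .lmm import FittedVCModel, fit_lmm, information_criteria
from .modelspec import ModelSpec

__all__ = [
    "RandomEffectTest",
    "FixedEffectTest",
    "lrt_random",
    "random_effect_tests",
    "pb_fixed",
    "simulate_from_model",
]

logger = logging.getLogger(__name__)


@dataclass
class RandomEffectTest:
    term: str
    chi_sq: float
    delta_AIC: float
    delta_BIC: float
    p_value: float
    df: int = 1
    scale: str = "ML"


@dataclass
class FixedEffectTest:
    term: str
    chi_sq_observed: float
    p_parametric_bootstrap: float
    n_sim: int
    p_LRT: float
    delta_AIC: float
    delta_BIC: float
    df: int = 1
    n_failed: int = 0


def _fit(table: ObservationTable, spec: ModelSpec,
         random_terms: tuple[str, ...] | None = None,
         theta0=None, fast: bool = False) -> FittedVCModel:
    if spec.is_gaussian:
        return fit_lmm(table, spec, random_terms=random_terms, theta0=theta0,
                       fast=fast)
    return fit_glmm(table, spec, random_terms=random_terms,
                    compute_beta0=False, theta0=theta0, fast=fast)


def _warm_theta(model: FittedVCModel) -> np.ndarray | None:
    """Relative-scale theta at a fitted optimum, for warm-started refits."""
    spec = model.spec
    values = [max(model.variance_estimates.get(t, 0.0), 0.0)
              for t in spec.random_terms]
    if spec.is_gaussian:
        resid = model.variance_estimates.get("residual", 0.0)
        if resid <= 0:
            return None
        return np.sqrt(np.array(values) / resid)
    olre = getattr(model, "olre_variance", None)
    if olre is not None:
        values.append(max(olre, 0.0))
    return np.sqrt(np.array(values))


def random_effect_tests(
    table: ObservationTable,
    spec: ModelSpec,
    terms: tuple[str, ...] | None = None,
    scale: str | None = None,
    full_model: FittedVCModel | None = None,
    fast: bool = False,
) -> list[RandomEffectTest]:
    """LRT of each random term against the term-deleted reduced model.

    ``scale`` selects REML or ML likelihoods for Gaussian models
    (default: the spec's estimation method); nonnormal models are ML.
    The full model is fitted once and reused across terms.
    """
    if scale is None:
        scale = spec.method if spec.is_gaussian else "ML"
    if spec.is_gaussian and scale != spec.method:
        spec = dc_replace(spec, method=scale)
        full_model = None
    if terms is None:
        terms = spec.random_terms
    unknown = [t for t in terms if t not in spec.random_terms]
    if unknown:
        raise ConfigurationError(f"not random terms of this model: {unknown}")

    if full_model is None:
        full_model = _fit(table, spec, fast=fast)
    full_crit = information_criteria(full_model)
    warm = _warm_theta(full_model)
    out = []
    for term in terms:
        reduced_terms = tuple(t for t in spec.random_terms if t != term)
        theta0 = None
        if warm is not None:
            keep = [i for i, t in enumerate(spec.random_terms) if t != term]
            theta0 = np.concatenate(
                [warm[keep], warm[len(spec.random_terms):]]
            )
        try:
            reduced = _fit(table, spec, random_terms=reduced_terms,
                           theta0=theta0, fast=fast)
        except FactorialVCError as exc:
            raise TestError(
                f"reduced model without {term!r} failed: {exc}",
                states={"full": full_model},
            ) from exc
        red_crit = information_criteria(reduced)
        chi_sq = max(0.0, 2.0 * (full_model.log_likelihood - reduced.log_likelihood))
        out.append(
            RandomEffectTest(
                term=term,
                chi_sq=float(chi_sq),
                delta_AIC=float(red_crit["AIC"] - full_crit["AIC"]),
                delta_BIC=float(red_crit["BIC"] - full_crit["BIC"]),
                p_value=float(stats.chi2.sf(chi_sq, df=1)) if chi_sq > 0 else 1.0,
                df=1,
                scale=scale,
            )
        )
    return out


def lrt_random(
    table: ObservationTable,
    spec: ModelSpec,
    term: str,
    scale: str | None = None,
) -> RandomEffectTest:
    """LRT for a single random term; see :func:`random_effect_tests`."""
    return random_effect_tests(table, spec, terms=(term,), scale=scale)[0]


def pb_pvalue(chi_sim, chi_obs: float) -> float:
    """(1 + k) / (1 + n) plug-in p from simulated null statistics."""
    chi_sim = np.asarray(chi_sim, dtype=float)
    return (1.0 + float(np.sum(chi_sim >= chi_obs))) / (len(chi_sim) + 1.0)


# ---------------------------------------------------------------------------
# simulation from a fitted model (shared with the power module)
# ---------------------------------------------------------------------------

def simulate_from_model(
    table: ObservationTable,
    spec: ModelSpec,
    model: FittedVCModel,
    rng: np.random.Generator,
) -> ObservationTable:
    """Draw a new response vector from the fitted model onto ``table``.

    Random effects are redrawn per level from their estimated variances;
    the fixed part is X @ beta on the original rows.
    """
    df = table.data
    n = len(df)
    eta = model.fixed_design @ model.beta
    from ._mixed import _term_column  # local import to avoid cycle

    for term in model.random_terms:
        var = model.variance_estimates.get(term, 0.0)
        col = _term_column(table, term)
        codes, levels = pd.factorize(df[col].astype(str), sort=True)
        effects = rng.normal(0.0, np.sqrt(max(var, 0.0)), size=len(levels))
        eta = eta + effects[codes]
    olre = getattr(model, "olre_variance", None)
    if olre:
        eta = eta + rng.normal(0.0, np.sqrt(olre), size=n)

    new = df.copy()
    if spec.is_gaussian:
        resid = model.variance_estimates.get("residual", 0.0)
        new[spec.response] = eta + rng.normal(0.0, np.sqrt(max(resid, 0.0)), n)
    else:
        mu = get_link(spec.link).inverse(eta)
        if spec.is_binomial:
            mu = np.clip(mu, 0.0, 1.0)
            if spec.failures is not None:
                m = (
                    df[spec.response].to_numpy(float)
                    + df[spec.failures].to_numpy(float)
                ).astype(np.int64)
                succ = rng.binomial(m, mu)
                new[spec.response] = succ
                new[spec.failures] = m - succ
            else:
                new[spec.response] = rng.binomial(1, mu)
        else:
            new[spec.response] = rng.poisson(np.maximum(mu, 0.0))
    return table.with_data(new)


def pb_fixed(
    table: ObservationTable,
    spec: ModelSpec,
    term: str,
    n_sim: int = 999,
    seed: int | None = None,
) -> FixedEffectTest:
    """Parametric-bootstrap test of one fixed term.

    Simulates ``n_sim`` responses from the ML-fitted null (term-deleted)
    model, refits both models per simulation, and reports
    p = (1 + #{chi2_sim >= chi2_obs}) / (n_sim + 1).  The analytic ML
    LRT p-value is reported alongside.
    """
    if term not in spec.fixed:
        raise ConfigurationError(f"{term!r} is not a fixed term of this model")
    if n_sim < 99:
        raise ConfigurationError("n_sim must be at least 99")
    ml_spec = dc_replace(spec, method="ML") if spec.is_gaussian else spec
    null_spec = ml_spec.without_fixed(term)
    full = _fit(table, ml_spec)
    null = _fit(table, null_spec)
    chi_obs = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    df_term = len(full.fixed_estimates) - len(null.fixed_estimates)
    full_crit = information_criteria(full)
    null_crit = information_criteria(null)

    streams = np.random.SeedSequence(seed).spawn(n_sim)
    warm = _warm_theta(null)
    chi_sim = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        sim_table = simulate_from_model(table, null_spec, null, rng)
        try:
            f = _fit(sim_table, ml_spec, theta0=warm, fast=True)
            r = _fit(sim_table, null_spec, theta0=warm, fast=True)
        except FactorialVCError as exc:
            n_failed += 1
            logger.debug("parametric-bootstrap refit failed: %s", exc)
            continue
        chi_sim.append(max(0.0, 2.0 * (f.log_likelihood - r.log_likelihood)))
    if n_failed > 0.1 * n_sim:
        raise TestError(
            f"{n_failed}/{n_sim} parametric-bootstrap refits failed",
            states={"chi_sim": chi_sim},
        )
    chi_sim = np.asarray(chi_sim)
    n_used = len(chi_sim)
    p_pb = pb_pvalue(chi_sim, chi_obs)
    return FixedEffectTest(
        term=term,
        chi_sq_observed=float(chi_obs),
        p_parametric_bootstrap=float(p_pb),
        n_sim=n_used,
        p_LRT=float(stats.chi2.sf(chi_obs, df=max(df_term, 1))),
        delta_AIC=float(null_crit["AIC"] - full_crit["AIC"]),
        delta_BIC=float(null_crit["BIC"] - full_crit["BIC"]),
        df=int(df_term),
        n_failed=n_failed,
    )


def tests_to_frame(tests) -> pd.DataFrame:
    """Serialize a list of test results to a tidy table."""
    return pd.DataFrame([t.__dict__ for t in tests])
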