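"""Simulation of factorial designs and per-component power analysis.

This module is also the repository's fixture generator: it draws
balanced n_dam x n_sire designs with known dam/sire/interaction
variances on the latent scale under Gaussian, binomial or Poisson error
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_data import ObservationTable
from .errors import ConfigurationError, FactorialVCError
from .families import check_family_link, get_link
from .modelspec import ModelSpec
from .significance import pb_fixed, random_effect_tests

__all__ = ["FactorialDesignSpec", "PowerResult", "simulate_factorial", "power_analysis"]


@dataclass(frozen=True)
class FactorialDesignSpec:
    """Balanced factorial design with known latent variance components.

    ``components`` maps ``dam``, ``sire``, ``dam_sire`` (and, for
    Gaussian, ``residual``) to variances; extra random terms are given
    as ``extra_components`` with a level count each, assigned cyclically
    across rows.  ``fixed_effects`` maps covariate names to slopes;
    covariates are drawn i.i.d. standard normal per offspring.
    """

    n_dam: int
    n_sire: int
    n_offspring_per_family: int
    components: dict[str, float] = field(default_factory=dict)
    family: str = "gaussian"
    link: str | None = None
    intercept: float = 0.0
    fixed_effects: dict[str, float] = field(default_factory=dict)
    extra_components: dict[str, tuple[float, int]] = field(default_factory=dict)
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "link", check_family_link(self.family, self.link)
        )
        if self.n_dam < 2 or self.n_sire < 2:
            raise ConfigurationError("need at least 2 dams and 2 sires")
        if self.n_offspring_per_family < 1:
            raise ConfigurationError("need at least 1 offspring per family")
        for key, value in self.components.items():
            if key not in ("dam", "sire", "dam_sire", "residual"):
                raise ConfigurationError(f"unknown component {key!r}")
            if value < 0:
                raise ConfigurationError(f"component {key!r} must be >= 0")
        if self.family == "gaussian" and "residual" not in self.components:
            raise ConfigurationError("gaussian designs require a residual variance")
        if self.family != "gaussian" and "residual" in self.components:
            raise ConfigurationError(
                "nonnormal designs have no residual variance input; the "
                "latent residual is fixed by the family/link"
            )
        if self.n_replicates < 1 or (
            self.n_offspring_per_family % self.n_replicates != 0
        ):
            raise ConfigurationError(
                "n_offspring_per_family must divide evenly across replicates"
            )

    @property
    def n_obs(self) -> int:
        return self.n_dam * self.n_sire * self.n_offspring_per_family

    def model_spec(self, method: str = "REML") -> ModelSpec:
        return ModelSpec(
            response="response",
            family=self.family,
            link=self.link,
            method=method if self.family == "gaussian" else "ML",
            extra_random=tuple(self.extra_components),
            fixed=tuple(self.fixed_effects),
        )


def simulate_factorial(
    design: FactorialDesignSpec, seed: int | None = None
) -> ObservationTable:
    """Draw one balanced factorial dataset under the design's components.

    Dam, sire and interaction effects are independent zero-mean normals
    on the latent scale; nonnormal responses are sampled through the
    inverse link.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    nd, ns, k = design.n_dam, design.n_sire, design.n_offspring_per_family
    comp = design.components

    dam_eff = rng.normal(0.0, np.sqrt(comp.get("dam", 0.0)), nd)
    sire_eff = rng.normal(0.0, np.sqrt(comp.get("sire", 0.0)), ns)
    fam_eff = rng.normal(0.0, np.sqrt(comp.get("dam_sire", 0.0)), nd * ns)

    dam_idx = np.repeat(np.arange(nd), ns * k)
    sire_idx = np.tile(np.repeat(np.arange(ns), k), nd)
    fam_idx = dam_idx * ns + sire_idx
    n = nd * ns * k

    eta = (
        design.intercept
        + dam_eff[dam_idx]
        + sire_eff[sire_idx]
        + fam_eff[fam_idx]
    )
    width = max(2, len(str(max(nd, ns))))
    df = pd.DataFrame(
        {
            "dam": np.char.add("D", np.char.zfill(dam_idx.astype(str), width)),
            "sire": np.char.add("S", np.char.zfill(sire_idx.astype(str), width)),
        }
    )
    if design.n_replicates > 1:
        per_rep = k // design.n_replicates
        rep = np.tile(np.repeat(np.arange(design.n_replicates), per_rep), nd * ns)
        df["replicate"] = np.char.add("R", rep.astype(str))

    for name, (var, levels) in design.extra_components.items():
        codes = np.arange(n) % levels
        effects = rng.normal(0.0, np.sqrt(var), levels)
        eta = eta + effects[codes]
        df[name] = np.char.add(f"{name}_", codes.astype(str))

    for name, slope in design.fixed_effects.items():
        x = rng.normal(0.0, 1.0, n)
        df[name] = x
        eta = eta + slope * x

    if design.family == "gaussian":
        response = eta + rng.normal(0.0, np.sqrt(comp["residual"]), n)
    else:
        mu = get_link(design.link).inverse(eta)
        if design.family in ("binomial", "quasibinomial"):
            response = rng.binomial(1, np.clip(mu, 0.0, 1.0))
        else:
            response = rng.poisson(np.maximum(mu, 0.0))
    df["response"] = response
    return ObservationTable(
        df,
        dam="dam",
        sire="sire",
        replicate="replicate" if design.n_replicates > 1 else None,
    )


@dataclass
class PowerResult:
    """Per-term power estimates."""

    power: dict[str, float]
    n_significant: dict[str, int]
    n_sim: int
    alpha: float
    method_notes: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.power),
                "power": [self.power[t] for t in self.power],
                "n_significant": [self.n_significant[t] for t in self.power],
                "n_sim": self.n_sim,
                "alpha": self.alpha,
            }
        )


def power_analysis(
    design: FactorialDesignSpec,
    n_sim: int,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    seed: int | None = None,
    include_fixed: bool = False,
    n_sim_pb: int = 99,
) -> PowerResult:
    """Estimate power per variance component by repeated simulation.

    Each simulation draws a dataset from ``design``, fits the model, and
    records each random term's LRT p-value (and, when requested, each
    fixed term's parametric-bootstrap p-value).  Power is the fraction
    of p-values below ``alpha``.
    """
    import warnings

    if n_sim < 50:
        raise ConfigurationError("n_sim must be at least 50")
    if n_sim < 500:
        warnings.warn(
            f"n_sim={n_sim} is below the recommended 500 simulations",
            stacklevel=2,
        )
    if spec is None:
        spec = design.model_spec()
    streams = np.random.SeedSequence(seed).spawn(n_sim)
    terms = spec.random_terms
    hits = {t: 0 for t in terms}
    if include_fixed:
        for t in spec.fixed:
            hits[t] = 0
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        sim_seed = int(rng.integers(2**63))
        table = simulate_factorial(design, seed=sim_seed)
        try:
            tests = random_effect_tests(table, spec, fast=True)
        except FactorialVCError:
            n_failed += 1
            continue
        for test in tests:
            if test.p_value < alpha:
                hits[test.term] += 1
        if include_fixed:
            for term in spec.fixed:
                res = pb_fixed(table, spec, term, n_sim=n_sim_pb,
                               seed=int(rng.integers(2**63)))
                if res.p_parametric_bootstrap < alpha:
                    hits[term] += 1
    if n_failed > 0.1 * n_sim:
        raise FactorialVCError(
            f"{n_failed}/{n_sim} simulated fits failed; power estimates "
            "would be unreliable"
        )
    n_used = n_sim - n_failed
    notes = {t: f"LRT ({spec.method})" for t in terms}
    if include_fixed:
        notes.update({t: "parametric bootstrap" for t in spec.fixed})
    return PowerResult(
        power={t: hits[t] / n_used for t in hits},
        n_significant=dict(hits),
        n_sim=n_used,
        alpha=alpha,
        method_notes=notes,
    )
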