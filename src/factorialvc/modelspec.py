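"""Model specification shared by the Gaussian and nonnormal engines."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .families import (
    BINOMIAL_FAMILIES,
    GAUSSIAN_FAMILIES,
    POISSON_FAMILIES,
    check_family_link,
)

#: random terms present in every factorial model, in canonical order
BASE_RANDOM_TERMS = ("dam", "sire", "dam_sire")

#: internal name of the observation-level random effect
OLRE_TERM = "olre"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, error structure and extra model terms.

    Parameters
    ----------
    response
        Response column name.  For proportion data supplied as
        success/failure count pairs, ``response`` is the success-count
        column and ``failures`` the failure-count column.
    family
        One of ``gaussian``, ``binomial``, ``quasibinomial``,
        ``poisson``, ``quasipoisson``.  The quasi- variants add an
        observation-level random effect to absorb (and test for)
        overdispersion; they are not valid for binary responses.
    link
        Defaults to the family's canonical link (identity / logit / log).
    method
        ``REML`` or ``ML``; Gaussian only.  Nonnormal families always
        use ML via the Laplace approximation.
    extra_random
        Additional categorical random-intercept columns (e.g. tray, cell).
    fixed
        Fixed-effect terms: column names, or ``a:b`` interactions.
        Numeric columns enter as covariates, others as dummy-coded
        factors.  An intercept is always included.
    alpha
        Significance level used by downstream tests.
    """

    response: str
    family: str = "gaussian"
    link: str | None = None
    method: str = "REML"
    extra_random: tuple[str, ...] = ()
    fixed: tuple[str, ...] = ()
    alpha: float = 0.05
    failures: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "extra_random", tuple(self.extra_random))
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "link", check_family_link(self.family, self.link))
        if self.method not in ("REML", "ML"):
            raise ConfigurationError(f"method must be REML or ML, got {self.method!r}")
        if not self.is_gaussian and self.method == "REML":
            # nonnormal models are always ML; normalize silently
            object.__setattr__(self, "method", "ML")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.failures is not None and self.family not in BINOMIAL_FAMILIES:
            raise ConfigurationError(
                "a failures column is only meaningful for binomial families"
            )

    # -- convenience -----------------------------------------------------
    @property
    def is_gaussian(self) -> bool:
        return self.family in GAUSSIAN_FAMILIES

    @property
    def is_binomial(self) -> bool:
        return self.family in BINOMIAL_FAMILIES

    @property
    def is_poisson(self) -> bool:
        return self.family in POISSON_FAMILIES

    @property
    def has_olre(self) -> bool:
        """Quasi- families carry an observation-level random effect."""
        return self.family in ("quasibinomial", "quasipoisson")

    @property
    def random_terms(self) -> tuple[str, ...]:
        return BASE_RANDOM_TERMS + self.extra_random

    def without_fixed(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ConfigurationError(f"{term!r} is not a fixed term of this model")
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))
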