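"""GLM family and link primitives used by the mixed-model engines.

Only the family/link pairs supported by the factorial workflow are
implemented: gaussian/identity, binomial/{logit, probit} and
poisson/{log, sqrt}.  The quasi- variants reuse the binomial/poisson
likelihoods; overdispersion is absorbed by an observation-level random
effect rather than a dispersion parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .errors import ConfigurationError

_EPS = 1e-10

GAUSSIAN_FAMILIES = frozenset({"gaussian"})
BINOMIAL_FAMILIES = frozenset({"binomial", "quasibinomial"})
POISSON_FAMILIES = frozenset({"poisson", "quasipoisson"})

#: links admissible for each error family
VALID_LINKS = {
    "gaussian": ("identity",),
    "binomial": ("logit", "probit"),
    "quasibinomial": ("logit", "probit"),
    "poisson": ("log", "sqrt"),
    "quasipoisson": ("log", "sqrt"),
}

DEFAULT_LINKS = {
    "gaussian": "identity",
    "binomial": "logit",
    "quasibinomial": "logit",
    "poisson": "log",
    "quasipoisson": "log",
}


def check_family_link(family: str, link: str | None) -> str:
    """Validate the family/link pair and return the (defaulted) link."""
    if family not in VALID_LINKS:
        raise ConfigurationError(f"unsupported error family {family!r}")
    if link is None:
        return DEFAULT_LINKS[family]
    if link not in VALID_LINKS[family]:
        raise ConfigurationError(
            f"link {link!r} is not valid for family {family!r}; "
            f"choose one of {VALID_LINKS[family]}"
        )
    return link


class Link:
    """Monotone link g with inverse and derivative dmu/deta."""

    name: str

    def __call__(self, mu):  # g(mu) = eta
        raise NotImplementedError

    def inverse(self, eta):  # mu = g^{-1}(eta)
        raise NotImplementedError

    def dmu_deta(self, eta):
        raise NotImplementedError


class IdentityLink(Link):
    name = "identity"

    def __call__(self, mu):
        return np.asarray(mu, dtype=float)

    def inverse(self, eta):
        return np.asarray(eta, dtype=float)

    def dmu_deta(self, eta):
        return np.ones_like(np.asarray(eta, dtype=float))


class LogitLink(Link):
    name = "logit"

    def __call__(self, mu):
        mu = np.clip(mu, _EPS, 1 - _EPS)
        return np.log(mu / (1 - mu))

    def inverse(self, eta):
        return special.expit(np.asarray(eta, dtype=float))

    def dmu_deta(self, eta):
        mu = self.inverse(eta)
        return mu * (1 - mu)


class ProbitLink(Link):
    name = "probit"

    def __call__(self, mu):
        return stats.norm.ppf(np.clip(mu, _EPS, 1 - _EPS))

    def inverse(self, eta):
        return stats.norm.cdf(eta)

    def dmu_deta(self, eta):
        return stats.norm.pdf(eta)


class LogLink(Link):
    name = "log"

    _ETA_MAX = 50.0  # exp stays finite; rates beyond this are saturated

    def __call__(self, mu):
        return np.log(np.maximum(mu, _EPS))

    def inverse(self, eta):
        return np.exp(np.minimum(np.asarray(eta, dtype=float), self._ETA_MAX))

    def dmu_deta(self, eta):
        return np.exp(np.minimum(np.asarray(eta, dtype=float), self._ETA_MAX))


class SqrtLink(Link):
    name = "sqrt"

    def __call__(self, mu):
        return np.sqrt(np.maximum(mu, 0.0))

    def inverse(self, eta):
        eta = np.asarray(eta, dtype=float)
        return eta**2

    def dmu_deta(self, eta):
        return 2.0 * np.asarray(eta, dtype=float)


_LINKS = {
    "identity": IdentityLink(),
    "logit": LogitLink(),
    "probit": ProbitLink(),
    "log": LogLink(),
    "sqrt": SqrtLink(),
}


def get_link(name: str) -> Link:
    try:
        return _LINKS[name]
    except KeyError:
        raise ConfigurationError(f"unknown link {name!r}") from None


class Family:
    """Exponential-family pieces needed by PIRLS and the Laplace likelihood.

    ``y`` is the mean response per row (a proportion for binomial) and
    ``m`` the prior weight (number of Bernoulli trials; 1 otherwise).
    """

    name: str

    def variance(self, mu):
        raise NotImplementedError

    def deviance_resid(self, y, mu, m):
        """Per-row deviance residual contribution (non-negative)."""
        raise NotImplementedError

    def loglik(self, y, mu, m):
        """Exact conditional log-likelihood, including constants."""
        raise NotImplementedError

    def clip_mu(self, mu):
        return mu


class BinomialFamily(Family):
    name = "binomial"

    def variance(self, mu):
        return mu * (1 - mu)

    def clip_mu(self, mu):
        return np.clip(mu, _EPS, 1 - _EPS)

    def deviance_resid(self, y, mu, m):
        mu = self.clip_mu(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return 2.0 * m * (t1 + t2)

    def loglik(self, y, mu, m):
        mu = self.clip_mu(mu)
        k = np.round(y * m)
        return float(np.sum(stats.binom.logpmf(k, np.round(m), mu)))


class PoissonFamily(Family):
    name = "poisson"

    def variance(self, mu):
        return mu

    def clip_mu(self, mu):
        return np.maximum(mu, _EPS)

    def deviance_resid(self, y, mu, m):
        mu = self.clip_mu(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * m * (t - (y - mu))

    def loglik(self, y, mu, m):
        mu = self.clip_mu(mu)
        return float(np.sum(m * stats.poisson.logpmf(np.round(y), mu)))


_FAMILIES = {
    "binomial": BinomialFamily(),
    "quasibinomial": BinomialFamily(),
    "poisson": PoissonFamily(),
    "quasipoisson": PoissonFamily(),
}


def get_family(name: str) -> Family:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ConfigurationError(f"unsupported nonnormal family {name!r}") from None
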