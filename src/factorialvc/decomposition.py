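"""Raw/percent variance components and the genetic decomposition.

Given a fitted model, the phenotypic variance is split into dam, sire,
dam-by-sire, extra random, fixed-group and residual components; the
derived quantities are

* additive genetic variance      V_A = 4 * V_sire
* nonadditive genetic variance   V_N = 4 * V_dam_sire
* maternal variance              V_M = V_dam - V_sire

V_M may be negative and is reported as-is.  Percentages use one shared
total (the sum of all modeled components); the derived percentages can
therefore sum above 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .lmm import FittedVCModel

__all__ = [
    "VarianceDecomposition",
    "residual_variance",
    "fixed_group_variance",
    "decompose",
]

#: derived-component column order used across resampling matrices
DERIVED_COMPONENTS = ("additive", "nonadditive", "maternal")


def residual_variance(model: FittedVCModel) -> float:
    """Residual variance on the (latent) scale of the linear predictor.

    Gaussian models return their estimated residual variance.  For the
    nonnormal families the latent-scale constants are: binomial/logit
    pi^2/3, binomial/probit 1, poisson/sqrt 0.25, and poisson/log
    ln(1/exp(beta0) + 1) with beta0 the intercept of the
    random-effects-only refit.
    """
    spec = model.spec
    return latent_residual_variance(
        spec.family, spec.link,
        beta0=model.intercept_only_beta0,
        gaussian_residual=model.variance_estimates.get("residual"),
    )


def latent_residual_variance(
    family: str,
    link: str,
    beta0: float | None = None,
    gaussian_residual: float | None = None,
) -> float:
    """Family/link residual rule, usable without a fitted model."""
    if family == "gaussian" and link == "identity":
        if gaussian_residual is None:
            raise ConfigurationError(
                "gaussian residual variance requires a fitted model"
            )
        return float(gaussian_residual)
    if family in ("binomial", "quasibinomial"):
        if link == "logit":
            return math.pi**2 / 3.0
        if link == "probit":
            return 1.0
    if family in ("poisson", "quasipoisson"):
        if link == "sqrt":
            return 0.25
        if link == "log":
            if beta0 is None:
                raise ConfigurationError(
                    "poisson/log residual variance requires beta0 from the "
                    "random-effects-only model"
                )
            return float(np.log(1.0 / np.exp(beta0) + 1.0))
    raise ConfigurationError(f"unsupported family/link pair: {family}/{link}")


def fixed_group_variance(design_matrix, estimates) -> float:
    """Variance (n-1 denominator) of the fixed-effect contributions X @ beta."""
    X = np.asarray(design_matrix, dtype=float)
    beta = np.asarray(estimates, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: design {X.shape} vs {beta.shape[0]} estimates"
        )
    values = X @ beta
    if values.shape[0] < 2:
        return 0.0
    return float(np.var(values, ddof=1))


@dataclass
class VarianceDecomposition:
    """Raw and percent variance components plus the derived triple."""

    raw: dict[str, float]
    percent: dict[str, float]
    derived_raw: dict[str, float]
    derived_percent: dict[str, float]
    degenerate: bool = False

    @property
    def total(self) -> float:
        return self.raw["total"]

    def component_row(self) -> dict[str, float]:
        """Flat raw-scale row for resampling matrices."""
        row = {k: v for k, v in self.raw.items()}
        row.update(self.derived_raw)
        return row

    def as_frame(self, round_percent: int | None = 1) -> pd.DataFrame:
        """Display table: component, raw, percent (percent rounded)."""
        rows = []
        for key, val in self.raw.items():
            pct = self.percent[key]
            rows.append((key, val, round(pct, round_percent) if round_percent
                         is not None else pct))
        for key, val in self.derived_raw.items():
            pct = self.derived_percent[key]
            rows.append((key, val, round(pct, round_percent) if round_percent
                         is not None else pct))
        return pd.DataFrame(rows, columns=["component", "raw", "percent"])

    def to_json(self, path) -> None:
        payload = {
            "raw": self.raw,
            "percent": self.percent,
            "derived_raw": self.derived_raw,
            "derived_percent": self.derived_percent,
            "degenerate": self.degenerate,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        self.as_frame(round_percent=None).to_csv(path, index=False)


def decompose(model: FittedVCModel) -> VarianceDecomposition:
    """Split the phenotypic variance of a fitted model into components."""
    raw: dict[str, float] = {}
    for term, value in model.variance_estimates.items():
        if term == "residual":
            continue
        raw[term] = float(value)
    olre = getattr(model, "olre_variance", None)
    if olre is not None:
        raw["olre"] = float(olre)
    if len(model.fixed_estimates) > 1:
        raw["fixed_group"] = fixed_group_variance(
            model.fixed_design, model.beta
        )
    raw["residual"] = residual_variance(model)
    total = float(sum(raw.values()))
    raw["total"] = total

    degenerate = total <= 0.0
    def pct(x: float) -> float:
        return 0.0 if degenerate else 100.0 * x / total

    percent = {k: pct(v) for k, v in raw.items()}
    v_d = raw.get("dam", 0.0)
    v_s = raw.get("sire", 0.0)
    v_ds = raw.get("dam_sire", 0.0)
    derived_raw = {
        "additive": 4.0 * v_s,
        "nonadditive": 4.0 * v_ds,
        "maternal": v_d - v_s,
    }
    derived_percent = {k: pct(v) for k, v in derived_raw.items()}
    return VarianceDecomposition(
        raw=raw,
        percent=percent,
        derived_raw=derived_raw,
        derived_percent=derived_percent,
        degenerate=degenerate,
    )
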