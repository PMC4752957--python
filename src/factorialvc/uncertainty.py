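"""Bootstrap and jackknife machinery for variance-component intervals.

Workflow: resample observations (within family, or family x replicate,
strata), refit the model per iteration to build a component matrix,
then extract quantile-based bootstrap-t intervals (optionally BCa
corrected) or pseudo-value jackknife intervals.  Pairwise group
comparison uses the paired-iteration proportion rule.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DERIVED_COMPONENTS, VarianceDecomposition, decompose
from .design_data import ObservationTable
from .errors import (
    ConfigurationError,
    FactorialVCError,
    FitError,
    UsageError,
    ValidationError,
)
from .glmm import fit_glmm
from .lmm import fit_lmm
from .modelspec import ModelSpec

__all__ = [
    "ResampledData",
    "ComponentMatrix",
    "IntervalSet",
    "Interval",
    "resample_by_replicate",
    "resample_by_family",
    "fit_resampled",
    "ci_bootstrap_t",
    "compare_groups",
    "jackknife_fit",
    "ci_jackknife",
]

logger = logging.getLogger(__name__)

ITERATION_COLUMN = "iteration"

Interval = namedtuple("Interval", ["lower", "center", "upper"])


@dataclass
class ResampledData:
    """Stacked resampled observations with a 1-based iteration column."""

    table: ObservationTable
    iterations: int

    def iteration(self, b: int) -> ObservationTable:
        df = self.table.data
        sub = df[df[ITERATION_COLUMN] == b].drop(columns=[ITERATION_COLUMN])
        return self.table.with_data(sub.reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.table.data.to_csv(path, index=False)


@dataclass
class ComponentMatrix:
    """Iterations (or deleted blocks) x raw variance components."""

    frame: pd.DataFrame
    kind: str = "bootstrap"            # or "jackknife"
    n_obs: int | None = None           # N of the source data (jackknife)
    d: int | None = None               # deleted-block size (jackknife)
    n_failed: int = 0

    @property
    def usable(self) -> pd.DataFrame:
        return self.frame.dropna()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True, index_label="iteration")

    @classmethod
    def from_csv(cls, path, **meta) -> "ComponentMatrix":
        frame = pd.read_csv(path, index_col="iteration")
        return cls(frame=frame, **meta)


def _strata_indices(table: ObservationTable, columns: list[str]) -> dict:
    df = table.data
    groups = df.groupby(columns, observed=True, sort=True).indices
    for key, idx in groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empties
            raise ValidationError(f"empty stratum {key!r}")
    return groups


def _resample(
    table: ObservationTable,
    strata_columns: list[str],
    iterations: int,
    seed: int | None,
    out_dir=None,
) -> ResampledData:
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    df = table.data.reset_index(drop=True)
    base = table.with_data(df)
    groups = _strata_indices(base, strata_columns)
    rng = np.random.default_rng(seed)
    n = len(df)
    blocks = []
    for b in range(1, iterations + 1):
        idx = np.concatenate(
            [g[rng.integers(0, len(g), size=len(g))] for g in groups.values()]
        )
        part = df.iloc[idx].copy()
        part[ITERATION_COLUMN] = b
        blocks.append(part)
    stacked = pd.concat(blocks, ignore_index=True)
    assert len(stacked) == n * iterations

    if out_dir is not None:
        # mirror the per-family shard workflow: one CSV per family, merged
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        shards = []
        for i, (fam, part) in enumerate(
            stacked.groupby(table.family, observed=True, sort=True)
        ):
            shard = out_dir / f"resample_family_{i:04d}.csv"
            part.to_csv(shard, index=False)
            shards.append(shard)
        merged = pd.concat(
            [pd.read_csv(s) for s in shards], ignore_index=True
        )
        merged.to_csv(out_dir / "resampled_merged.csv", index=False)
        stacked = merged

    return ResampledData(table=base.with_data(stacked), iterations=iterations)


def resample_by_replicate(
    table: ObservationTable,
    iterations: int,
    seed: int | None = None,
    out_dir=None,
) -> ResampledData:
    """Resample with replacement within each family x replicate stratum.

    Every iteration reproduces each stratum's original size exactly.
    """
    if table.replicate is None:
        raise ConfigurationError(
            "resample_by_replicate requires a replicate column; use "
            "resample_by_family for designs without replicates"
        )
    return _resample(
        table, [table.family, table.replicate], iterations, seed, out_dir
    )


def resample_by_family(
    table: ObservationTable,
    iterations: int,
    seed: int | None = None,
    out_dir=None,
) -> ResampledData:
    """Resample with replacement within each family stratum."""
    return _resample(table, [table.family], iterations, seed, out_dir)


def _fit_once(
    table: ObservationTable,
    spec: ModelSpec,
    theta0: np.ndarray | None = None,
    fast: bool = False,
) -> VarianceDecomposition:
    if spec.is_gaussian:
        model = fit_lmm(table, spec, theta0=theta0, fast=fast)
    else:
        model = fit_glmm(table, spec, theta0=theta0, fast=fast)
    return decompose(model)


def _observed_theta(table: ObservationTable, spec: ModelSpec) -> np.ndarray | None:
    """Warm start for resampling refits: theta at the observed optimum."""
    try:
        if spec.is_gaussian:
            model = fit_lmm(table, spec)
            resid = model.variance_estimates.get("residual", 0.0)
            if resid <= 0:
                return None
            return np.sqrt(np.array([
                max(model.variance_estimates[t], 0.0) / resid
                for t in spec.random_terms
            ]))
        model = fit_glmm(table, spec, compute_beta0=False)
        theta = [max(model.variance_estimates[t], 0.0) for t in spec.random_terms]
        if spec.has_olre:
            theta.append(max(model.olre_variance or 0.0, 0.0))
        return np.sqrt(np.array(theta))
    except FactorialVCError:
        return None


def _matrix_columns(row: dict) -> list[str]:
    lead = [c for c in ("dam", "sire", "dam_sire") if c in row]
    extras = [
        c for c in row
        if c not in lead
        and c not in ("residual", "total", *DERIVED_COMPONENTS)
    ]
    return lead + extras + ["residual", "total", *DERIVED_COMPONENTS]


def fit_resampled(
    resampled: ResampledData,
    spec: ModelSpec,
    start: int = 1,
    end: int | None = None,
) -> ComponentMatrix:
    """Refit the model on each resampled iteration.

    Returns one row of raw components per iteration; failed refits
    become missing rows (logged, counted, excluded from quantiles).
    """
    if end is None:
        end = resampled.iterations
    if not 1 <= start <= end <= resampled.iterations:
        raise ConfigurationError(
            f"invalid iteration range [{start}, {end}] for "
            f"{resampled.iterations} iterations"
        )
    df = resampled.table.data
    by_iter = df.groupby(ITERATION_COLUMN, observed=True).indices
    rows = {}
    columns = None
    n_failed = 0
    theta0 = None
    for b in range(start, end + 1):
        idx = by_iter.get(b)
        sub = resampled.table.with_data(
            df.iloc[idx].drop(columns=[ITERATION_COLUMN]).reset_index(drop=True)
        )
        if theta0 is None:
            theta0 = _observed_theta(sub, spec)
        try:
            row = _fit_once(sub, spec, theta0=theta0, fast=True).component_row()
            if columns is None:
                columns = _matrix_columns(row)
            rows[b] = row
        except FactorialVCError as exc:
            n_failed += 1
            logger.warning("iteration %d fit failed: %s", b, exc)
            rows[b] = None
    if columns is None:
        raise FitError("every resampled fit failed")
    frame = pd.DataFrame(
        [
            rows[b] if rows[b] is not None else dict.fromkeys(columns, np.nan)
            for b in range(start, end + 1)
        ],
        index=pd.Index(range(start, end + 1), name=ITERATION_COLUMN),
        columns=columns,
    )
    return ComponentMatrix(frame=frame, kind="bootstrap", n_failed=n_failed)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Per-component (lower, center, upper) at one confidence level."""

    level: float
    center_kind: str                    # "median" or "pseudo-value mean"
    correction: str                     # "none" or "BCa"
    raw: dict[str, Interval] = field(default_factory=dict)
    percent: dict[str, Interval] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(d):
            return {
                k: {"lower": v.lower, "center": v.center, "upper": v.upper}
                for k, v in d.items()
            }
        return {
            "level": self.level,
            "center_kind": self.center_kind,
            "correction": self.correction,
            "raw": conv(self.raw),
            "percent": conv(self.percent),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scale, d in (("raw", self.raw), ("percent", self.percent)):
            for comp, iv in d.items():
                rows.append((scale, comp, iv.lower, iv.center, iv.upper))
        return pd.DataFrame(
            rows, columns=["scale", "component", "lower", "center", "upper"]
        )

    def to_json(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "IntervalSet":
        def conv(d):
            return {
                k: Interval(v["lower"], v["center"], v["upper"])
                for k, v in d.items()
            }
        return cls(
            level=payload["level"],
            center_kind=payload["center_kind"],
            correction=payload["correction"],
            raw=conv(payload.get("raw", {})),
            percent=conv(payload.get("percent", {})),
        )

    @classmethod
    def from_json(cls, path) -> "IntervalSet":
        import json

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def percent_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert every row's components to percentages of that row's total."""
    total = frame["total"]
    out = frame.div(total, axis=0) * 100.0
    out["total"] = np.where(total > 0, 100.0, 0.0)
    return out


def _observed_values(observed: VarianceDecomposition, scale: str) -> dict:
    if scale == "raw":
        return observed.component_row()
    vals = dict(observed.percent)
    vals.update(observed.derived_percent)
    return vals


def _bca_probs(values, obs, jack_values, alpha) -> tuple[float, float]:
    """Bias/acceleration-adjusted quantile probabilities."""
    b = len(values)
    frac = np.sum(values < obs) / b
    frac = min(max(frac, 1.0 / (b + 1)), b / (b + 1))
    z0 = stats.norm.ppf(frac)
    dev = np.mean(jack_values) - jack_values
    ss = np.sum(dev**2)
    a = float(np.sum(dev**3) / (6.0 * ss**1.5)) if ss > 0 else 0.0
    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)

    def adj(z):
        return float(stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z))))

    return adj(z_lo), adj(z_hi)


def ci_bootstrap_t(
    matrix: ComponentMatrix,
    level: float = 95.0,
    observed: VarianceDecomposition | None = None,
    jack: ComponentMatrix | None = None,
    components: tuple[str, ...] | None = None,
) -> IntervalSet:
    """Quantile-based bootstrap-t intervals and medians per component.

    Quantiles use linear interpolation (Hyndman-Fan definition 7).  When
    both the observed decomposition and a delete-one jackknife matrix
    are supplied, the BCa adjustment relocates the interval
    probabilities (the median is reported unadjusted).
    """
    if (observed is None) != (jack is None):
        raise ConfigurationError(
            "BCa correction needs both the observed decomposition and the "
            "delete-one jackknife matrix"
        )
    use_bca = observed is not None
    frame = matrix.usable
    if len(frame) < 100:
        warnings.warn(
            f"only {len(frame)} usable bootstrap rows; at least 100 are "
            "recommended for stable intervals",
            stacklevel=2,
        )
    alpha = 1.0 - level / 100.0
    if components is None:
        components = tuple(frame.columns)
    out = IntervalSet(
        level=level,
        center_kind="median",
        correction="BCa" if use_bca else "none",
    )
    for scale in ("raw", "percent"):
        values_frame = frame if scale == "raw" else percent_rows(frame)
        jack_frame = None
        obs_vals = None
        if use_bca:
            jack_frame = jack.usable if scale == "raw" else percent_rows(jack.usable)
            obs_vals = _observed_values(observed, scale)
        target = out.raw if scale == "raw" else out.percent
        for comp in components:
            vals = values_frame[comp].to_numpy(dtype=float)
            p_lo, p_hi = alpha / 2.0, 1.0 - alpha / 2.0
            if use_bca and comp in jack_frame.columns and comp in obs_vals:
                p_lo, p_hi = _bca_probs(
                    vals, obs_vals[comp],
                    jack_frame[comp].to_numpy(dtype=float), alpha
                )
            lower, upper = np.quantile(vals, [p_lo, p_hi], method="linear")
            center = float(np.quantile(vals, 0.5, method="linear"))
            target[comp] = Interval(float(lower), center, float(upper))
    return out


def compare_groups(
    matrix_a: ComponentMatrix, matrix_b: ComponentMatrix, component: str
) -> float:
    """One-tailed p for a pairwise group difference in one component.

    p = min(#{A-B < 0}, #{A-B > 0}) / n over paired iteration numbers;
    ties count toward neither tail (a tie count triggers a warning).
    """
    a = matrix_a.frame[component]
    b = matrix_b.frame[component]
    if len(a) != len(b):
        raise UsageError(
            f"groups must have equal iteration counts ({len(a)} vs {len(b)})"
        )
    diff = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    diff = diff[~np.isnan(diff)]
    n = len(diff)
    if n == 0:
        raise UsageError("no usable paired iterations")
    n_less = int(np.sum(diff < 0))
    n_greater = int(np.sum(diff > 0))
    n_ties = n - n_less - n_greater
    if n_ties:
        warnings.warn(
            f"{n_ties} tied paired differences contribute to neither tail",
            stacklevel=2,
        )
    return min(n_less, n_greater) / n


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife_fit(
    table: ObservationTable,
    spec: ModelSpec,
    d: int = 1,
    seed: int | None = None,
) -> ComponentMatrix:
    """Delete-one (or delete-d) jackknife refits.

    Delete-one processes observations in original row order; delete-d
    shuffles once (seeded) and deletes floor(N/d) sequential blocks.
    """
    n = table.n_obs
    if d < 1:
        raise ConfigurationError("d must be >= 1")
    if d >= n:
        raise UsageError(f"d={d} must be smaller than the number of rows {n}")
    if n / d < 10:
        warnings.warn(
            f"only {n // d} jackknife groups (N/d = {n / d:.1f}); intervals "
            "will be unstable",
            stacklevel=2,
        )
    df = table.data.reset_index(drop=True)
    base = table.with_data(df)
    if d == 1:
        order = np.arange(n)
        n_groups = n
    else:
        order = np.random.default_rng(seed).permutation(n)
        n_groups = n // d
    rows = {}
    columns = None
    n_failed = 0
    all_idx = np.arange(n)
    theta0 = _observed_theta(base, spec)
    for g in range(n_groups):
        deleted = order[g * d : (g + 1) * d]
        keep = np.delete(all_idx, deleted)
        sub = base.subset(keep)
        try:
            row = _fit_once(sub, spec, theta0=theta0, fast=True).component_row()
            if columns is None:
                columns = _matrix_columns(row)
            rows[g] = row
        except FactorialVCError as exc:
            n_failed += 1
            logger.warning("jackknife group %d fit failed: %s", g, exc)
            rows[g] = None
    if columns is None:
        raise FitError("every jackknife fit failed")
    frame = pd.DataFrame(
        [
            rows[g] if rows[g] is not None else dict.fromkeys(columns, np.nan)
            for g in range(n_groups)
        ],
        index=pd.Index(range(1, n_groups + 1), name=ITERATION_COLUMN),
        columns=columns,
    )
    return ComponentMatrix(
        frame=frame, kind="jackknife", n_obs=n, d=d, n_failed=n_failed
    )


def ci_jackknife(
    matrix: ComponentMatrix,
    observed: VarianceDecomposition,
    level: float = 95.0,
    d: int | None = None,
    N: int | None = None,
    components: tuple[str, ...] | None = None,
) -> IntervalSet:
    """Pseudo-value jackknife intervals.

    Pseudo-value per row: M*obs - (M-1)*row with M = N/d; the interval
    is the pseudo-value mean +/- t(alpha/2, df=M) * SE.  Percent-scale
    rows are converted to percentages of their row total before the
    pseudo-value transform.
    """
    if observed is None:
        raise ConfigurationError(
            "jackknife intervals require the observed variance components"
        )
    d = d if d is not None else matrix.d
    N = N if N is not None else matrix.n_obs
    if d is None or N is None:
        raise ConfigurationError(
            "d and N must be supplied (or carried by the jackknife matrix)"
        )
    m_groups = N / d
    alpha = 1.0 - level / 100.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=m_groups)
    frame = matrix.usable
    if components is None:
        components = tuple(frame.columns)
    out = IntervalSet(
        level=level, center_kind="pseudo-value mean", correction="none"
    )
    for scale in ("raw", "percent"):
        values_frame = frame if scale == "raw" else percent_rows(frame)
        obs_vals = _observed_values(observed, scale)
        target = out.raw if scale == "raw" else out.percent
        for comp in components:
            if comp not in obs_vals:
                continue
            vals = values_frame[comp].to_numpy(dtype=float)
            pseudo = m_groups * obs_vals[comp] - (m_groups - 1.0) * vals
            center = float(np.mean(pseudo))
            if len(pseudo) > 1:
                se = float(np.std(pseudo, ddof=1) / np.sqrt(len(pseudo)))
            else:
                se = 0.0
            half = t_crit * se
            target[comp] = Interval(center - half, center, center + half)
    return out
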