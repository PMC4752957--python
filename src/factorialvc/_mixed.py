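"""Shared machinery for mixed models with crossed random intercepts.

Both engines profile out the random-effect coefficients with the same
sparse-design / dense-Schur linear algebra:

* Gaussian models maximize the profiled (restricted) log-likelihood over
  the relative standard deviations ``theta_k = sigma_k / sigma_R``; the
  residual variance and fixed effects are profiled out in closed form.
* Nonnormal models maximize the Laplace-approximated marginal likelihood;
  the inner penalized iteratively reweighted least squares (PIRLS) loop
  finds the joint conditional modes of the spherical random effects and
  the fixed effects, and the outer optimizer moves ``theta``.

The observation-level random effect (one level per row) is eliminated
analytically through its diagonal block, so overdispersion models cost
O(n) extra work instead of an n x n factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg.lapack import dpotrf, dpotrs
from scipy.special import gammaln

from .design_data import ObservationTable
from .errors import (
    ConvergenceError,
    FitError,
    RankError,
    SchemaError,
    ValidationError,
)
from .families import Family, Link, get_family, get_link
from .modelspec import ModelSpec

# contract tolerances
DEVIANCE_RTOL = 1e-8
PIRLS_TOL = 1e-12
MAX_OUTER_ITER = 500
MAX_PIRLS_ITER = 200
BOUNDARY_REL_TOL = 1e-8
THETA_MAX = 100.0  # latent-scale sd cap for nonnormal fits (separation guard)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Numeric design extracted from an ObservationTable for one model."""

    y: np.ndarray                    # mean response per row
    m: np.ndarray                    # prior weights (binomial trials)
    X: np.ndarray                    # fixed-effect design, intercept first
    fixed_names: list[str]
    Z: sparse.csr_matrix             # group random effects (no OLRE block)
    term_names: list[str]            # group random terms, canonical order
    term_slices: dict[str, slice]
    olre: bool = False               # observation-level random effect present
    n_obs_original: int = 0          # rows before any internal aggregation
    X_original: np.ndarray = None    # fixed design on the original rows
    loglik_offset: float = 0.0       # log binomial coefficients added by aggregation

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def n_theta(self) -> int:
        return len(self.term_names) + (1 if self.olre else 0)

    @property
    def Z_dense(self) -> np.ndarray | None:
        """Dense copy of Z when small enough that BLAS beats sparse ops."""
        if not hasattr(self, "_z_dense"):
            if self.Z.shape[0] * max(self.Z.shape[1], 1) <= 200_000:
                self._z_dense = self.Z.toarray()
            else:
                self._z_dense = None
        return self._z_dense


def _term_column(table: ObservationTable, term: str) -> str:
    if term == "dam":
        return table.dam
    if term == "sire":
        return table.sire
    if term == "dam_sire":
        return table.family
    return term


def _fixed_matrix(
    df: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + main effects / ':' interactions, dummy-coding factors."""

    def expand(name: str) -> tuple[np.ndarray, list[str]]:
        if name not in df.columns:
            raise SchemaError(f"fixed-effect column {name!r} not found")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            return col.to_numpy(dtype=float)[:, None], [name]
        dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
        return dummies.to_numpy(dtype=float), list(dummies.columns)

    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    for term in terms:
        parts = term.split(":")
        mat, labels = expand(parts[0])
        for part in parts[1:]:
            m2, l2 = expand(part)
            mat = np.einsum("ni,nj->nij", mat, m2).reshape(len(df), -1)
            labels = [f"{a}:{b}" for a in labels for b in l2]
        blocks.append(mat)
        names.extend(labels)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError(
            f"fixed-effect design matrix is rank deficient ({X.shape[1]} columns)"
        )
    return X, names


def _response(table: ObservationTable, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (mean response, prior weights) per row."""
    df = table.data
    if spec.failures is not None:
        for col in (spec.response, spec.failures):
            if col not in df.columns:
                raise SchemaError(f"count column {col!r} not found")
        succ = df[spec.response].to_numpy(dtype=float)
        fail = df[spec.failures].to_numpy(dtype=float)
        if (succ < 0).any() or (fail < 0).any():
            raise ValidationError("success/failure counts must be non-negative")
        m = succ + fail
        if (m <= 0).any():
            raise ValidationError(
                "rows with zero total trials cannot enter a binomial fit"
            )
        return succ / m, m
    kind = "continuous"
    if spec.is_binomial:
        kind = "binary"
    elif spec.is_poisson:
        kind = "count"
    table.check_response(spec.response, kind)
    y = df[spec.response].to_numpy(dtype=float)
    return y, np.ones_like(y)


def build_design(
    table: ObservationTable,
    spec: ModelSpec,
    drop_random: str | None = None,
    random_terms: tuple[str, ...] | None = None,
    fixed_terms: tuple[str, ...] | None = None,
    olre: bool | None = None,
    aggregate: bool = True,
) -> DesignMatrices:
    """Assemble the numeric design for one model fit.

    ``drop_random`` removes a single random term (for LRTs);
    ``random_terms`` overrides the full random structure (expert use,
    e.g. one-way oracle fits); ``olre`` overrides the spec's
    overdispersion flag.  Binary responses with fixed effects constant
    within the crossed random cells are aggregated to weighted binomial
    rows — an exact reformulation of the Bernoulli likelihood that makes
    large balanced designs cheap.  The aggregation partition always uses
    the spec's *full* random structure so that log-likelihood constants
    cancel between nested models.
    """
    df = table.data
    y, m = _response(table, spec)
    use_olre = spec.has_olre if olre is None else olre

    all_terms = tuple(random_terms) if random_terms is not None else spec.random_terms
    terms_used = [t for t in all_terms if t != drop_random]
    if drop_random is not None and drop_random not in all_terms:
        raise SchemaError(f"cannot drop unknown random term {drop_random!r}")

    terms = fixed_terms if fixed_terms is not None else spec.fixed
    X, fixed_names = _fixed_matrix(df, terms)
    X_original = X
    n_original = len(df)

    loglik_offset = 0.0
    if (
        aggregate
        and spec.is_binomial
        and not use_olre
        and spec.failures is None
        and len(df) > 0
    ):
        agg = _aggregate_binary(df, table, list(all_terms), X, y)
        if agg is not None:
            df, X, y, m = agg
            k = y * m
            loglik_offset = float(np.sum(
                gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
            ))
    random_terms = terms_used

    codes_per_term = {}
    offsets = {}
    q = 0
    for term in random_terms:
        col = _term_column(table, term)
        if col not in df.columns:
            raise SchemaError(f"random-effect column {col!r} not found")
        codes, levels = pd.factorize(df[col].astype(str), sort=True)
        codes_per_term[term] = (codes, len(levels))
        offsets[term] = q
        q += len(levels)

    n = len(df)
    rows = np.tile(np.arange(n), len(random_terms))
    cols = np.concatenate(
        [codes_per_term[t][0] + offsets[t] for t in random_terms]
    ) if random_terms else np.empty(0, dtype=int)
    if random_terms:
        Z = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, q)
        )
    else:
        Z = sparse.csr_matrix((n, 0))
    slices = {
        t: slice(offsets[t], offsets[t] + codes_per_term[t][1])
        for t in random_terms
    }
    return DesignMatrices(
        y=y,
        m=m,
        X=X,
        fixed_names=fixed_names,
        Z=Z,
        term_names=list(random_terms),
        term_slices=slices,
        olre=use_olre,
        n_obs_original=n_original,
        X_original=X_original,
        loglik_offset=loglik_offset,
    )


def _aggregate_binary(df, table, random_terms, X, y):
    """Collapse Bernoulli rows to binomial counts per design cell.

    Valid only when every fixed-effect value is constant within a cell,
    which holds e.g. for dam-level covariates.  Returns None when the
    reduction is not exact.
    """
    key_cols = [_term_column(table, t) for t in random_terms]
    if not key_cols:
        return None
    combined = np.zeros(len(df), dtype=np.int64)
    for col in key_cols:
        c, levels = pd.factorize(df[col].astype(str), sort=True)
        combined = combined * len(levels) + c
    codes, _ = pd.factorize(combined, sort=True)
    n_cells = codes.max() + 1
    if n_cells >= 0.7 * len(df):
        return None  # nothing to gain
    # fixed effects must be cell-constant for exactness
    order = np.argsort(codes, kind="stable")
    first_of_cell = order[np.searchsorted(codes[order], np.arange(n_cells))]
    if not np.allclose(X, X[first_of_cell][codes]):
        return None
    m_agg = np.bincount(codes, minlength=n_cells).astype(float)
    succ = np.bincount(codes, weights=y, minlength=n_cells)
    df_agg = df.iloc[first_of_cell].reset_index(drop=True)
    return df_agg, X[first_of_cell], succ / m_agg, m_agg


# ---------------------------------------------------------------------------
# penalized weighted least squares with Schur elimination
# ---------------------------------------------------------------------------

class _PWLS:
    """Solve one penalized weighted least-squares system.

    Unknowns are the spherical group modes ``u`` (scaled by ``s`` per
    column), the fixed effects ``beta``, and — eliminated analytically —
    the OLRE modes.  ``w`` are working weights, ``z`` the working
    response.
    """

    def __init__(self, dm: DesignMatrices, s: np.ndarray, s_olre: float,
                 w: np.ndarray, z: np.ndarray):
        self.dm = dm
        self.s_olre = s_olre
        if dm.olre:
            # effective weights after eliminating the diagonal OLRE block
            self.d_olre = s_olre**2 * w + 1.0
            w_eff = w / self.d_olre
            self.logdet_olre = float(np.sum(np.log(self.d_olre)))
        else:
            self.d_olre = None
            w_eff = w
            self.logdet_olre = 0.0
        self.w = w
        self.w_eff = w_eff
        X = dm.X
        Zd = dm.Z_dense
        if Zd is not None:
            Zw = Zd * w_eff[:, None]
            ZtWZ = Zd.T @ Zw
            ZtWX = Zw.T @ X
            ZtWz = Zw.T @ z
        else:
            Z = dm.Z
            Zw_sp = Z.multiply(w_eff[:, None]).tocsc()
            ZtWZ = (Z.T @ Zw_sp).toarray()
            ZtWX = Zw_sp.T @ X
            ZtWz = Zw_sp.T @ z
        XtWX = X.T @ (w_eff[:, None] * X)
        XtWz = X.T @ (w_eff * z)
        q = dm.q
        if q:
            A = ZtWZ * s
            A *= s[:, None]
            A.flat[:: q + 1] += 1.0
            cA, info = dpotrf(A, lower=1, overwrite_a=1)
            if info != 0:
                raise FitError("random-effect system not positive definite")
            self.cA = cA
            self.logdetA = 2.0 * float(np.sum(np.log(np.diag(cA)))) \
                + self.logdet_olre
            B = s[:, None] * ZtWX
            AinvB, _ = dpotrs(cA, B, lower=1)
        else:
            self.cA = None
            self.logdetA = self.logdet_olre
            B = np.zeros((0, dm.p))
            AinvB = B
        S = XtWX - B.T @ AinvB
        cS, info = dpotrf(S, lower=1)
        if info != 0:
            raise RankError("fixed-effect system singular at the optimum")
        self.cS = cS
        self.logdetS = 2.0 * float(np.sum(np.log(np.diag(cS))))
        rhs_u = s * ZtWz
        rhs_b = XtWz
        self.beta, _ = dpotrs(cS, rhs_b - AinvB.T @ rhs_u, lower=1)
        if q:
            self.u, _ = dpotrs(cA, rhs_u - B @ self.beta, lower=1)
        else:
            self.u = np.zeros(0)
        self.s = s
        self._z = z

    def olre_modes(self, eta_groups: np.ndarray) -> np.ndarray:
        """Conditional OLRE modes given the group+fixed linear predictor."""
        if not self.dm.olre:
            return np.zeros(0)
        resid = self._z - eta_groups
        return self.s_olre * self.w * resid / self.d_olre


def linear_predictor(dm: DesignMatrices, s, u, beta, s_olre=0.0, u_olre=None):
    Zd = dm.Z_dense
    if Zd is not None:
        eta = dm.X @ beta + Zd @ (s * u)
    else:
        eta = dm.X @ beta + dm.Z @ (s * u)
    if dm.olre and u_olre is not None and u_olre.size:
        eta = eta + s_olre * u_olre
    return eta


# ---------------------------------------------------------------------------
# Gaussian profiled deviance
# ---------------------------------------------------------------------------

@dataclass
class GaussianFitResult:
    theta: np.ndarray
    sigma2: dict[str, float]
    sigma2_resid: float
    beta: np.ndarray
    u: np.ndarray
    loglik: float
    deviance: float
    method: str
    converged: bool
    n_iter: int
    boundary: bool


class GaussianProfile:
    """Profiled (RE)ML deviance over theta for a Gaussian mixed model."""

    def __init__(self, dm: DesignMatrices, method: str = "REML"):
        if dm.olre:
            raise FitError("observation-level random effects are not defined "
                           "for gaussian models")
        self.dm = dm
        self.method = method
        Z, X, y = dm.Z, dm.X, dm.y
        self.ZtZ = (Z.T @ Z).toarray()
        self.ZtX = Z.T @ X
        self.XtX = X.T @ X
        self.Zty = Z.T @ y
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n = dm.n
        self.p = dm.p

    def _expand(self, theta: np.ndarray) -> np.ndarray:
        s = np.empty(self.dm.q)
        for k, term in enumerate(self.dm.term_names):
            s[self.dm.term_slices[term]] = theta[k]
        return s

    def components(self, theta: np.ndarray):
        # hot path: raw LAPACK (dpotrf/dpotrs) to dodge wrapper overhead
        s = self._expand(np.asarray(theta, dtype=float))
        if self.dm.q:
            A = self.ZtZ * s
            A *= s[:, None]
            A.flat[:: A.shape[0] + 1] += 1.0
            cA, info = dpotrf(A, lower=1, overwrite_a=1)
            if info != 0:
                raise FitError("random-effect system not positive definite")
            logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
            B = s[:, None] * self.ZtX
            AinvB, _ = dpotrs(cA, B, lower=1)
        else:
            cA = None
            logdetA = 0.0
            B = np.zeros((0, self.p))
            AinvB = B
        S = self.XtX - B.T @ AinvB
        cS, info = dpotrf(S, lower=1)
        if info != 0:
            raise RankError("fixed-effect design is singular")
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cS))))
        rhs_u = s * self.Zty
        beta, _ = dpotrs(cS, self.Xty - AinvB.T @ rhs_u, lower=1)
        if self.dm.q:
            u, _ = dpotrs(cA, rhs_u - B @ beta, lower=1)
        else:
            u = np.zeros(0)
        pwrss = self.yty - float(rhs_u @ u) - float(self.Xty @ beta)
        pwrss = max(pwrss, 1e-300)
        return s, u, beta, pwrss, logdetA, logdetS

    def deviance(self, theta: np.ndarray) -> float:
        try:
            _, _, _, pwrss, logdetA, logdetS = self.components(theta)
        except (FitError, RankError):
            # numeric blow-up at an extreme probe: steer the search back
            return 1e12
        n, p = self.n, self.p
        if self.method == "REML":
            df = n - p
            return logdetA + logdetS + df * (1.0 + _LOG2PI + np.log(pwrss / df))
        return logdetA + n * (1.0 + _LOG2PI + np.log(pwrss / n))

    def value_and_grad(self, theta: np.ndarray):
        """Profiled deviance and its exact theta-gradient.

        Uses the envelope theorem for the penalized RSS (u and beta are
        profiled minimizers) and trace identities for the log-determinant
        terms; everything reduces to the cached cross-products.
        """
        theta = np.asarray(theta, dtype=float)
        k = len(theta)
        try:
            s = self._expand(theta)
            ZtZ_D = self.ZtZ * s  # columns scaled: ZtZ @ diag(s)
            A = ZtZ_D * s[:, None]
            A.flat[:: self.dm.q + 1] += 1.0
            cA, info = dpotrf(A, lower=1, overwrite_a=1)
            if info != 0:
                raise FitError("random-effect system not positive definite")
            logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
            B = s[:, None] * self.ZtX
            G, _ = dpotrs(cA, B, lower=1)          # A^{-1} B
            S = self.XtX - B.T @ G
            cS, info = dpotrf(S, lower=1)
            if info != 0:
                raise RankError("fixed-effect design is singular")
            logdetS = 2.0 * float(np.sum(np.log(np.diag(cS))))
            rhs_u = s * self.Zty
            beta, _ = dpotrs(cS, self.Xty - G.T @ rhs_u, lower=1)
            u, _ = dpotrs(cA, rhs_u - B @ beta, lower=1)
            pwrss = self.yty - float(rhs_u @ u) - float(self.Xty @ beta)
            pwrss = max(pwrss, 1e-300)

            # tr(A^{-1} P_k ZtZ D) = sum over slice of diag(A^{-1} D ZtZ)
            M, _ = dpotrs(cA, s[:, None] * self.ZtZ, lower=1)
            diagM = np.diag(M)
            # Z' r from cross-products: r = y - X beta - Z D u
            Ztr = self.Zty - self.ZtX @ beta - self.ZtZ @ (s * u)
            n, p = self.n, self.p
            df = n - p if self.method == "REML" else n
            if self.method == "REML":
                W = ZtZ_D @ G                       # for d logdet(S)
            grad = np.empty(k)
            for j, term in enumerate(self.dm.term_names):
                sl = self.dm.term_slices[term]
                d_logdetA = 2.0 * float(diagM[sl].sum())
                d_pwrss = -2.0 * float(Ztr[sl] @ u[sl])
                g = d_logdetA + df / pwrss * d_pwrss
                if self.method == "REML":
                    C = self.ZtX[sl].T @ G[sl]
                    H = G[sl].T @ W[sl]
                    dS = (H + H.T) - (C + C.T)
                    SinvdS, _ = dpotrs(cS, dS, lower=1)
                    g += float(np.trace(SinvdS))
                grad[j] = g
            if self.method == "REML":
                dev = logdetA + logdetS + df * (
                    1.0 + _LOG2PI + np.log(pwrss / df)
                )
            else:
                dev = logdetA + n * (1.0 + _LOG2PI + np.log(pwrss / n))
            return dev, grad
        except (FitError, RankError):
            return 1e12, np.zeros(k)

    def fit(self, theta0: np.ndarray | None = None,
            fast: bool = False) -> GaussianFitResult:
        dm = self.dm
        if np.var(dm.y) == 0.0:
            # degenerate: constant response pins every component at zero
            sigma2 = {t: 0.0 for t in dm.term_names}
            beta = np.zeros(self.p)
            beta[0] = dm.y[0] if self.n else 0.0
            return GaussianFitResult(
                theta=np.zeros(dm.n_theta), sigma2=sigma2, sigma2_resid=0.0,
                beta=beta, u=np.zeros(dm.q), loglik=np.inf, deviance=-np.inf,
                method=self.method, converged=True, n_iter=0, boundary=True,
            )
        k = dm.n_theta
        if k == 0:
            theta = np.zeros(0)
            _, u, beta, pwrss, _, _ = self.components(theta)
            df = self.n - self.p if self.method == "REML" else self.n
            dev = self.deviance(theta)
            return GaussianFitResult(
                theta=theta, sigma2={}, sigma2_resid=float(pwrss / df),
                beta=beta, u=u, loglik=-dev / 2.0, deviance=dev,
                method=self.method, converged=True, n_iter=0, boundary=False,
            )
        if theta0 is not None and len(theta0) == k:
            x0 = np.clip(np.asarray(theta0, dtype=float), 0.0, None)
        else:
            x0 = np.ones(k)
        # fast mode trades the last ~3 digits of theta for ~2x fewer
        # evaluations; used inside resampling loops where Monte-Carlo
        # noise dwarfs optimizer noise
        opts = (
            {"maxiter": MAX_OUTER_ITER, "ftol": DEVIANCE_RTOL, "gtol": 1e-7}
            if fast
            else {"maxiter": MAX_OUTER_ITER, "ftol": 1e-12, "gtol": 1e-9}
        )
        res = optimize.minimize(
            self.value_and_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * k, options=opts,
        )
        if not res.success:
            res2 = optimize.minimize(
                self.deviance, x0, method="Powell",
                bounds=[(0.0, None)] * k,
                options={"maxiter": MAX_OUTER_ITER, "ftol": DEVIANCE_RTOL},
            )
            if res2.fun <= res.fun:
                res = res2
        theta = np.clip(res.x, 0.0, None)
        s, u, beta, pwrss, logdetA, logdetS = self.components(theta)
        df = self.n - self.p if self.method == "REML" else self.n
        sigma2_resid = pwrss / df
        sigma2 = {
            t: float(theta[k_] ** 2 * sigma2_resid)
            for k_, t in enumerate(dm.term_names)
        }
        total = sum(sigma2.values()) + sigma2_resid
        boundary = False
        for t in sigma2:
            if sigma2[t] < BOUNDARY_REL_TOL * max(total, 1e-300):
                sigma2[t] = 0.0
                boundary = True
        dev = float(res.fun)
        if not np.isfinite(dev):
            raise ConvergenceError(
                "gaussian deviance did not converge to a finite value",
                last_state={"theta": theta, "deviance": dev},
            )
        return GaussianFitResult(
            theta=theta, sigma2=sigma2, sigma2_resid=float(sigma2_resid),
            beta=beta, u=u, loglik=-dev / 2.0, deviance=dev,
            method=self.method, converged=bool(res.success or np.isfinite(dev)),
            n_iter=int(res.nit), boundary=boundary,
        )


# ---------------------------------------------------------------------------
# nonnormal Laplace deviance via PIRLS
# ---------------------------------------------------------------------------

@dataclass
class LaplaceFitResult:
    theta: np.ndarray
    sigma2: dict[str, float]
    olre_variance: float | None
    beta: np.ndarray
    u: np.ndarray
    loglik: float
    deviance: float
    converged: bool
    n_iter: int
    boundary: bool
    mu: np.ndarray = field(repr=False, default=None)


class LaplaceProfile:
    """Laplace-approximated ML deviance over theta for binomial/Poisson."""

    def __init__(self, dm: DesignMatrices, family: Family, link: Link):
        self.dm = dm
        self.family = family
        self.link = link
        # warm start shared across outer evaluations
        self._state: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- helpers ---------------------------------------------------------
    def _split(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        dm = self.dm
        k = len(dm.term_names)
        s = np.empty(dm.q)
        for j, term in enumerate(dm.term_names):
            s[dm.term_slices[term]] = theta[j]
        s_olre = float(theta[k]) if dm.olre else 0.0
        return s, s_olre

    def _initial_state(self):
        dm = self.dm
        y, m = dm.y, dm.m
        if self.family.name == "binomial":
            mu0 = (y * m + 0.5) / (m + 1.0)
        else:
            mu0 = np.maximum(y, 0.1)
        eta0 = self.link(mu0)
        beta = np.zeros(dm.p)
        beta[0] = float(np.mean(eta0))
        u = np.zeros(dm.q)
        u_olre = np.zeros(dm.n if dm.olre else 0)
        return u, u_olre, beta

    def _penalized_dev(self, eta, u, u_olre):
        mu = self.family.clip_mu(self.link.inverse(eta))
        dev = float(np.sum(self.family.deviance_resid(self.dm.y, mu, self.dm.m)))
        return dev + float(u @ u) + float(u_olre @ u_olre), mu

    def pirls(self, theta: np.ndarray):
        """Find joint conditional modes of (u, beta) at fixed theta."""
        dm = self.dm
        s, s_olre = self._split(np.asarray(theta, dtype=float))
        warm_started = self._state is not None
        if self._state is None:
            # cold start a la glm.fit: one undamped solve at the row-wise
            # mustart linear predictor, which avoids the log-link overshoot
            u, u_olre, beta = self._initial_state()
            if self.family.name == "binomial":
                mustart = (dm.y * dm.m + 0.5) / (dm.m + 1.0)
            else:
                mustart = dm.y + 0.1
            eta0 = self.link(mustart)
            dmu = self.link.dmu_deta(eta0)
            mu_eta = np.maximum(np.abs(dmu), 1e-6)
            var = np.maximum(self.family.variance(mustart), 1e-10)
            w0 = dm.m * mu_eta**2 / var
            z0 = eta0 + (dm.y - mustart) / (np.sign(dmu) + (dmu == 0)) / mu_eta
            sys0 = _PWLS(dm, s, s_olre, w0, z0)
            u, beta = sys0.u, sys0.beta
            u_olre = sys0.olre_modes(linear_predictor(dm, s, u, beta))
        else:
            u, u_olre, beta = (v.copy() for v in self._state)
        eta = linear_predictor(dm, s, u, beta, s_olre, u_olre)
        pdev, mu = self._penalized_dev(eta, u, u_olre)
        for it in range(MAX_PIRLS_ITER):
            # clamp the link derivative consistently in weights and working
            # response: keeps the step finite near saturated fitted values
            dmu = self.link.dmu_deta(eta)
            mu_eta = np.maximum(np.abs(dmu), 1e-6)
            var = np.maximum(self.family.variance(mu), 1e-10)
            w = dm.m * mu_eta**2 / var
            z = eta + (dm.y - mu) / (np.sign(dmu) + (dmu == 0)) / mu_eta
            if not np.all(np.isfinite(w)) or not np.all(np.isfinite(z)):
                raise FitError(
                    "non-finite working weights; the fit may suffer from "
                    "complete separation in a random or fixed term"
                )
            sys = _PWLS(dm, s, s_olre, w, z)
            u_new, beta_new = sys.u, sys.beta
            eta_g = linear_predictor(dm, s, u_new, beta_new)
            u_olre_new = sys.olre_modes(eta_g)
            # step-halving on the penalized deviance
            step = 1.0
            improved = False
            for _ in range(25):
                u_t = u + step * (u_new - u)
                b_t = beta + step * (beta_new - beta)
                uo_t = u_olre + step * (u_olre_new - u_olre)
                eta_t = linear_predictor(dm, s, u_t, b_t, s_olre, uo_t)
                pdev_t, mu_t = self._penalized_dev(eta_t, u_t, uo_t)
                if np.isfinite(pdev_t) and pdev_t <= pdev * (1.0 + 1e-12) + 1e-12:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                if warm_started:
                    # stale warm state can strand the loop; restart cold
                    self._state = None
                    return self.pirls(theta)
                break  # line search stalled from cold start: at the mode
            delta = abs(pdev - pdev_t)
            u, beta, u_olre, eta, mu = u_t, b_t, uo_t, eta_t, mu_t
            converged_inner = delta < PIRLS_TOL * (abs(pdev_t) + 1.0)
            pdev = pdev_t
            if converged_inner:
                break
        else:
            raise ConvergenceError(
                "PIRLS failed to converge",
                last_state={"theta": theta, "pdev": pdev},
            )
        # recompute weights/logdet at the converged modes
        mu_eta = np.maximum(np.abs(self.link.dmu_deta(eta)), 1e-10)
        var = np.maximum(self.family.variance(mu), 1e-12)
        w = dm.m * mu_eta**2 / var
        sys = _PWLS(dm, s, s_olre, w, eta)  # z unused for logdet
        self._state = (u.copy(), u_olre.copy(), beta.copy())
        return {
            "u": u, "u_olre": u_olre, "beta": beta, "eta": eta, "mu": mu,
            "pdev": pdev, "logdetA": sys.logdetA, "n_iter": it + 1,
        }

    def deviance(self, theta: np.ndarray) -> float:
        try:
            state = self.pirls(theta)
        except (ConvergenceError, FitError, RankError):
            # extreme theta (separation ridge or numeric blow-up): steer
            # the optimizer back with a large finite value
            self._state = None
            return 1e12
        return state["pdev"] + state["logdetA"]

    def fit(self, theta0: np.ndarray | None = None,
            fast: bool = False) -> LaplaceFitResult:
        dm = self.dm
        k = dm.n_theta
        if k == 0:
            # plain GLM: a single PIRLS pass is the whole fit
            state = self.pirls(np.zeros(0))
            loglik = self.family.loglik(dm.y, state["mu"], dm.m)
            return LaplaceFitResult(
                theta=np.zeros(0), sigma2={}, olre_variance=None,
                beta=state["beta"], u=state["u"], loglik=float(loglik),
                deviance=float(state["pdev"]), converged=True,
                n_iter=int(state["n_iter"]), boundary=False, mu=state["mu"],
            )
        if theta0 is not None and len(theta0) == k:
            x0 = np.clip(np.asarray(theta0, dtype=float), 1e-3, THETA_MAX)
        else:
            x0 = np.full(k, 0.5)
        # Optimize on the log scale: steps are multiplicative, which keeps
        # the search off the separation cliffs that wreck unscaled line
        # searches.  The deviance is stationary at theta = 0, so floored
        # components are lifted once and re-optimized before accepting a
        # boundary solution.
        log_min, log_max = np.log(1e-6), np.log(THETA_MAX)
        # finite-difference step well above the PIRLS hysteresis noise
        opts = (
            {"maxiter": MAX_OUTER_ITER, "ftol": 1e-8, "gtol": 1e-6,
             "eps": 1e-5}
            if fast
            else {"maxiter": MAX_OUTER_ITER, "ftol": 1e-10, "gtol": 1e-7,
                  "eps": 1e-5}
        )
        bounds = [(log_min, log_max)] * k

        def objective(phi):
            return self.deviance(np.exp(phi))

        res = optimize.minimize(
            objective, np.log(x0), method="L-BFGS-B",
            bounds=bounds, options=opts,
        )
        floored = np.exp(res.x) < 1e-3
        if floored.any():
            self._state = None
            lifted = np.log(np.maximum(np.exp(res.x), 5e-2))
            res2 = optimize.minimize(
                objective, lifted, method="L-BFGS-B",
                bounds=bounds, options=opts,
            )
            if res2.fun < res.fun:
                res = res2
        if not res.success and not np.isfinite(res.fun):
            self._state = None
            res3 = optimize.minimize(
                self.deviance, x0, method="Powell",
                bounds=[(0.0, THETA_MAX)] * k,
                options={"maxiter": MAX_OUTER_ITER, "ftol": DEVIANCE_RTOL},
            )
            if res3.fun <= res.fun:
                res = res3
                res.x = np.log(np.clip(res.x, 1e-6, THETA_MAX))
        theta = np.exp(res.x)
        theta[theta < 2e-6] = 0.0
        self._state = None
        state = self.pirls(theta)
        n_group_terms = len(dm.term_names)
        sigma2 = {
            t: float(theta[j] ** 2) for j, t in enumerate(dm.term_names)
        }
        olre_var = float(theta[n_group_terms] ** 2) if dm.olre else None
        total = sum(sigma2.values()) + (olre_var or 0.0)
        boundary = False
        for t in sigma2:
            if total > 0 and sigma2[t] < BOUNDARY_REL_TOL * total:
                sigma2[t] = 0.0
                boundary = True
        u_all_sq = float(state["u"] @ state["u"]) + float(
            state["u_olre"] @ state["u_olre"]
        )
        loglik = (
            self.family.loglik(dm.y, state["mu"], dm.m)
            - 0.5 * u_all_sq
            - 0.5 * state["logdetA"]
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError(
                "Laplace deviance did not converge to a finite value",
                last_state={"theta": theta},
            )
        return LaplaceFitResult(
            theta=theta, sigma2=sigma2, olre_variance=olre_var,
            beta=state["beta"], u=state["u"], loglik=float(loglik),
            deviance=float(res.fun),
            converged=bool(res.success or np.isfinite(res.fun)),
            n_iter=int(res.nit), boundary=boundary, mu=state["mu"],
        )


def fit_laplace(dm: DesignMatrices, family_name: str, link_name: str) -> LaplaceFitResult:
    return LaplaceProfile(dm, get_family(family_name), get_link(link_name)).fit()
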