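import numpy as np
import pandas as pd
import pytest

from factorialvc import (
    FactorialDesignSpec,
    ModelSpec,
    ObservationTable,
    fit_glmm,
    overdispersion_test,
    simulate_factorial,
)
from factorialvc._mixed import LaplaceProfile, build_design
from factorialvc.errors import ConfigurationError, UsageError
from factorialvc.families import get_family, get_link


class TestAgainstGlmer:
    """Frozen oracle values computed with R lme4 1.1-37 glmer (Laplace)."""

    def test_binomial_logit(self, binomial_table):
        model = fit_glmm(binomial_table, ModelSpec(response="response",
                                                   family="binomial"))
        expected = {"dam": 0.7096712, "sire": 0.0904203, "dam_sire": 0.2311636}
        for term, value in expected.items():
            assert model.variance_estimates[term] == pytest.approx(
                value, rel=5e-3, abs=1e-4
            )
        assert model.log_likelihood == pytest.approx(-1186.523, abs=5e-3)

    def test_poisson_log(self, poisson_table):
        model = fit_glmm(poisson_table, ModelSpec(response="response",
                                                  family="poisson"))
        expected = {"dam": 0.46373018, "sire": 0.33321981, "dam_sire": 0.05992678}
        for term, value in expected.items():
            assert model.variance_estimates[term] == pytest.approx(
                value, rel=1e-2, abs=2e-4
            )
        assert model.log_likelihood == pytest.approx(-1689.313, abs=5e-3)
        # intercept-only refit is the model itself (no fixed terms)
        assert model.intercept_only_beta0 == pytest.approx(
            model.fixed_estimates["(Intercept)"]
        )


def test_aggregation_is_exact(binomial_table):
    """Collapsing Bernoulli rows to weighted binomial rows is a
    reformulation, not an approximation."""
    spec = ModelSpec(response="response", family="binomial")
    fam, link = get_family("binomial"), get_link("logit")

    dm_agg = build_design(binomial_table, spec, aggregate=True)
    dm_raw = build_design(binomial_table, spec, aggregate=False)
    assert dm_agg.n < dm_raw.n
    res_agg = LaplaceProfile(dm_agg, fam, link).fit()
    res_raw = LaplaceProfile(dm_raw, fam, link).fit()
    assert res_agg.loglik - dm_agg.loglik_offset == pytest.approx(
        res_raw.loglik, abs=1e-4
    )
    for term in res_raw.sigma2:
        assert res_agg.sigma2[term] == pytest.approx(
            res_raw.sigma2[term], rel=1e-3, abs=1e-5
        )


def test_null_simulation_components_vanish():
    """i.i.d. Bernoulli(0.5) data carry no group signal."""
    spec = ModelSpec(response="response", family="binomial")
    design = FactorialDesignSpec(
        n_dam=11, n_sire=11, n_offspring_per_family=10,
        components={}, family="binomial", intercept=0.0,
    )
    sums = {"dam": 0.0, "sire": 0.0, "dam_sire": 0.0}
    n_seeds = 100
    for seed in range(n_seeds):
        model = fit_glmm(simulate_factorial(design, seed=seed), spec,
                         compute_beta0=False)
        for term in sums:
            sums[term] += model.variance_estimates[term]
    for term, total in sums.items():
        assert total / n_seeds < 0.02, term


def test_logit_probit_rank_order(binomial_table):
    """Component importance ordering survives the link change."""
    logit = fit_glmm(binomial_table, ModelSpec(response="response",
                                               family="binomial", link="logit"))
    probit = fit_glmm(binomial_table, ModelSpec(response="response",
                                                family="binomial", link="probit"))

    def order(model):
        terms = ("dam", "sire", "dam_sire")
        return tuple(sorted(terms, key=lambda t: model.variance_estimates[t]))

    assert order(logit) == order(probit)


def test_relabel_binary_flips_intercept_only(binomial_table):
    spec = ModelSpec(response="response", family="binomial")
    base = fit_glmm(binomial_table, spec)
    flipped_table = binomial_table.with_data(
        binomial_table.data.assign(
            response=1 - binomial_table.data["response"]
        )
    )
    flipped = fit_glmm(flipped_table, spec)
    for term in ("dam", "sire", "dam_sire"):
        assert flipped.variance_estimates[term] == pytest.approx(
            base.variance_estimates[term], rel=5e-3, abs=1e-5
        )
    assert flipped.fixed_estimates["(Intercept)"] == pytest.approx(
        -base.fixed_estimates["(Intercept)"], rel=5e-3, abs=1e-4
    )


def test_sqrt_link_poisson_fits():
    design = FactorialDesignSpec(
        n_dam=6, n_sire=6, n_offspring_per_family=20,
        components={"dam": 0.2, "sire": 0.1, "dam_sire": 0.05},
        family="poisson", link="sqrt", intercept=3.0,
    )
    table = simulate_factorial(design, seed=11)
    model = fit_glmm(table, design.model_spec())
    assert model.converged
    assert all(v >= 0 for v in model.variance_estimates.values())


class TestOverdispersion:
    def _proportion_table(self, overdispersed, seed=4, n_per=40):
        rng = np.random.default_rng(seed)
        rows = []
        for d in range(6):
            for s in range(6):
                for rep in range(2):
                    eta = 0.3 * rng.standard_normal() if overdispersed else 0.0
                    p = 1 / (1 + np.exp(-eta))
                    succ = rng.binomial(n_per, p)
                    rows.append({
                        "dam": f"D{d}", "sire": f"S{s}", "rep": rep,
                        "succ": int(succ), "fail": int(n_per - succ),
                    })
        return ObservationTable(pd.DataFrame(rows))

    def test_binary_response_is_usage_error(self, binomial_table):
        spec = ModelSpec(response="response", family="binomial")
        with pytest.raises(UsageError, match="no overdispersion with binary"):
            overdispersion_test(binomial_table, spec)

    def test_quasi_family_on_binary_rejected(self, binomial_table):
        with pytest.raises(UsageError):
            fit_glmm(binomial_table,
                     ModelSpec(response="response", family="quasibinomial"))

    def test_no_overdispersion_not_detected(self):
        table = self._proportion_table(overdispersed=False)
        spec = ModelSpec(response="succ", failures="fail",
                         family="quasibinomial")
        result = overdispersion_test(table, spec)
        assert result.p_value > 0.05
        assert result.olre_variance < 0.05

    def test_overdispersion_detected(self):
        table = self._proportion_table(overdispersed=True, n_per=60)
        spec = ModelSpec(response="succ", failures="fail",
                         family="quasibinomial")
        result = overdispersion_test(table, spec)
        assert result.p_value < 0.05
        assert result.olre_variance > 0.01

    def test_quasipoisson_null_olre_near_zero(self, poisson_table):
        spec = ModelSpec(response="response", family="quasipoisson")
        model = fit_glmm(poisson_table, spec, compute_beta0=False)
        assert model.olre_variance is not None
        assert model.olre_variance < 0.05

    def test_poisson_overdispersion_power(self):
        """Lognormal extra noise on the rate is caught by the OLRE test."""
        hits = 0
        n_reps = 8
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            design = FactorialDesignSpec(
                n_dam=8, n_sire=8, n_offspring_per_family=32,
                components={"dam": 0.1, "sire": 0.05, "dam_sire": 0.05},
                family="poisson", intercept=1.0,
            )
            table = simulate_factorial(design, seed=seed + 100)
            # multiply rates by a lognormal factor: re-draw responses
            df = table.data.copy()
            n = len(df)
            extra = rng.lognormal(mean=0.0, sigma=0.5, size=n)
            base_rate = np.exp(1.0)
            df["response"] = rng.poisson(base_rate * extra)
            table = table.with_data(df)
            spec = ModelSpec(response="response", family="quasipoisson")
            if overdispersion_test(table, spec).p_value < 0.05:
                hits += 1
        assert hits / n_reps > 0.5


def test_gaussian_spec_rejected(gaussian_table):
    with pytest.raises(ConfigurationError):
        fit_glmm(gaussian_table, ModelSpec(response="response"))


def test_binary_quasi_via_counts_allowed():
    """Proportion data supplied as count pairs may carry an OLRE."""
    rng = np.random.default_rng(1)
    rows = []
    for d in range(4):
        for s in range(4):
            rows.append({
                "dam": f"D{d}", "sire": f"S{s}",
                "succ": int(rng.integers(5, 30)), "fail": int(rng.integers(5, 30)),
            })
    table = ObservationTable(pd.DataFrame(rows))
    spec = ModelSpec(response="succ", failures="fail", family="quasibinomial")
    model = fit_glmm(table, spec)
    assert model.olre_variance is not None
    assert model.olre_variance >= 0
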