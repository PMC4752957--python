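import numpy as np
import pandas as pd
import pytest
from scipy import stats

from factorialvc import (
    ComponentMatrix,
    ModelSpec,
    ObservationTable,
    ci_bootstrap_t,
    ci_jackknife,
    compare_groups,
    decompose,
    fit_lmm,
    fit_resampled,
    jackknife_fit,
    resample_by_family,
    resample_by_replicate,
    simulate_factorial,
)
from factorialvc.decomposition import VarianceDecomposition
from factorialvc.errors import ConfigurationError, UsageError
from factorialvc.power import FactorialDesignSpec
from factorialvc.uncertainty import ITERATION_COLUMN, ResampledData, percent_rows


@pytest.fixture(scope="module")
def small_design():
    return FactorialDesignSpec(
        n_dam=5, n_sire=5, n_offspring_per_family=8,
        components={"dam": 0.4, "sire": 0.1, "dam_sire": 0.1, "residual": 1.0},
        n_replicates=2,
    )


@pytest.fixture(scope="module")
def small_table(small_design):
    return simulate_factorial(small_design, seed=9)


def toy_matrix(values, total=None, extra=None):
    """ComponentMatrix with one component column plus a total."""
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame({"x": values})
    frame["total"] = total if total is not None else np.abs(values) + 1.0
    if extra:
        for k, v in extra.items():
            frame[k] = v
    frame.index = pd.Index(range(1, len(values) + 1), name=ITERATION_COLUMN)
    return ComponentMatrix(frame=frame)


def make_decomposition(raw):
    total = sum(raw.values())
    pct = {k: 100 * v / total for k, v in raw.items()}
    raw = dict(raw, total=total)
    pct["total"] = 100.0
    derived = {
        "additive": 4 * raw.get("sire", 0.0),
        "nonadditive": 4 * raw.get("dam_sire", 0.0),
        "maternal": raw.get("dam", 0.0) - raw.get("sire", 0.0),
    }
    dpct = {k: 100 * v / total for k, v in derived.items()}
    return VarianceDecomposition(
        raw=raw, percent=pct, derived_raw=derived, derived_percent=dpct
    )


class TestResampling:
    def test_sizes_preserved_per_stratum(self, small_table):
        res = resample_by_replicate(small_table, iterations=3, seed=0)
        df = res.table.data
        orig = small_table.data.groupby(
            [small_table.family, small_table.replicate]
        ).size()
        for b in (1, 2, 3):
            sub = df[df[ITERATION_COLUMN] == b]
            assert len(sub) == small_table.n_obs
            sizes = sub.groupby(
                [small_table.family, small_table.replicate]
            ).size()
            pd.testing.assert_series_equal(sizes, orig, check_names=False)

    def test_family_strata(self, small_table):
        res = resample_by_family(small_table, iterations=2, seed=0)
        df = res.table.data
        orig = small_table.data.groupby(small_table.family).size()
        sub = df[df[ITERATION_COLUMN] == 2]
        sizes = sub.groupby(small_table.family).size()
        pd.testing.assert_series_equal(sizes, orig, check_names=False)

    def test_seed_reproducibility(self, small_table):
        a = resample_by_family(small_table, 5, seed=42)
        b = resample_by_family(small_table, 5, seed=42)
        pd.testing.assert_frame_equal(a.table.data, b.table.data)
        c = resample_by_family(small_table, 5, seed=43)
        assert not a.table.data["response"].equals(c.table.data["response"])

    def test_singleton_stratum_duplicated(self):
        df = pd.DataFrame({
            "dam": ["d1", "d1", "d2"],
            "sire": ["s1", "s2", "s1"],
            "y": [1.0, 2.0, 3.0],
        })
        table = ObservationTable(df)
        res = resample_by_family(table, iterations=4, seed=1)
        out = res.table.data
        for fam, group in out.groupby(table.family):
            assert group["y"].nunique() == 1  # singleton strata

    def test_replicate_required(self, gaussian_table):
        with pytest.raises(ConfigurationError):
            resample_by_replicate(gaussian_table, 2, seed=0)

    def test_shard_workflow(self, small_table, tmp_path):
        res = resample_by_family(small_table, 2, seed=3, out_dir=tmp_path)
        shards = list(tmp_path.glob("resample_family_*.csv"))
        assert len(shards) == 25
        merged = tmp_path / "resampled_merged.csv"
        assert merged.exists()
        assert len(res.table.data) == 2 * small_table.n_obs


class TestFitResampled:
    def test_row_count_matches_range(self, small_table, small_design):
        res = resample_by_family(small_table, 12, seed=5)
        mat = fit_resampled(res, small_design.model_spec(), start=2, end=11)
        assert len(mat.frame) == 10
        assert list(mat.frame.index) == list(range(2, 12))

    def test_degenerate_resampling_recovers_observed(
        self, small_table, small_design
    ):
        spec = small_design.model_spec()
        observed = decompose(fit_lmm(small_table, spec))
        copies = []
        for b in (1, 2, 3):
            part = small_table.data.copy()
            part[ITERATION_COLUMN] = b
            copies.append(part)
        res = ResampledData(
            table=small_table.with_data(pd.concat(copies, ignore_index=True)),
            iterations=3,
        )
        mat = fit_resampled(res, spec)
        for col in ("dam", "sire", "dam_sire", "residual", "total"):
            np.testing.assert_allclose(
                mat.frame[col], observed.raw[col], rtol=1e-3, atol=1e-6
            )

    def test_bootstrap_consistency(self):
        design = FactorialDesignSpec(
            n_dam=6, n_sire=6, n_offspring_per_family=10,
            components={"dam": 0.5, "sire": 0.2, "dam_sire": 0.1,
                        "residual": 1.0},
        )
        table = simulate_factorial(design, seed=21)
        spec = design.model_spec()
        observed = decompose(fit_lmm(table, spec))
        res = resample_by_family(table, 200, seed=22)
        mat = fit_resampled(res, spec)
        assert mat.n_failed == 0
        for col in ("dam", "total"):
            mean = mat.frame[col].mean()
            se = mat.frame[col].std(ddof=1)
            assert abs(mean - observed.raw[col]) < 3 * se

    def test_invalid_range(self, small_table, small_design):
        res = resample_by_family(small_table, 3, seed=1)
        with pytest.raises(ConfigurationError):
            fit_resampled(res, small_design.model_spec(), start=2, end=5)


class TestBootstrapInterval:
    def test_definition7_quantiles(self):
        mat = toy_matrix(np.arange(1, 1001))
        with pytest.warns(None) if False else np.errstate():
            ivs = ci_bootstrap_t(mat, level=95, components=("x",))
        iv = ivs.raw["x"]
        assert iv.lower == pytest.approx(25.975)
        assert iv.center == pytest.approx(500.5)
        assert iv.upper == pytest.approx(975.025)

    def test_constant_column(self):
        mat = toy_matrix(np.full(200, 7.0))
        iv = ci_bootstrap_t(mat, components=("x",)).raw["x"]
        assert iv == (7.0, 7.0, 7.0)

    def test_bca_degenerates_to_percentile(self):
        rng = np.random.default_rng(0)
        sym = rng.normal(size=4001)
        sym = np.concatenate([sym, -sym])  # exactly symmetric about 0
        frame = pd.DataFrame({
            "dam": sym, "sire": sym, "dam_sire": sym,
            "residual": 1.0, "total": 4.0,
            "additive": sym, "nonadditive": sym, "maternal": sym,
        })
        frame.index = pd.Index(range(1, len(sym) + 1), name=ITERATION_COLUMN)
        mat = ComponentMatrix(frame=frame)
        jack = ComponentMatrix(frame=frame.copy())
        observed = make_decomposition(
            {"dam": 0.0, "sire": 0.0, "dam_sire": 0.0, "residual": 4.0}
        )
        plain = ci_bootstrap_t(mat, components=("dam",))
        bca = ci_bootstrap_t(mat, observed=observed, jack=jack,
                             components=("dam",))
        assert bca.correction == "BCa"
        assert bca.raw["dam"].lower == pytest.approx(
            plain.raw["dam"].lower, abs=1e-2
        )
        assert bca.raw["dam"].upper == pytest.approx(
            plain.raw["dam"].upper, abs=1e-2
        )

    def test_bca_needs_both_inputs(self):
        mat = toy_matrix(np.arange(100.0))
        with pytest.raises(ConfigurationError):
            ci_bootstrap_t(mat, observed=make_decomposition({"dam": 1.0}))

    def test_percent_rows_sum_to_100(self, small_table, small_design):
        res = resample_by_family(small_table, 20, seed=6)
        mat = fit_resampled(res, small_design.model_spec())
        pct = percent_rows(mat.usable)
        non_derived = [
            c for c in pct.columns
            if c not in ("total", "additive", "nonadditive", "maternal")
        ]
        np.testing.assert_allclose(pct[non_derived].sum(axis=1), 100.0)

    def test_low_row_warning(self):
        mat = toy_matrix(np.arange(10.0))
        with pytest.warns(UserWarning, match="usable bootstrap rows"):
            ci_bootstrap_t(mat, components=("x",))


class TestCompareGroups:
    def _mat(self, values):
        return toy_matrix(np.asarray(values, dtype=float))

    def test_all_greater(self):
        a = self._mat(np.arange(1000) + 10_000.0)
        b = self._mat(np.arange(1000.0))
        assert compare_groups(a, b, "x") == 0.0

    def test_alternating(self):
        diff = np.tile([1.0, -1.0], 500)
        a = self._mat(diff)
        b = self._mat(np.zeros(1000))
        assert compare_groups(a, b, "x") == pytest.approx(0.5)

    def test_49_of_1000_is_significant(self):
        a = np.ones(1000)
        a[:49] = -1.0  # 49 differences below zero
        mat_a = self._mat(a)
        mat_b = self._mat(np.zeros(1000))
        p = compare_groups(mat_a, mat_b, "x")
        assert p == pytest.approx(0.049)
        assert p < 0.05

    def test_50_of_1000_not_significant(self):
        a = np.ones(1000)
        a[:50] = -1.0
        p = compare_groups(self._mat(a), self._mat(np.zeros(1000)), "x")
        assert p == pytest.approx(0.05)
        assert not p < 0.05

    def test_identical_inputs_p_zero_with_tie_warning(self):
        a = self._mat(np.arange(100.0))
        with pytest.warns(UserWarning, match="tied"):
            assert compare_groups(a, a, "x") == 0.0

    def test_unequal_counts_rejected(self):
        with pytest.raises(UsageError):
            compare_groups(self._mat(np.ones(5)), self._mat(np.ones(6)), "x")


class TestJackknife:
    def test_delete_one_row_count(self, small_design):
        design = FactorialDesignSpec(
            n_dam=4, n_sire=4, n_offspring_per_family=6,
            components={"dam": 0.3, "sire": 0.1, "dam_sire": 0.1,
                        "residual": 1.0},
        )
        table = simulate_factorial(design, seed=30)
        mat = jackknife_fit(table, design.model_spec(), d=1)
        assert len(mat.frame) == table.n_obs == 96
        assert mat.kind == "jackknife"
        assert mat.d == 1 and mat.n_obs == 96

    def test_delete_d_floors_group_count(self):
        # N = 1005, d = 10 -> 100 groups
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "dam": rng.choice([f"d{i}" for i in range(5)], size=1005),
            "sire": rng.choice([f"s{i}" for i in range(5)], size=1005),
            "y": rng.normal(size=1005),
        })
        table = ObservationTable(df)
        mat = jackknife_fit(table, ModelSpec(response="y"), d=10, seed=3)
        assert len(mat.frame) == 100

    def test_d_too_large(self, small_table, small_design):
        with pytest.raises(UsageError):
            jackknife_fit(small_table, small_design.model_spec(),
                          d=small_table.n_obs)

    def test_delete_one_mean_near_observed(self, small_table, small_design):
        spec = small_design.model_spec()
        observed = decompose(fit_lmm(small_table, spec))
        mat = jackknife_fit(small_table, spec, d=1)
        n = small_table.n_obs
        for col in ("dam", "sire", "dam_sire", "residual"):
            # delete-one estimates differ from observed at O(1/N)
            assert abs(mat.frame[col].mean() - observed.raw[col]) < 5.0 / n


class TestJackknifeInterval:
    def test_pseudo_values_of_the_mean_are_raw_observations(self):
        """Textbook identity: jackknifing the sample mean gives back the
        observations as pseudo-values, and the classical t-interval."""
        rng = np.random.default_rng(8)
        x = rng.normal(10.0, 2.0, size=40)
        n = len(x)
        loo_means = (x.sum() - x) / (n - 1)
        mat = toy_matrix(loo_means, total=np.ones(n))
        observed = VarianceDecomposition(
            raw={"x": float(x.mean()), "total": 1.0},
            percent={"x": 100 * x.mean(), "total": 100.0},
            derived_raw={}, derived_percent={},
        )
        ivs = ci_jackknife(mat, observed, level=95, d=1, N=n,
                           components=("x",))
        iv = ivs.raw["x"]
        # pseudo-value mean == sample mean; half-width == t * s/sqrt(n)
        assert iv.center == pytest.approx(x.mean(), abs=1e-10)
        half = stats.t.ppf(0.975, df=n) * x.std(ddof=1) / np.sqrt(n)
        assert iv.upper - iv.center == pytest.approx(half, abs=1e-10)

    def test_all_equal_rows_degenerate_at_observed(self):
        mat = toy_matrix(np.full(30, 2.5), total=np.ones(30))
        observed = VarianceDecomposition(
            raw={"x": 2.5, "total": 1.0}, percent={"x": 250.0, "total": 100.0},
            derived_raw={}, derived_percent={},
        )
        iv = ci_jackknife(mat, observed, d=1, N=30, components=("x",)).raw["x"]
        assert iv == (2.5, 2.5, 2.5)

    def test_df_is_m_equals_n_over_d(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=100)
        mat = toy_matrix(vals, total=np.ones(100))
        observed = VarianceDecomposition(
            raw={"x": 0.0, "total": 1.0}, percent={"x": 0.0, "total": 100.0},
            derived_raw={}, derived_percent={},
        )
        # N=1000, d=10 -> df = 100
        iv = ci_jackknife(mat, observed, level=95, d=10, N=1000,
                          components=("x",)).raw["x"]
        m = 100.0
        pseudo = m * 0.0 - (m - 1.0) * vals
        se = pseudo.std(ddof=1) / np.sqrt(len(pseudo))
        expected_half = stats.t.ppf(0.975, df=m) * se
        assert iv.upper - iv.center == pytest.approx(expected_half, rel=1e-9)

    def test_observed_required(self):
        mat = toy_matrix(np.arange(20.0))
        with pytest.raises(ConfigurationError):
            ci_jackknife(mat, None, d=1, N=20)


def test_interval_set_serialization(tmp_path):
    mat = toy_matrix(np.arange(1, 201, dtype=float))
    ivs = ci_bootstrap_t(mat, components=("x",))
    ivs.to_json(tmp_path / "iv.json")
    ivs.to_csv(tmp_path / "iv.csv")
    from factorialvc import IntervalSet

    back = IntervalSet.from_json(tmp_path / "iv.json")
    assert back.raw["x"] == ivs.raw["x"]
    assert back.level == ivs.level
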