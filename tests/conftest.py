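import numpy as np
import pandas as pd
import pytest

from factorialvc import FactorialDesignSpec, ObservationTable, simulate_factorial


@pytest.fixture(scope="session")
def gaussian_design():
    return FactorialDesignSpec(
        n_dam=8,
        n_sire=8,
        n_offspring_per_family=20,
        components={"dam": 0.4, "sire": 0.1, "dam_sire": 0.1, "residual": 1.0},
    )


@pytest.fixture(scope="session")
def gaussian_table(gaussian_design):
    return simulate_factorial(gaussian_design, seed=1)


@pytest.fixture(scope="session")
def binomial_design():
    return FactorialDesignSpec(
        n_dam=8,
        n_sire=8,
        n_offspring_per_family=30,
        components={"dam": 0.6, "sire": 0.2, "dam_sire": 0.2},
        family="binomial",
        link="logit",
    )


@pytest.fixture(scope="session")
def binomial_table(binomial_design):
    return simulate_factorial(binomial_design, seed=2)


@pytest.fixture(scope="session")
def poisson_design():
    return FactorialDesignSpec(
        n_dam=6,
        n_sire=6,
        n_offspring_per_family=25,
        components={"dam": 0.3, "sire": 0.1, "dam_sire": 0.1},
        family="poisson",
        link="log",
        intercept=1.0,
    )


@pytest.fixture(scope="session")
def poisson_table(poisson_design):
    return simulate_factorial(poisson_design, seed=3)


@pytest.fixture()
def count_frame():
    """Small replicate-level survival counts over a 3x3 factorial."""
    rng = np.random.default_rng(42)
    rows = []
    for d in range(3):
        for s in range(3):
            for rep in ("a", "b"):
                alive = int(rng.integers(0, 8))
                dead = int(rng.integers(0, 8))
                rows.append(
                    {
                        "dam": f"D{d}",
                        "sire": f"S{s}",
                        "replicate": rep,
                        "alive": alive,
                        "dead": dead,
                    }
                )
    return pd.DataFrame(rows)


def make_table(df, **kwargs):
    return ObservationTable(df, **kwargs)
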