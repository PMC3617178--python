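import numpy as np
import pytest

from twinfam import model as tfm
from twinfam import simulate as tfs


@pytest.fixture(scope="session")
def truth():
    return tfs.default_truth()


@pytest.fixture(scope="session")
def truth_eq(truth):
    return tfm.solve_equilibrium(truth)


@pytest.fixture(scope="session")
def random_mating_model():
    """Full ABDSTE variant with the copath matrix zeroed."""
    model = tfm.build_model("ABDSTE")
    model.matrices["mu"][:] = 0.0
    return model


@pytest.fixture(scope="session")
def small_pop(truth):
    """Small equilibrium pool shared across tests (20k pairs, 15 gens)."""
    return tfs.simulate_equilibrium_population(truth, 20000, 15, seed=2024)


@pytest.fixture(scope="session")
def small_table(small_pop):
    """Standardized-trait family table, ~590 families, four-sample design."""
    table, _ = tfs.simulate_families(small_pop, tfs.table2_design(0.2),
                                     seed=7)
    return table


@pytest.fixture(scope="session")
def raw_table(small_pop):
    """Raw-scale table with ages, covariate effects and missingness."""
    config = tfs.SimConfig(design=tfs.table2_design(0.2), seed=5,
                           outlier_rate=0.0)
    table, _ = tfs.simulate_families(small_pop, config.design, seed=6)
    return tfs.apply_observation_model(table, config, seed=8)


def univariate_model(a2: float, mu: float) -> tfm.NTFModel:
    """Embed a one-trait model (trait2 inert) in the bivariate machinery."""
    m = tfm.build_model(
        "ABDSTE", drop=("b", "d_m", "d_f", "s_m", "s_f", "t_m", "t_f"),
        free_means=False)
    a = np.sqrt(a2)
    e = np.sqrt(max(1.0 - a2, 1e-6))
    for name, diag in (("a", a), ("e", e)):
        for sex in ("m", "f"):
            m.matrices[f"{name}_{sex}"][:] = [[diag, 0.0], [0.0, 0.5]]
    m.matrices["mu"][:] = [[mu, 0.0], [0.0, 0.0]]
    return m
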