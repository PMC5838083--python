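"""Shared fixtures: synthetic environments and the packaged experiments.

Expensive chains (environment generation, track simulation, CRW nulls,
matchup, model fit) are session-scoped so the suite builds them once.
"""

import logging
import warnings

import numpy as np
import pytest

import cpforage as cf
import cpforage.model as mdl
import cpforage.pipeline as pl

warnings.filterwarnings("ignore")
logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def demo_env():
    """Default winter coastal-upwelling environment."""
    return cf.generate_env_fields(cf.EnvScenario(seed=42))


@pytest.fixture(scope="session")
def demo_landmask(demo_env):
    return cf.land_lookup(demo_env)


@pytest.fixture(scope="session")
def demo_rookery(demo_env):
    return cf.synthetic.default_rookery(demo_env)


@pytest.fixture(scope="session")
def recovery_setup():
    return pl.recovery_experiment_setup()


@pytest.fixture(scope="session")
def recovery_env(recovery_setup):
    return cf.generate_env_fields(recovery_setup["scenario"])


@pytest.fixture(scope="session")
def recovery_table(recovery_setup, recovery_env):
    colony = cf.synthetic.default_rookery(recovery_env)
    return pl.matchup_chain(recovery_env, colony, recovery_setup["truth"],
                            recovery_setup["n_individuals"],
                            recovery_setup["trips_per_individual"],
                            recovery_setup["tracks_seed"],
                            recovery_setup["crw_seed_base"])


@pytest.fixture(scope="session")
def recovery_fit(recovery_setup, recovery_table):
    assembled = mdl.assemble_dataset(recovery_table,
                                     seed=recovery_setup["assembly_seed"])
    spec = mdl.ModelSpec(covariates=recovery_setup["covariates"])
    return assembled, mdl.fit_binomial_gamm(assembled, spec)


@pytest.fixture(scope="session")
def balanced_null_table():
    """Large modeling table with labels balanced within each individual.

    Covariates are independent of the labels; used for type-I and
    permutation properties of the fitter.
    """
    import pandas as pd
    rng = np.random.default_rng(7)
    n, G = 4800, 16
    per = n // G
    grp = np.repeat([f"A{i:02d}" for i in range(G)], per)
    y = np.concatenate([rng.permutation(np.repeat([0, 1], per // 2))
                        for _ in range(G)])
    return pd.DataFrame({"c1": rng.uniform(0, 1, n),
                         "c2": rng.uniform(0, 1, n),
                         "animal_id": grp, "presence": y})
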