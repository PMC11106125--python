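import numpy as np
import pandas as pd
import pytest

from twinmod.ace import (
    ACEModelSpec,
    ModerationCoefficients,
    PathMatrices,
    ThresholdModel,
)
from twinmod.io import VariableSpec
from twinmod.simulate import SimulationConfig, default_study_config, simulate_twins


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale dataset (319 MZ + 553 DZ) from the default conditions."""
    return simulate_twins(default_study_config(12345))


@pytest.fixture(scope="session")
def unmoderated_config():
    """Default study conditions with the moderation slope switched off."""
    cfg = default_study_config(0)
    spec = cfg.spec
    mods = ModerationCoefficients.zeros(spec.k)
    spec2 = ACEModelSpec(
        variables=list(spec.variables),
        paths=PathMatrices(spec.paths.a.copy(), spec.paths.c.copy(), spec.paths.e.copy()),
        mods=mods,
        thresholds={k: ThresholdModel(v.tau.copy(), dict(v.gammas))
                    for k, v in spec.thresholds.items()},
        means=spec.means.copy(),
        include_C=False,
        moderator=None,
    )
    return SimulationConfig(n_mz=cfg.n_mz, n_dz=cfg.n_dz, spec=spec2,
                            prevalence=cfg.prevalence, seed=0)


def univariate_spec(a2=0.5, c2=0.0, e2=0.5, name="X"):
    paths = PathMatrices(np.array([[np.sqrt(a2)]]), np.array([[np.sqrt(c2)]]),
                         np.array([[np.sqrt(e2)]]))
    return ACEModelSpec(variables=[VariableSpec(name, "continuous")], paths=paths,
                        include_C=c2 > 0)


@pytest.fixture
def tiny_table():
    """Two complete pairs (one MZ, one DZ), three phenotypes."""
    return pd.DataFrame({
        "pair_id": ["p1", "p2"],
        "zygosity": ["MZ", "DZ"],
        "age_t1": [35.0, 40.0], "age_t2": [35.0, 40.0],
        "sex_t1": [0.0, 1.0], "sex_t2": [0.0, 0.0],
        "ELA_t1": [30.0, 45.0], "ELA_t2": [31.5, 50.0],
        "CGN_t1": [20.0, 26.0], "CGN_t2": [22.0, 30.0],
        "SO_t1": [0.0, 1.0], "SO_t2": [0.0, 0.0],
    })


@pytest.fixture
def tiny_specs():
    return [
        VariableSpec("CGN", "continuous"),
        VariableSpec("ELA", "continuous"),
        VariableSpec("SO", "ordinal", n_categories=2),
    ]
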