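import numpy as np
import pandas as pd
import pytest

import crossconn as cc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small full cohort used by several structural tests."""
    cfg = cc.SynthConfig(
        n_nodes=20,
        group_sizes=(8, 8),
        effect_sizes=(0.0, 0.8),
        planted_edge_count=8,
        timepoints_per_paradigm=80,
        n_nuisance=4,
        seed=101,
    )
    return cc.generate_cohort(cfg)


def make_design(n_per_group, n_groups=2, covariates=None, seed=0):
    """Bare design with optional covariate frame."""
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    levels = tuple(f"g{k}" for k in range(n_groups))
    cov = None
    if covariates == "numeric":
        cov = pd.DataFrame({"age": rng.normal(20, 3, n), "fd": rng.gamma(3, 0.02, n)})
    elif covariates == "mixed":
        cov = pd.DataFrame(
            {
                "age": rng.normal(20, 3, n),
                "sex": rng.choice(["F", "M"], n),
                "site": rng.choice(["s1", "s2", "s3"], n),
            }
        )
    return cc.CohortDesign(
        subject_ids=[f"s{i}" for i in range(n)],
        group=np.repeat(levels, n_per_group),
        group_levels=levels,
        covariates=cov,
    )


@pytest.fixture
def design_factory():
    return make_design
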