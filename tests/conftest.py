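import warnings

import numpy as np
import pytest
from scipy.linalg import LinAlgWarning

from cascann.data_io import ExperimentMeta, ExpressionMatrix
from cascann.synthetic import generate_bundle, make_fixture

# LM deliberately pushes the damped normal equations into ill-conditioned
# territory before backing off; the solver warnings are expected noise.
warnings.filterwarnings("ignore", category=LinAlgWarning)


@pytest.fixture(scope="session")
def planted_module_bundle():
    return generate_bundle(make_fixture("planted_module", seed=2))


@pytest.fixture(scope="session")
def planted_delays_bundle():
    return generate_bundle(make_fixture("planted_delays", seed=0))


@pytest.fixture(scope="session")
def planted_dimer_bundle():
    return generate_bundle(make_fixture("planted_dimer", seed=0))


@pytest.fixture(scope="session")
def pure_noise_bundle():
    return generate_bundle(make_fixture("pure_noise", seed=3))


def make_expr(values, categories=None, conditions=None, time_points=None,
              replicate_groups=None, genes=None):
    """Small hand-rolled expression matrices for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_exp = values.shape
    genes = genes or [f"g{i+1}" for i in range(n_genes)]
    categories = categories or ["A"] * n_exp
    conditions = conditions or [f"c{i+1}" for i in range(n_exp)]
    time_points = time_points if time_points is not None else [None] * n_exp
    replicate_groups = replicate_groups or [f"e{i+1}" for i in range(n_exp)]
    meta = [
        ExperimentMeta(
            experiment_id=f"e{i+1}", category=categories[i],
            condition=conditions[i], time_point=time_points[i],
            replicate_group=replicate_groups[i])
        for i in range(n_exp)
    ]
    return ExpressionMatrix(genes=genes, experiments=meta, values=values)
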