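import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coremod import (AlterationCalls, ExpressionMatrix, MutationMatrix,
                     PlantConfig, compute_gene_universe, generate_dataset)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_mutation() -> MutationMatrix:
    """Five samples; g1 altered in {s1,s2}, g2 in {s3}, g3 in {s2,s3,s4}."""
    df = pd.DataFrame(
        {"g1": [1, 1, 0, 0, 0], "g2": [0, 0, 1, 0, 0], "g3": [0, 1, 1, 1, 0]},
        index=[f"s{i}" for i in range(1, 6)],
    )
    return MutationMatrix(indicator=df)


@pytest.fixture
def small_dataset():
    """Default synthetic benchmark dataset (one strict 3-gene module)."""
    return generate_dataset(PlantConfig(seed=11))


@pytest.fixture
def small_universe(small_dataset):
    from coremod import build_binary_mutation_matrix, collapse_metagenes

    somatic, cnv, expression, truth = small_dataset
    a = collapse_metagenes(build_binary_mutation_matrix(somatic, cnv))
    return a, expression, compute_gene_universe(a, expression)


def random_calls(rng: np.random.Generator, n_samples: int, n_genes: int,
                 p: float = 0.3) -> AlterationCalls:
    mat = (rng.random((n_samples, n_genes)) < p).astype(int)
    return AlterationCalls(pd.DataFrame(
        mat,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{i}" for i in range(n_genes)],
    ))


def random_expression(rng: np.random.Generator, n_samples: int,
                      n_genes: int) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(
        rng.normal(size=(n_samples, n_genes)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{i}" for i in range(n_genes)],
    ))
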