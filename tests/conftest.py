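import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tsevol.expression import ExpressionMatrix
from tsevol.synthetic import SyntheticConfig, gen_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic dataset shared by integration-style tests."""
    cfg = SyntheticConfig(
        n_genes=200,
        n_duplicate_pairs=10,
        n_background=20,
        codon_length=150,
        seed=11,
    )
    return gen_dataset(cfg)


def make_matrix(values, genes=None, tissues=None, subgenomes=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(values.shape[1])]
    sub = pd.Series(subgenomes or ["unknown"] * len(genes), index=genes, dtype=object)
    return ExpressionMatrix(
        fpkm=pd.DataFrame(values, index=genes, columns=tissues), subgenome=sub
    )
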