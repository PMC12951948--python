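import logging

import numpy as np
import pytest

from anscore import ExpressionMatrix, SyntheticConfig, generate_dataset

logging.getLogger("anscore").setLevel(logging.ERROR)
for _name in ("anscore.controls", "anscore.scoring", "anscore.core",
              "anscore.benchmarks", "anscore.annotation", "anscore.io"):
    logging.getLogger(_name).setLevel(logging.ERROR)


def random_matrix(n, p, seed=0, sparsity=0.0, prefix=""):
    """Random nonnegative log-scale-like matrix with unique ids."""
    rng = np.random.default_rng(seed)
    X = rng.gamma(shape=2.0, scale=0.5, size=(n, p))
    if sparsity:
        X[rng.random((n, p)) < sparsity] = 0.0
    return ExpressionMatrix(
        values=X,
        cell_ids=[f"{prefix}cell{i}" for i in range(n)],
        gene_ids=[f"{prefix}gene{j}" for j in range(p)],
    )


@pytest.fixture(scope="session")
def three_type_dataset():
    """Shared annotation-scale dataset: 3 types x 200 cells, 20 markers."""
    cfg = SyntheticConfig(
        n_genes=1000,
        cell_types=(("typeA", 200), ("typeB", 200), ("typeC", 200)),
        markers_per_type=20,
        marker_log2fc=2.0,
        dropout_rate=0.3,
        seed=5,
    )
    return generate_dataset(cfg)
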