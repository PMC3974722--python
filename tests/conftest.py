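import numpy as np
import pytest

import somcoex as sx
from somcoex import consistency as cons


@pytest.fixture(scope="session")
def default_grid():
    return sx.HexGrid()


@pytest.fixture(scope="session")
def synthetic_run():
    """One default synthetic study, preprocessed and trained (seed 1)."""
    spec = sx.SyntheticSpec(rng_seed=1)
    datasets, catalog, truth = sx.generate(spec)
    processed, models, tables = [], [], []
    for i, ds in enumerate(datasets):
        clean, _, _ = sx.preprocess_dataset(ds, catalog)
        model = sx.train(clean, sx.TrainingConfig(rng_seed=100 + i))
        processed.append(clean)
        models.append(model)
        tables.append(cons.assign_bmus(model, clean))
    return {
        "spec": spec,
        "datasets": datasets,
        "catalog": catalog,
        "truth": truth,
        "processed": processed,
        "models": models,
        "tables": tables,
    }


@pytest.fixture
def small_dataset():
    """3 genes x 4 samples with one missing cell."""
    return sx.ExpressionDataset(
        database_name="toy",
        gene_ids=["g1", "g2", "g3"],
        sample_times=np.array([0.0, 7.0, 14.0, 21.0]),
        values=np.array(
            [[0.1, 0.2, 0.3, 0.4], [1.0, 0.5, 0.0, -0.5], [0.0, 0.0, 1.0, 2.0]]
        ),
        missing_mask=np.array(
            [
                [False, False, False, False],
                [False, True, False, False],
                [False, False, False, False],
            ]
        ),
        scale="log2-ratio",
    )
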