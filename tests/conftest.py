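import numpy as np
import pytest

from synerank.core_data import Dataset, DrugRecord, ExpressionMatrix, MeasurementRecord
from synerank.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Hand-built dataset: 3 drugs, 2 cells, one 2x2 combination matrix
    per pair plus monotherapy rows."""
    drugs = [
        DrugRecord("DA", "CCO"),
        DrugRecord("DB", "c1ccccc1"),
        DrugRecord("DC", "CC(=O)O"),
    ]
    doses = [1e-7, 1e-6]
    cells = ["X", "Y"]
    measurements = []
    for d1, d2 in [("DA", "DB"), ("DA", "DC")]:
        for cell in cells:
            for a in doses:
                for b in doses:
                    measurements.append(
                        MeasurementRecord(d1, d2, a, b, cell, 100.0 - 1e7 * a - 5e6 * b)
                    )
    for d in ("DA", "DB", "DC"):
        for cell in cells:
            for a in doses:
                measurements.append(MeasurementRecord(d, None, a, 0.0, cell, 95.0 - 1e7 * a))
    rng = np.random.default_rng(0)
    expr = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(30)],
        cell_ids=cells,
        values=rng.normal(size=(30, 2)),
    )
    return Dataset(drugs=drugs, measurements=measurements, expression=expr)


@pytest.fixture(scope="session")
def small_screen():
    """A generated small screen with noise, shared across tests."""
    cfg = GeneratorConfig(
        n_drugs=6, n_cells=3, n_pairs=6, n_genes=60, noise_sd=1.0, seed=11
    )
    dataset, truth = generate_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def ranking_benchmark():
    """Noiseless benchmark: ~100 combination lists on a 4x4 dose grid."""
    cfg = GeneratorConfig(n_drugs=12, n_cells=6, n_pairs=17, noise_sd=0.0, seed=7)
    dataset, _ = generate_dataset(cfg)
    return dataset
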